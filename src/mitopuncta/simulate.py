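"""Synthetic triple-stained fields with known ground truth.

Scenes emulate the structures the subtraction method must separate:

* **nuclei** — bright discs positive for both H2B and (via the nuclear bleed
  factor ``bleed_y_true``) dsDNA;
* **mitochondrial network** — curvilinear Hsp60-positive filaments with
  brighter nucleoid bumps.  In control scenes the dsDNA channel inside
  mitochondria is exactly ``bleed_x_true`` times the Hsp60 channel, the
  proportionality assumption on which the calibration rule rests;
* **ectopic puncta** — dsDNA-only discs placed in marker-free cytoplasm, the
  objects the method counts;
* **nuclear-origin dots** — cytoplasmic dsDNA discs with a supra-threshold
  histone co-signal (excluded by the histone-overlap rule);
* **donuts** — dsDNA annuli with a faint, sub-threshold histone co-signal,
  the ring artefact excluded by the Euler-number rule.

Rendering is a pure function of the :class:`SceneSpec` (including its seed).
Each structural layer draws from its own child RNG, so enlarging one layer
(say, adding histone dots) leaves every other layer — and the noise field —
bit-identical.  Ectopic puncta are placed well clear of nuclei and the
mitochondrial network so ground-truth classes are unambiguous.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import disk as disk_selem

from .io import ChannelStack

logger = logging.getLogger(__name__)

PRESETS = ("control", "tfam_kd", "gba_kd")

# rendering amplitudes (arbitrary intensity units, full scale ~1)
_NUCLEUS_AMP = (0.8, 1.0)
_NETWORK_BASE = 0.6
_NUCLEOID_AMP = 1.0
_DOT_DSDNA_EXTRA = 0.35     # survives subtract-2 at this amplitude
_DOT_H2B_AMP = 0.55         # supra-threshold histone co-signal
_DONUT_AMP = 0.35
_DONUT_H2B_AMP = 0.08       # sub-threshold: the "small histone signal" case
_DONUT_OUTER_PX = 7
_DONUT_INNER_PX = 4

# placement margins (px): puncta keep clear of everything else so that
# ground-truth classes stay unambiguous after PSF blur
_PUNCTUM_CLEARANCE = 6
_PUNCTUM_SPACING = 8
_MAX_TRIES = 4000


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed after bounded retries."""


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic field; the seed fixes it exactly."""

    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.25
    n_cells: int = 5
    n_ectopic_puncta: int = 10
    ectopic_area_range_um2: tuple[float, float] = (3.0, 12.0)
    n_nuclear_dots: int = 0
    n_donuts: int = 0
    bleed_x_true: float = 1.5
    bleed_y_true: float = 0.6
    psf_sigma_px: float = 1.0
    noise_model: str = "gaussian"
    noise_sigma: float = 0.05
    ectopic_amplitude: float = 0.25
    seed: int = 0
    image_id: str = ""

    def __post_init__(self) -> None:
        if min(self.field_size_px) < 32:
            raise ValueError("field must be at least 32 px on a side")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        for name in ("n_cells", "n_ectopic_puncta", "n_nuclear_dots", "n_donuts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.ectopic_area_range_um2
        if not (0 < lo <= hi):
            raise ValueError("bad ectopic_area_range_um2")
        if self.bleed_x_true < 0 or self.bleed_y_true < 0:
            raise ValueError("bleed factors must be non-negative")
        if self.noise_model not in ("gaussian", "poisson_gaussian"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson_gaussian'")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclasses.dataclass
class GroundTruth:
    """Object table (type, centroid, area) plus the true bleed factors."""

    objects: pd.DataFrame
    true_factors: tuple[float, float]

    def of_type(self, object_type: str) -> pd.DataFrame:
        return self.objects[self.objects["type"] == object_type]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _paint_disc(img: np.ndarray, center: tuple[int, int], radius: float, amplitude: float) -> None:
    rr, cc = draw_disk(center, radius, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], amplitude)


def _disc_free(occupied: np.ndarray, center: tuple[int, int], radius: float) -> bool:
    rr, cc = draw_disk(center, radius, shape=occupied.shape)
    return not occupied[rr, cc].any()


def _place_disc(
    rng: np.random.Generator,
    occupied: np.ndarray,
    radius_px: float,
    clearance_px: float,
    what: str,
) -> tuple[int, int]:
    """Random centre whose disc + clearance avoids all occupied pixels."""
    h, w = occupied.shape
    margin = int(np.ceil(radius_px)) + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(f"field too small for {what}")
    for _ in range(_MAX_TRIES):
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if _disc_free(occupied, (r, c), radius_px + clearance_px):
            return r, c
    raise PlacementError(f"could not place {what} after {_MAX_TRIES} tries; field too crowded")


def _render_nuclei(spec: SceneSpec, h2b: np.ndarray, records: list[dict]) -> np.ndarray:
    rng = _rng(spec.seed, 1)
    nuc_mask = np.zeros(spec.field_size_px, dtype=bool)
    occupied = np.zeros(spec.field_size_px, dtype=bool)
    for i in range(spec.n_cells):
        r_um = rng.uniform(4.5, 6.0)
        r_px = r_um / spec.pixel_size_um
        center = _place_disc(rng, occupied, r_px, 6.0, "nucleus")
        amp = rng.uniform(*_NUCLEUS_AMP)
        rr, cc = draw_disk(center, r_px, shape=h2b.shape)
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        profile = amp * (1.0 - 0.15 * d2 / r_px**2)
        h2b[rr, cc] = np.maximum(h2b[rr, cc], profile)
        nuc_mask[rr, cc] = True
        occupied[rr, cc] = True
        records.append(
            {"type": "nucleus", "row": center[0], "col": center[1],
             "area_um2": np.pi * r_um**2}
        )
    return nuc_mask


def _render_network(
    spec: SceneSpec, nuc_mask: np.ndarray, hsp60: np.ndarray, records: list[dict]
) -> np.ndarray:
    rng = _rng(spec.seed, 2)
    h, w = spec.field_size_px
    forbidden = ndi.binary_dilation(nuc_mask, structure=disk_selem(2))
    skeleton = np.zeros(spec.field_size_px, dtype=bool)
    nucleoids: list[tuple[int, int, float]] = []
    n_filaments = 2 * spec.n_cells  # mitochondrial mass scales with cell count
    step = 2.0
    for fil in range(n_filaments):
        start = None
        for _ in range(_MAX_TRIES):
            r = int(rng.integers(3, h - 3))
            c = int(rng.integers(3, w - 3))
            if not forbidden[r, c]:
                start = (float(r), float(c))
                break
        if start is None:
            raise PlacementError("could not seed a mitochondrial filament")
        theta = rng.uniform(0, 2 * np.pi)
        pos = start
        n_steps = int(rng.integers(35, 70))
        length = 0
        for s in range(n_steps):
            theta += rng.normal(0.0, 0.35)
            nxt = (pos[0] + step * np.sin(theta), pos[1] + step * np.cos(theta))
            ri, ci = int(round(nxt[0])), int(round(nxt[1]))
            if not (1 <= ri < h - 1 and 1 <= ci < w - 1) or forbidden[ri, ci]:
                break
            rr, cc = draw_line(int(round(pos[0])), int(round(pos[1])), ri, ci)
            skeleton[rr, cc] = True
            pos = nxt
            length += 1
            if rng.random() < 0.15:
                nucleoids.append((ri, ci, rng.uniform(1.0, 2.0)))
        records.append(
            {"type": "mito_segment", "row": start[0], "col": start[1],
             "area_um2": length * step * 3 * spec.pixel_size_um**2}
        )
    network = ndi.binary_dilation(skeleton, structure=disk_selem(1))
    network &= ~nuc_mask  # matrix signal is strictly cytoplasmic
    hsp60[network] = np.maximum(hsp60[network], _NETWORK_BASE)
    for r, c, rad in nucleoids:
        rr, cc = draw_disk((r, c), rad, shape=hsp60.shape)
        keep = ~nuc_mask[rr, cc]
        hsp60[rr[keep], cc[keep]] = _NUCLEOID_AMP
    return hsp60 > 0


def _render_blobs(
    spec: SceneSpec,
    stream: int,
    n: int,
    occupied: np.ndarray,
    what: str,
    records: list[dict],
) -> list[tuple[int, int, float]]:
    """Place n discs with standard clearances; returns (row, col, radius_px)."""
    rng = _rng(spec.seed, stream)
    placed = []
    lo, hi = spec.ectopic_area_range_um2
    for i in range(n):
        if what == "donut":
            r_px = float(_DONUT_OUTER_PX)
            area_um2 = np.pi * (_DONUT_OUTER_PX**2 - _DONUT_INNER_PX**2) * spec.pixel_size_um**2
        else:
            area_um2 = rng.uniform(lo, hi)
            r_px = np.sqrt(area_um2 / np.pi) / spec.pixel_size_um
        center = _place_disc(rng, occupied, r_px, _PUNCTUM_CLEARANCE, what)
        rr, cc = draw_disk(center, r_px + _PUNCTUM_SPACING, shape=occupied.shape)
        occupied[rr, cc] = True
        placed.append((center[0], center[1], r_px))
        records.append(
            {"type": what, "row": center[0], "col": center[1], "area_um2": area_um2}
        )
    return placed


def _apply_noise(spec: SceneSpec, channel: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "poisson_gaussian" and spec.noise_sigma > 0:
        photons = 200.0  # full-scale photon budget for the shot-noise term
        channel = rng.poisson(np.clip(channel, 0, None) * photons) / photons
    if spec.noise_sigma > 0:
        channel = channel + rng.normal(0.0, spec.noise_sigma, channel.shape)
    return np.clip(channel, 0.0, None)


def render(spec: SceneSpec) -> tuple[ChannelStack, GroundTruth]:
    """Render a scene; same spec (same seed) gives bit-identical output."""
    records: list[dict] = []
    h2b = np.zeros(spec.field_size_px, dtype=np.float64)
    hsp60 = np.zeros(spec.field_size_px, dtype=np.float64)
    ds_extra = np.zeros(spec.field_size_px, dtype=np.float64)

    nuc_mask = _render_nuclei(spec, h2b, records)
    net_mask = _render_network(spec, nuc_mask, hsp60, records)

    # exclusion map for cytoplasmic objects: nuclei and network plus clearance
    occupied = ndi.binary_dilation(
        nuc_mask | net_mask, structure=disk_selem(_PUNCTUM_CLEARANCE)
    )

    for r, c, r_px in _render_blobs(
        spec, 3, spec.n_ectopic_puncta, occupied, "ectopic_punctum", records
    ):
        _paint_disc(ds_extra, (r, c), r_px, spec.ectopic_amplitude)

    for r, c, r_px in _render_blobs(
        spec, 4, spec.n_nuclear_dots, occupied, "nuclear_dot", records
    ):
        _paint_disc(ds_extra, (r, c), r_px, _DOT_DSDNA_EXTRA)
        _paint_disc(h2b, (r, c), r_px, _DOT_H2B_AMP)

    for r, c, _ in _render_blobs(spec, 5, spec.n_donuts, occupied, "donut", records):
        outer = np.zeros(spec.field_size_px, dtype=bool)
        rr, cc = draw_disk((r, c), _DONUT_OUTER_PX, shape=outer.shape)
        outer[rr, cc] = True
        rr, cc = draw_disk((r, c), _DONUT_INNER_PX, shape=outer.shape)
        outer[rr, cc] = False
        ds_extra[outer] = np.maximum(ds_extra[outer], _DONUT_AMP)
        h2b[outer] = np.maximum(h2b[outer], _DONUT_H2B_AMP)

    dsdna = spec.bleed_y_true * h2b + spec.bleed_x_true * hsp60 + ds_extra

    channels = []
    rng_noise = _rng(spec.seed, 6)
    for channel in (dsdna, h2b, hsp60):
        if spec.psf_sigma_px > 0:
            channel = ndi.gaussian_filter(channel, spec.psf_sigma_px, mode="constant")
        channels.append(_apply_noise(spec, channel, rng_noise))

    columns = ["object_id", "type", "row", "col", "area_um2"]
    if records:
        objects = pd.DataFrame(records)
        objects.insert(0, "object_id", np.arange(len(objects)))
    else:
        objects = pd.DataFrame(columns=columns)
    stack = ChannelStack(
        dsdna=channels[0],
        h2b=channels[1],
        hsp60=channels[2],
        pixel_size_um=spec.pixel_size_um,
        image_id=spec.image_id or f"scene-seed{spec.seed}",
    )
    return stack, GroundTruth(objects=objects, true_factors=(spec.bleed_x_true, spec.bleed_y_true))


def preset(name: str, seed: int) -> SceneSpec:
    """Scene specs mimicking the three experimental conditions.

    * ``control`` — at most one ectopic punctum, no nuclear-origin dots;
    * ``tfam_kd`` — many (8–15) histone-negative ectopic puncta, the
      mitochondrial-DNA-leakage phenotype;
    * ``gba_kd`` — a mixture: 4–8 ectopic puncta plus 3–6 histone-positive
      nuclear-origin dots.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    rng = _rng(seed, 99)
    if name == "control":
        n_ectopic, n_dots = int(rng.integers(0, 2)), 0
    elif name == "tfam_kd":
        n_ectopic, n_dots = int(rng.integers(8, 16)), 0
    else:  # gba_kd
        n_ectopic, n_dots = int(rng.integers(4, 9)), int(rng.integers(3, 7))
    return SceneSpec(
        n_ectopic_puncta=n_ectopic,
        n_nuclear_dots=n_dots,
        seed=seed,
        image_id=f"{name}-seed{seed}",
    )
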