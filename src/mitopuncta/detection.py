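"""Binarization, puncta measurement, filtering and classification.

The subtracted dsDNA image is binarized (Otsu on its non-zero pixels by
default), connected components are measured, and each component ("punctum")
receives exactly one class by the first failing rule, in order:

1. **size** — area outside the inclusive ``[min_area_um2, max_area_um2]``
   window (defaults 2–20 μm², the HeLa values) → ``rejected_size``;
2. **shape** — circularity ``4π·area/perimeter²`` (capped at 1) outside
   ``[min_circularity, max_circularity]`` → ``rejected_shape``;
3. **donut** — Euler number < 1, i.e. the component contains a hole.
   Ring-shaped dsDNA arises from nuclear-origin cytoplasmic DNA whose faint
   histone signal survives subtraction only at the rim → ``nuclear_origin_donut``;
4. **histone overlap** — more than ``histone_overlap_max_fraction`` of the
   component lies on histone-positive pixels → ``nuclear_origin_overlap``;
5. otherwise → ``ectopic_mito``, a cytosolic mitochondria-derived dsDNA punctum.

With the ``subtract1`` variant (H2B not subtracted) rule 4 is the mandatory
discriminator against nuclear-origin dsDNA; with ``subtract2`` it is a
safeguard.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .calibration import CalibrationFactors, _otsu_positive
from .cells import NucleusParams, count_cells, dots_per_cell
from .io import ChannelStack
from .subtraction import SubtractedImage, apply_contrast, subtract

logger = logging.getLogger(__name__)

CLASSES = (
    "ectopic_mito",
    "nuclear_origin_donut",
    "nuclear_origin_overlap",
    "rejected_size",
    "rejected_shape",
)


@dataclasses.dataclass(frozen=True)
class DetectionParams:
    """Puncta filter settings; defaults follow the HeLa protocol."""

    min_area_um2: float = 2.0
    max_area_um2: float = 20.0
    min_circularity: float = 0.1
    max_circularity: float = 1.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    connectivity: int = 8
    histone_overlap_max_fraction: float = 0.3
    exclude_donuts: bool = True
    #: Gaussian sigma (px) applied to the subtracted image by :func:`detect`
    #: before binarization.  Puncta a few pixels across sit barely above the
    #: per-pixel noise floor; averaging over the spot footprint restores the
    #: bimodality the automatic threshold needs.  0 disables.
    denoise_sigma: float = 1.0
    #: Holes smaller than this are noise dropouts, not donut lumina, and are
    #: filled before measurement; a resolvable ring lumen is several times
    #: larger.  0 disables filling.
    fill_holes_below_um2: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("need 0 < min_area_um2 < max_area_um2")
        if not (0 <= self.min_circularity <= self.max_circularity <= 1.0):
            raise ValueError("need 0 <= min_circularity <= max_circularity <= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if not (0 <= self.histone_overlap_max_fraction <= 1):
            raise ValueError("histone_overlap_max_fraction must lie in [0, 1]")
        if self.denoise_sigma < 0:
            raise ValueError("denoise_sigma must be >= 0")
        if self.fill_holes_below_um2 < 0:
            raise ValueError("fill_holes_below_um2 must be >= 0")


@dataclasses.dataclass
class Punctum:
    """One measured connected component of the binarized subtracted image."""

    label: int
    area_um2: float
    perimeter_um: float
    circularity: float
    euler_number: int
    centroid: tuple[float, float]
    histone_overlap_fraction: float
    classification: str


@dataclasses.dataclass
class DetectionResult:
    image_id: str
    puncta: list[Punctum]
    n_ectopic: int
    n_cells: int
    dots_per_cell: float | None
    params: DetectionParams
    factors: CalibrationFactors

    def to_dataframe(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "image_id": self.image_id,
                    "label": p.label,
                    "area_um2": p.area_um2,
                    "perimeter_um": p.perimeter_um,
                    "circularity": p.circularity,
                    "euler_number": p.euler_number,
                    "centroid_row": p.centroid[0],
                    "centroid_col": p.centroid[1],
                    "histone_overlap_fraction": p.histone_overlap_fraction,
                    "classification": p.classification,
                }
                for p in self.puncta
            ]
        )


def binarize(
    image: SubtractedImage | np.ndarray,
    params: DetectionParams | None = None,
    *,
    threshold_source: np.ndarray | None = None,
) -> np.ndarray:
    """Binarize a subtracted image; pixels >= threshold are foreground.

    The Otsu threshold is computed on the non-zero pixels only (the clipped
    zero background would otherwise dominate the histogram).  An all-zero
    image yields an all-false mask with a warning rather than an error.

    ``threshold_source`` optionally supplies the values the threshold is
    estimated from while the mask is still taken on ``image``;
    :func:`detect` uses this to threshold at the scale of the *raw*
    subtracted image while masking its denoised version, which keeps the
    threshold anchored to the per-pixel noise floor.
    """
    params = params or DetectionParams()
    values = image.values if isinstance(image, SubtractedImage) else np.asarray(image)
    if values.min() < 0:
        raise ValueError("binarize expects a non-negative image")
    if params.threshold_method == "fixed":
        threshold = float(params.fixed_threshold)
    else:
        source = values if threshold_source is None else np.asarray(threshold_source)
        if not (source > 0).any():
            warnings.warn("all-zero image: returning empty mask", stacklevel=2)
            return np.zeros(values.shape, dtype=bool)
        threshold = _otsu_positive(source)
    logger.info("binarize: threshold %.6g (%s)", threshold, params.threshold_method)
    return values >= threshold


def _classify(
    area_um2: float,
    circularity: float,
    euler_number: int,
    overlap_fraction: float,
    params: DetectionParams,
) -> str:
    """First failing rule wins: size -> shape -> donut -> histone overlap."""
    if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
        return "rejected_size"
    if not (params.min_circularity <= circularity <= params.max_circularity):
        return "rejected_shape"
    if params.exclude_donuts and euler_number < 1:
        return "nuclear_origin_donut"
    if overlap_fraction > params.histone_overlap_max_fraction:
        return "nuclear_origin_overlap"
    return "ectopic_mito"


def _fill_small_holes(mask: np.ndarray, max_hole_px: int, object_connectivity: int) -> np.ndarray:
    """Fill background components smaller than ``max_hole_px`` that do not
    touch the image border (interior holes only).  Hole connectivity is the
    complement of the object connectivity."""
    if max_hole_px <= 0:
        return mask
    hole_connectivity = 1 if object_connectivity == 2 else 2
    inv_labels = measure.label(~mask, connectivity=hole_connectivity)
    if inv_labels.max() == 0:
        return mask
    border = np.unique(
        np.concatenate(
            [inv_labels[0, :], inv_labels[-1, :], inv_labels[:, 0], inv_labels[:, -1]]
        )
    )
    sizes = np.bincount(inv_labels.ravel())
    fill_ids = [
        i for i in range(1, sizes.size)
        if sizes[i] <= max_hole_px and i not in border
    ]
    if not fill_ids:
        return mask
    return mask | np.isin(inv_labels, fill_ids)


def _histone_positive(h2b: np.ndarray, factors: CalibrationFactors) -> np.ndarray:
    """Pixels where the scaled nuclear channel y*H2B exceeds its Otsu threshold."""
    scaled = (factors.y if factors.y > 0 else 1.0) * np.asarray(h2b, dtype=np.float64)
    try:
        t_nuc = _otsu_positive(scaled)
    except ValueError:
        return np.zeros(scaled.shape, dtype=bool)
    return scaled >= t_nuc


def circularity_from(area: float, perimeter: float) -> float:
    """ImageJ-convention circularity, ``4π·area/perimeter²`` capped at 1."""
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perimeter**2)


def find_puncta(
    mask: np.ndarray,
    h2b: np.ndarray,
    factors: CalibrationFactors,
    pixel_size_um: float,
    params: DetectionParams | None = None,
) -> list[Punctum]:
    """Measure and classify every connected component of ``mask``.

    The histone-overlap fraction of a component is the fraction of its pixels
    where the scaled nuclear channel ``y*H2B`` exceeds the nuclear threshold
    (Otsu of the positive scaled-H2B pixels).
    """
    params = params or DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    h2b = np.asarray(h2b, dtype=np.float64)
    if mask.shape != h2b.shape:
        raise ValueError(f"mask shape {mask.shape} != h2b shape {h2b.shape}")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")

    histone_positive = _histone_positive(h2b, factors)

    skimage_connectivity = 2 if params.connectivity == 8 else 1
    px_area = pixel_size_um**2
    max_hole_px = int(params.fill_holes_below_um2 / px_area)
    mask = _fill_small_holes(mask, max_hole_px, skimage_connectivity)
    labels = measure.label(mask, connectivity=skimage_connectivity)

    puncta: list[Punctum] = []
    for region in measure.regionprops(labels):
        n_px = int(region.area)
        area_um2 = n_px * px_area
        perimeter_px = float(region.perimeter)
        circ = circularity_from(float(region.area), perimeter_px)
        euler = int(measure.euler_number(region.image, connectivity=skimage_connectivity))
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        overlap = float(np.mean(histone_positive[rr, cc]))
        cls = _classify(area_um2, circ, euler, overlap, params)
        puncta.append(
            Punctum(
                label=int(region.label),
                area_um2=float(area_um2),
                perimeter_um=perimeter_px * pixel_size_um,
                circularity=float(circ),
                euler_number=euler,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                histone_overlap_fraction=overlap,
                classification=cls,
            )
        )
    return puncta


def batch_threshold(
    stacks: "list[ChannelStack]",
    factors: CalibrationFactors,
    variant: str = "subtract2",
) -> float:
    """Shared binarization threshold for one experiment batch.

    The staining protocol adjusts display conditions identically for every
    sample of a batch; the automated analogue is a single Otsu threshold
    computed over the pooled nonzero subtracted pixels of all fields, applied
    to each field via ``DetectionParams(threshold_method="fixed", ...)``.
    With variant ``subtract1`` histone-positive pixels are excluded from the
    pool, as in :func:`detect`.
    """
    pooled = []
    for stack in stacks:
        values = subtract(stack, factors, variant).values
        if variant == "subtract1":
            values = values[~_histone_positive(stack.h2b, factors)]
        pooled.append(np.ravel(values))
    return _otsu_positive(np.concatenate(pooled))


def detect(
    stack: ChannelStack,
    factors: CalibrationFactors,
    params: DetectionParams | None = None,
    variant: str = "subtract2",
    *,
    nucleus_params: NucleusParams | None = None,
    contrast_window: tuple[float, float] | None = None,
) -> DetectionResult:
    """Full per-field pipeline: subtract → binarize → classify → per-cell ratio."""
    params = params or DetectionParams()
    nucleus_params = nucleus_params or NucleusParams()
    if nucleus_params.min_nucleus_area_um2 <= params.max_area_um2:
        raise ValueError(
            "min_nucleus_area_um2 must exceed max punctum area; nuclei must "
            "not be confusable with puncta"
        )
    sub = subtract(stack, factors, variant)
    if contrast_window is not None:
        sub = apply_contrast(sub, contrast_window)
    raw = sub.values
    values = raw
    if params.denoise_sigma > 0:
        values = ndi.gaussian_filter(raw, params.denoise_sigma, mode="constant")
    threshold_source = raw
    if variant == "subtract1":
        # H2B was not subtracted, so nuclei stay bright and would capture the
        # Otsu threshold; estimate it from histone-negative pixels only (the
        # histone-positive ones are discarded by the overlap rule anyway).
        threshold_source = raw[~_histone_positive(stack.h2b, factors)]
    mask = binarize(values, params, threshold_source=threshold_source)
    puncta = find_puncta(mask, stack.h2b, factors, stack.pixel_size_um, params)
    n_cells, _ = count_cells(stack.h2b, stack.pixel_size_um, nucleus_params)
    n_ectopic = sum(p.classification == "ectopic_mito" for p in puncta)
    return DetectionResult(
        image_id=stack.image_id,
        puncta=puncta,
        n_ectopic=n_ectopic,
        n_cells=n_cells,
        dots_per_cell=dots_per_cell(n_ectopic, n_cells),
        params=params,
        factors=factors,
    )
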