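"""Cell counting from the histone-H2B (nuclear) channel.

One nucleus stands for one cell; the count is the denominator of the
field-level "ectopic dots per cell" ratio.  Nuclei are segmented by Otsu
threshold, hole filling, an area floor (so no punctum-sized object can ever be
mistaken for a nucleus), and an optional distance-transform watershed that
splits touching nuclei.  Border-touching nuclei are counted: the ratio uses
whole-field counts, and excluding them would bias the denominator.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .calibration import _otsu_positive, _smooth

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class NucleusParams:
    """Nucleus segmentation settings.

    ``min_nucleus_area_um2`` (default 40 μm², about half an adherent HeLa
    nucleus) must exceed the puncta max area so that the two object classes
    cannot overlap; :func:`mitopuncta.detection.detect` enforces this.
    """

    min_nucleus_area_um2: float = 40.0
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    split_touching: bool = True
    connectivity: int = 8
    smooth_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.min_nucleus_area_um2 > 0:
            raise ValueError("min_nucleus_area_um2 must be positive")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def count_cells(
    h2b: np.ndarray,
    pixel_size_um: float,
    params: NucleusParams | None = None,
) -> tuple[int, np.ndarray]:
    """Count nuclei in the H2B channel; returns (count, label mask).

    An empty field returns 0, never an error.
    """
    params = params or NucleusParams()
    h2b = np.asarray(h2b, dtype=np.float64)
    if h2b.min() < 0:
        raise ValueError("h2b must be non-negative")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")

    smoothed = _smooth(h2b, params.smooth_sigma)
    if params.threshold_method == "fixed":
        threshold = float(params.fixed_threshold)
    else:
        if not (smoothed > 0).any():
            return 0, np.zeros(h2b.shape, dtype=np.int32)
        threshold = _otsu_positive(smoothed)
    mask = smoothed >= threshold
    mask = ndi.binary_fill_holes(mask)

    min_px = max(1, int(round(params.min_nucleus_area_um2 / pixel_size_um**2)))
    mask = remove_small_objects(mask, max_size=min_px - 1)
    if not mask.any():
        return 0, np.zeros(h2b.shape, dtype=np.int32)

    connectivity = 2 if params.connectivity == 8 else 1
    labels = measure.label(mask, connectivity=connectivity)

    if params.split_touching:
        labels = _watershed_split(mask, labels, pixel_size_um, params)

    n = int(labels.max())
    logger.info("count_cells: threshold %.4g, %d nuclei", threshold, n)
    return n, labels


def _watershed_split(
    mask: np.ndarray, labels: np.ndarray, pixel_size_um: float, params: NucleusParams
) -> np.ndarray:
    """Split touching nuclei by distance-transform watershed.

    Marker peaks must be at least one minimal nucleus radius apart; the
    distance map is smoothed first so a lone convex nucleus keeps a single
    peak.  Components that end up with no peak (flat plateaus) keep their
    original label so nuclei are never lost.
    """
    r_min_px = max(3, int(round(np.sqrt(params.min_nucleus_area_um2 / np.pi) / pixel_size_um)))
    distance = ndi.distance_transform_edt(mask)
    distance_s = _smooth(distance, 2.0)
    coords = peak_local_max(
        distance_s, min_distance=r_min_px, labels=labels, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    seeded = set(np.unique(labels[markers > 0]))
    next_marker = len(coords) + 1
    for region in measure.regionprops(labels):
        if region.label not in seeded:
            r, c = region.coords[0]
            markers[r, c] = next_marker
            next_marker += 1
    return watershed(-distance_s, markers, mask=mask)


def dots_per_cell(n_ectopic: int, n_cells: int) -> float | None:
    """Field-level ratio of ectopic puncta to nuclei.

    Undefined (``None``) when the field contains no cells; such fields are
    excluded from group means and flagged in reports.
    """
    if n_ectopic < 0 or n_cells < 0:
        raise ValueError("counts must be non-negative")
    if n_cells == 0:
        return None
    return n_ectopic / n_cells
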