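"""Brute-force reference implementations used only by the tests.

Everything here is written with explicit per-pixel Python loops and no calls
into the package or into scikit-image, so that measurements and
classifications can be checked against an implementation that shares no code
with the one under test.
"""

from __future__ import annotations

import math

import numpy as np

SQRT2 = math.sqrt(2.0)

# weight lookup of the weighted border-configuration perimeter estimator:
# code = 1 (border pixel itself) + 2 per 4-adjacent border pixel
#          + 10 per diagonally adjacent border pixel
PERIMETER_WEIGHTS = {5: 1.0, 7: 1.0, 15: 1.0, 17: 1.0, 25: 1.0, 27: 1.0,
                     21: SQRT2, 33: SQRT2, 13: (1 + SQRT2) / 2, 23: (1 + SQRT2) / 2}

N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
N8 = N4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))
DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _inside(mask, r, c):
    return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]


def perimeter_brute(mask: np.ndarray) -> float:
    """Weighted-configuration perimeter of a binary image, pixel by pixel."""
    mask = np.asarray(mask, dtype=bool)
    border = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and any(not _inside(mask, r + dr, c + dc) for dr, dc in N4):
                border[r, c] = True
    total = 0.0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not border[r, c]:
                continue
            code = 1
            for dr, dc in N4:
                if _inside(border, r + dr, c + dc):
                    code += 2
            for dr, dc in DIAG:
                if _inside(border, r + dr, c + dc):
                    code += 10
            total += PERIMETER_WEIGHTS.get(code, 0.0)
    return total


def label_brute(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components (as pixel sets) by flood fill; connectivity 4 or 8."""
    mask = np.asarray(mask, dtype=bool)
    neigh = N8 if connectivity == 8 else N4
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and not seen[r, c]:
                stack, comp = [(r, c)], set()
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    comp.add((rr, cc))
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if _inside(mask, nr, nc) and not seen[nr, nc]:
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.append(comp)
    return comps


def euler_brute(component: set[tuple[int, int]], object_connectivity: int) -> int:
    """Euler number (1 - number of holes) of a single connected component.

    Holes are background components, in the complementary connectivity, that
    do not touch the border of the component's bounding box (padded by one).
    """
    rows = [p[0] for p in component]
    cols = [p[1] for p in component]
    r0, c0 = min(rows) - 1, min(cols) - 1
    h = max(rows) - r0 + 2
    w = max(cols) - c0 + 2
    img = np.zeros((h, w), dtype=bool)
    for r, c in component:
        img[r - r0, c - c0] = True
    hole_connectivity = 4 if object_connectivity == 8 else 8
    background = label_brute(~img, hole_connectivity)
    n_holes = 0
    for comp in background:
        if not any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp):
            n_holes += 1
    return 1 - n_holes


def fill_small_holes_brute(
    mask: np.ndarray, max_hole_px: int, object_connectivity: int
) -> np.ndarray:
    """Fill interior background components of at most ``max_hole_px`` pixels."""
    mask = np.asarray(mask, dtype=bool).copy()
    if max_hole_px <= 0:
        return mask
    h, w = mask.shape
    hole_connectivity = 4 if object_connectivity == 8 else 8
    for comp in label_brute(~mask, hole_connectivity):
        touches_border = any(r in (0, h - 1) or c in (0, w - 1) for r, c in comp)
        if not touches_border and len(comp) <= max_hole_px:
            for r, c in comp:
                mask[r, c] = True
    return mask


def otsu_brute(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive inter-class-variance maximisation over a 256-bin histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    total = counts.sum()
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
        if var_between > best:
            best, best_t = var_between, centers[k - 1]
    return float(best_t)


def classify_components_brute(
    mask: np.ndarray,
    histone_positive: np.ndarray,
    pixel_size_um: float,
    *,
    min_area_um2: float = 2.0,
    max_area_um2: float = 20.0,
    min_circularity: float = 0.1,
    max_circularity: float = 1.0,
    connectivity: int = 8,
    histone_overlap_max_fraction: float = 0.3,
    exclude_donuts: bool = True,
    fill_holes_below_um2: float = 0.5,
) -> dict[tuple[int, int], tuple]:
    """Classify every component of ``mask`` by direct pixel enumeration.

    Returns a mapping from a component's lexicographically smallest pixel to
    ``(n_px, area_um2, circularity, euler, overlap_fraction, classification)``.
    """
    px_area = pixel_size_um**2
    max_hole_px = int(fill_holes_below_um2 / px_area)
    filled = fill_small_holes_brute(mask, max_hole_px, connectivity)
    out = {}
    for comp in label_brute(filled, connectivity):
        n_px = len(comp)
        area = n_px * px_area
        sub = np.zeros(
            (max(p[0] for p in comp) - min(p[0] for p in comp) + 1,
             max(p[1] for p in comp) - min(p[1] for p in comp) + 1),
            dtype=bool,
        )
        r0 = min(p[0] for p in comp)
        c0 = min(p[1] for p in comp)
        for r, c in comp:
            sub[r - r0, c - c0] = True
        per = perimeter_brute(sub)
        circ = 1.0 if per <= 0 else min(1.0, 4.0 * math.pi * n_px / per**2)
        euler = euler_brute(comp, connectivity)
        overlap = sum(bool(histone_positive[r, c]) for r, c in comp) / n_px
        if not (min_area_um2 <= area <= max_area_um2):
            cls = "rejected_size"
        elif not (min_circularity <= circ <= max_circularity):
            cls = "rejected_shape"
        elif exclude_donuts and euler < 1:
            cls = "nuclear_origin_donut"
        elif overlap > histone_overlap_max_fraction:
            cls = "nuclear_origin_overlap"
        else:
            cls = "ectopic_mito"
        out[min(comp)] = (n_px, area, circ, euler, overlap, cls)
    return out


def ratio_quantile_brute(
    stacks, which: str, quantile: float, smooth_sigma: float,
    exclusion_radius_px: int, mask_erosion_px: int,
) -> float:
    """Calibration ratio quantile recomputed with per-pixel masking loops.

    Smoothing and Otsu thresholds are taken as given operations (scipy /
    histogram search); the masking geometry — dilation of the other marker,
    erosion of the own marker, mask combination and the ratio pooling — is
    re-derived pixel by pixel.
    """
    from scipy.ndimage import gaussian_filter

    pooled = []
    for stack in stacks:
        ds = gaussian_filter(stack.dsdna, smooth_sigma, mode="constant")
        h2b = gaussian_filter(stack.h2b, smooth_sigma, mode="constant")
        hsp = gaussian_filter(stack.hsp60, smooth_sigma, mode="constant")
        t_hsp = otsu_brute(hsp[hsp > 0])
        t_h2b = otsu_brute(h2b[h2b > 0])
        hsp_mask = hsp >= t_hsp
        h2b_mask = h2b >= t_h2b
        own_mask, other_mask, denom = (
            (hsp_mask, h2b_mask, hsp) if which == "x" else (h2b_mask, hsp_mask, h2b)
        )
        h, w = ds.shape
        for r in range(h):
            for c in range(w):
                if not own_mask[r, c]:
                    continue
                # erosion of the own mask by a disc
                eroded = True
                e = mask_erosion_px
                for dr in range(-e, e + 1):
                    for dc in range(-e, e + 1):
                        if dr * dr + dc * dc <= e * e and not _inside(own_mask, r + dr, c + dc):
                            eroded = False
                            break
                    if not eroded:
                        break
                if not eroded:
                    continue
                # exclusion buffer around the other marker
                near_other = False
                x = exclusion_radius_px
                for dr in range(-x, x + 1):
                    if near_other:
                        break
                    for dc in range(-x, x + 1):
                        if dr * dr + dc * dc <= x * x and _inside(other_mask, r + dr, c + dc):
                            near_other = True
                            break
                if near_other:
                    continue
                pooled.append(ds[r, c] / denom[r, c])
    return float(np.quantile(np.array(pooled), quantile, method="higher"))
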