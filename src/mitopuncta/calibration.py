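"""Estimation of the channel-subtraction scaling factors x and y.

The subtraction method removes intra-mitochondrial and nuclear dsDNA signal by
subtracting scaled copies of the Hsp60 (mitochondrial matrix) and histone-H2B
(nuclear) channels from the dsDNA channel.  The scalars are defined by their
effect on *control* images: ``x`` is the smallest multiplier such that
``dsDNA - x * Hsp60 <= 0`` over the mitochondrial signal of controls, and
``y`` likewise drives the nuclear dsDNA residual to zero or below.

Operationally both are quantiles of a pixelwise intensity ratio:

* ``x`` = quantile of ``dsDNA / Hsp60`` over pixels inside the mitochondrial
  mask (Hsp60 above its threshold) and away from nuclei,
* ``y`` = quantile of ``dsDNA / H2B`` over pixels inside the nuclear mask
  (H2B above its threshold) and away from mitochondria.

``quantile=1`` reproduces the literal "less than or equal to zero" rule; the
default 0.999 is robust to hot pixels.  Channels are lightly Gaussian-smoothed
before the ratio is taken (``smooth_sigma``, default 1.5 px) — the ratio of two
proportional signals is invariant under linear smoothing, while per-pixel
noise in the ratio shrinks by roughly the kernel norm, which keeps the extreme
quantiles usable on noisy data.  Two mask refinements serve the same end: a
buffer zone (``exclusion_radius_px``) around the *other* marker's mask is
excluded so that point-spread/smoothing tails of one structure never
contaminate the ratio of the other, and each mask is eroded by
``mask_erosion_px`` so that dim, PSF-mixed boundary pixels — whose ratio
variance diverges as the denominator approaches the threshold — never enter
the quantile.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .io import ChannelStack

logger = logging.getLogger(__name__)

#: residuals within this relative rounding of zero count as non-positive
_RESIDUAL_RTOL = 1e-9


@dataclasses.dataclass(frozen=True)
class CalibrationFactors:
    """The scalars x (Hsp60 multiplier) and y (H2B multiplier).

    ``quantile`` and ``mito_mask_threshold_method`` record how the factors
    were obtained; one factor pair is estimated per experiment batch from the
    pooled control images and applied unchanged to every condition.
    """

    x: float
    y: float
    quantile: float = 0.999
    mito_mask_threshold_method: str = "otsu"
    n_control_images: int = 1

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("factors must be non-negative")
        if not (0 < self.quantile <= 1):
            raise ValueError("quantile must lie in (0, 1]")
        if self.mito_mask_threshold_method not in ("otsu", "fixed"):
            raise ValueError("mask method must be 'otsu' or 'fixed'")
        if self.n_control_images < 1:
            raise ValueError("n_control_images must be positive")


def _otsu_positive(values: np.ndarray) -> float:
    """Otsu threshold computed on the strictly positive pixels only."""
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("no positive pixels to threshold")
    if np.ptp(positive) == 0:
        return float(positive.flat[0])
    return float(threshold_otsu(positive))


def _smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return arr
    return ndi.gaussian_filter(arr, sigma, mode="constant")


def _channel_threshold(values: np.ndarray, mask_method: str, fixed: float | None) -> float:
    if mask_method == "fixed":
        if fixed is None:
            raise ValueError("mask_method='fixed' requires a threshold value")
        return float(fixed)
    return _otsu_positive(values)


def _control_masks(
    stack: ChannelStack,
    mask_method: str,
    smooth_sigma: float,
    exclusion_radius_px: int,
    mask_erosion_px: int,
    fixed_hsp60_threshold: float | None,
    fixed_h2b_threshold: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed channels and the two calibration masks for one control image.

    Returns (ds_s, h2b_s, hsp_s, mito_mask, nuclear_mask).
    """
    ds_s = _smooth(stack.dsdna, smooth_sigma)
    h2b_s = _smooth(stack.h2b, smooth_sigma)
    hsp_s = _smooth(stack.hsp60, smooth_sigma)

    try:
        t_hsp = _channel_threshold(hsp_s, mask_method, fixed_hsp60_threshold)
        hsp_mask = hsp_s >= t_hsp
    except ValueError:
        hsp_mask = np.zeros(stack.shape, dtype=bool)
    try:
        t_h2b = _channel_threshold(h2b_s, mask_method, fixed_h2b_threshold)
        h2b_mask = h2b_s >= t_h2b
    except ValueError:
        h2b_mask = np.zeros(stack.shape, dtype=bool)

    if exclusion_radius_px > 0:
        selem = disk(exclusion_radius_px)
        h2b_buffer = ndi.binary_dilation(h2b_mask, structure=selem)
        hsp_buffer = ndi.binary_dilation(hsp_mask, structure=selem)
    else:
        h2b_buffer, hsp_buffer = h2b_mask, hsp_mask
    if mask_erosion_px > 0:
        core = disk(mask_erosion_px)
        hsp_core = ndi.binary_erosion(hsp_mask, structure=core)
        h2b_core = ndi.binary_erosion(h2b_mask, structure=core)
    else:
        hsp_core, h2b_core = hsp_mask, h2b_mask

    mito_mask = hsp_core & ~h2b_buffer
    nuclear_mask = h2b_core & ~hsp_buffer
    return ds_s, h2b_s, hsp_s, mito_mask, nuclear_mask


def _pooled_ratio(
    controls: Sequence[ChannelStack],
    which: str,
    mask_method: str,
    smooth_sigma: float,
    exclusion_radius_px: int,
    mask_erosion_px: int,
    fixed_hsp60_threshold: float | None,
    fixed_h2b_threshold: float | None,
) -> np.ndarray:
    if len(controls) == 0:
        raise ValueError("need at least one control image")
    ratios = []
    for stack in controls:
        ds_s, h2b_s, hsp_s, mito_mask, nuclear_mask = _control_masks(
            stack, mask_method, smooth_sigma, exclusion_radius_px,
            mask_erosion_px, fixed_hsp60_threshold, fixed_h2b_threshold,
        )
        if which == "x":
            mask, denom = mito_mask, hsp_s
        else:
            mask, denom = nuclear_mask, h2b_s
        if mask.any():
            ratios.append(ds_s[mask] / denom[mask])
    if not ratios:
        name = "mitochondrial" if which == "x" else "nuclear"
        raise ValueError(f"empty {name} mask: no pixels above threshold in any control")
    return np.concatenate(ratios)


def estimate_x(
    controls: Sequence[ChannelStack],
    quantile: float = 0.999,
    mask_method: str = "otsu",
    *,
    smooth_sigma: float = 1.5,
    exclusion_radius_px: int = 12,
    mask_erosion_px: int = 2,
    fixed_hsp60_threshold: float | None = None,
    fixed_h2b_threshold: float | None = None,
) -> float:
    """Estimate the Hsp60 multiplier x from control images.

    With ``quantile=1`` the returned x makes ``dsDNA - x*Hsp60 <= 0`` at every
    masked pixel of every control (the defining rule); smaller quantiles trade
    a controlled fraction of positive residual for robustness.
    """
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    ratios = _pooled_ratio(
        controls, "x", mask_method, smooth_sigma, exclusion_radius_px,
        mask_erosion_px, fixed_hsp60_threshold, fixed_h2b_threshold,
    )
    x = float(np.max(ratios)) if quantile == 1 else float(np.quantile(ratios, quantile, method="higher"))
    logger.info("estimate_x: %d masked pixels, quantile %.4g -> x = %.6g",
                ratios.size, quantile, x)
    return max(x, 0.0)


def estimate_y(
    controls: Sequence[ChannelStack],
    quantile: float = 0.999,
    mask_method: str = "otsu",
    *,
    smooth_sigma: float = 1.5,
    exclusion_radius_px: int = 12,
    mask_erosion_px: int = 2,
    fixed_hsp60_threshold: float | None = None,
    fixed_h2b_threshold: float | None = None,
) -> float:
    """Estimate the histone-H2B multiplier y from control images.

    Same rule as :func:`estimate_x` with the ratio ``dsDNA / H2B`` evaluated
    inside the nuclear (H2B-above-threshold) mask.
    """
    if not (0 < quantile <= 1):
        raise ValueError("quantile must lie in (0, 1]")
    ratios = _pooled_ratio(
        controls, "y", mask_method, smooth_sigma, exclusion_radius_px,
        mask_erosion_px, fixed_hsp60_threshold, fixed_h2b_threshold,
    )
    y = float(np.max(ratios)) if quantile == 1 else float(np.quantile(ratios, quantile, method="higher"))
    logger.info("estimate_y: %d masked pixels, quantile %.4g -> y = %.6g",
                ratios.size, quantile, y)
    return max(y, 0.0)


def estimate_factors(
    controls: Sequence[ChannelStack],
    quantile: float = 0.999,
    mask_method: str = "otsu",
    **kwargs,
) -> CalibrationFactors:
    """Estimate both factors from the pooled controls of one batch."""
    x = estimate_x(controls, quantile, mask_method, **kwargs)
    y = estimate_y(controls, quantile, mask_method, **kwargs)
    return CalibrationFactors(
        x=x, y=y, quantile=quantile,
        mito_mask_threshold_method=mask_method,
        n_control_images=len(controls),
    )


def verify_factors(
    controls: Sequence[ChannelStack],
    factors: CalibrationFactors,
    mask_method: str | None = None,
    *,
    smooth_sigma: float = 1.5,
    exclusion_radius_px: int = 12,
    mask_erosion_px: int = 2,
    fixed_hsp60_threshold: float | None = None,
    fixed_h2b_threshold: float | None = None,
) -> pd.DataFrame:
    """Check the defining property of the factors on control images.

    Returns a per-image report of the fraction of masked pixels whose residual
    (``dsDNA - x*Hsp60`` on the mitochondrial mask, ``dsDNA - y*H2B`` on the
    nuclear mask) is positive.  For factors estimated at ``quantile=1`` on the
    same controls every fraction is 0.  Residuals are evaluated on the same
    smoothed representation used for estimation; values within floating-point
    rounding of zero count as non-positive.
    """
    if len(controls) == 0:
        raise ValueError("need at least one control image")
    if mask_method is None:
        mask_method = factors.mito_mask_threshold_method
    rows = []
    for stack in controls:
        ds_s, h2b_s, hsp_s, mito_mask, nuclear_mask = _control_masks(
            stack, mask_method, smooth_sigma, exclusion_radius_px,
            mask_erosion_px, fixed_hsp60_threshold, fixed_h2b_threshold,
        )
        row: dict[str, object] = {"image_id": stack.image_id}
        for name, mask, denom, factor in (
            ("mito", mito_mask, hsp_s, factors.x),
            ("nuclear", nuclear_mask, h2b_s, factors.y),
        ):
            n = int(mask.sum())
            row[f"n_{name}_pixels"] = n
            if n == 0:
                row[f"frac_positive_{name}"] = np.nan
                continue
            residual = ds_s[mask] - factor * denom[mask]
            tol = _RESIDUAL_RTOL * (np.abs(ds_s[mask]) + factor * np.abs(denom[mask]))
            row[f"frac_positive_{name}"] = float(np.mean(residual > tol))
        rows.append(row)
    return pd.DataFrame(rows)
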