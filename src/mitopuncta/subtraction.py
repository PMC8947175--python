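"""The two subtraction variants and batch-consistent contrast adjustment.

Subtract-1 removes only the mitochondrial marker, ``dsDNA - x*Hsp60``;
Subtract-2 additionally removes the nuclear marker,
``dsDNA - x*Hsp60 - y*H2B``.  Negatives are clipped to zero (display-image
subtraction saturates at zero, and downstream thresholding assumes
non-negative input).  Contrast adjustment is a linear window shared across a
batch so all conditions are treated identically.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .calibration import CalibrationFactors
from .io import ChannelStack

VARIANTS = ("subtract1", "subtract2")


@dataclasses.dataclass
class SubtractedImage:
    values: np.ndarray
    variant: str
    factors_used: CalibrationFactors
    contrast_window: tuple[float, float] | None = None
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0:
            raise ValueError("subtracted values must be non-negative (clip first)")
        if self.contrast_window is not None:
            low, high = self.contrast_window
            if not low < high:
                raise ValueError(f"degenerate contrast window ({low}, {high})")


def _window_rescale(values: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ValueError(f"degenerate contrast window ({low}, {high})")
    return np.clip((values - low) / (high - low), 0.0, 1.0)


def subtract(
    stack: ChannelStack,
    factors: CalibrationFactors,
    variant: str = "subtract2",
    *,
    premultiply_window: tuple[float, float] | None = None,
) -> SubtractedImage:
    """Compute ``clip(dsDNA - x*Hsp60 [- y*H2B], 0)`` for one field.

    ``premultiply_window``, off by default, applies the contrast window to the
    multiplied marker image(s) *before* subtraction, for batches where the
    multiplication raises the background; when used it must be identical for
    every image of the batch.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if not (stack.dsdna.shape == stack.h2b.shape == stack.hsp60.shape):
        raise ValueError("channel shapes differ")  # defensive; ChannelStack enforces

    removed = factors.x * stack.hsp60
    if variant == "subtract2":
        removed = removed + factors.y * stack.h2b
    if premultiply_window is not None:
        removed = _window_rescale(removed, premultiply_window)
    values = np.clip(stack.dsdna - removed, 0.0, None)
    return SubtractedImage(
        values=values,
        variant=variant,
        factors_used=factors,
        contrast_window=None,
        source_image_id=stack.image_id,
    )


def apply_contrast(image: SubtractedImage, window: tuple[float, float]) -> SubtractedImage:
    """Linearly rescale values from ``[low, high]`` to ``[0, 1]``, clipping outside.

    The same window must be applied to every image of a batch (the CLI
    enforces this); the window used is recorded on the result.
    """
    values = _window_rescale(image.values, window)
    return SubtractedImage(
        values=values,
        variant=image.variant,
        factors_used=image.factors_used,
        contrast_window=(float(window[0]), float(window[1])),
        source_image_id=image.source_image_id,
    )


def auto_window(
    images: Sequence[SubtractedImage], upper_percentile: float = 99.9
) -> tuple[float, float]:
    """Batch-shared default window: (0, ``upper_percentile`` of pooled values)."""
    if len(images) == 0:
        raise ValueError("need at least one image to derive a window")
    pooled = np.concatenate([im.values.ravel() for im in images])
    high = float(np.percentile(pooled, upper_percentile))
    if high <= 0:
        high = float(pooled.max()) or 1.0
    return (0.0, high)
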