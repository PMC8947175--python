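"""Per-condition summaries and the two-group comparison.

The statistical unit is the per-image dots-per-cell ratio (one value per
field), never the individual punctum — matching a bar-of-means presentation
and avoiding pseudo-replication.  Groups are summarised as mean ± SEM and
compared with a classical two-sided Student's t-test (pooled variance);
Welch's correction is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import DetectionResult

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GroupSummary:
    """Mean ± SEM of per-image dots-per-cell ratios for one condition."""

    condition: str
    n_images: int
    mean_dots_per_cell: float
    sem_dots_per_cell: float  # NaN when n_images == 1
    values: list[float]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("a summary needs at least one image")


def summarize(
    results: Sequence[DetectionResult],
    condition_map: Mapping[str, str],
) -> tuple[list[GroupSummary], pd.DataFrame]:
    """Aggregate per-image results into per-condition summaries.

    Images whose ratio is undefined (no cells counted) are excluded from the
    means and tallied in ``n_excluded``.  Besides per-image means, the tidy
    table reports the pooled alternative (total puncta / total cells per
    condition) so both aggregation conventions are visible.

    Raises ``KeyError`` for any image_id missing from ``condition_map``.
    """
    groups: dict[str, dict] = {}
    for res in results:
        if res.image_id not in condition_map:
            raise KeyError(f"image {res.image_id!r} has no condition assigned")
        cond = condition_map[res.image_id]
        g = groups.setdefault(
            cond, {"values": [], "excluded": 0, "n_ectopic": 0, "n_cells": 0}
        )
        g["n_ectopic"] += res.n_ectopic
        g["n_cells"] += res.n_cells
        if res.dots_per_cell is None:
            g["excluded"] += 1
        else:
            g["values"].append(float(res.dots_per_cell))

    summaries = []
    rows = []
    for cond, g in groups.items():
        values = g["values"]
        if not values:
            logger.warning("condition %r has no image with a defined ratio", cond)
            continue
        n = len(values)
        mean = float(np.mean(values))
        sem = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        summaries.append(
            GroupSummary(
                condition=cond, n_images=n, mean_dots_per_cell=mean,
                sem_dots_per_cell=sem, values=values, n_excluded=g["excluded"],
            )
        )
        rows.append(
            {
                "condition": cond,
                "n_images": n,
                "n_excluded": g["excluded"],
                "mean_dots_per_cell": mean,
                "sem_dots_per_cell": sem,
                "pooled_dots_per_cell": (
                    g["n_ectopic"] / g["n_cells"] if g["n_cells"] else np.nan
                ),
            }
        )
    return summaries, pd.DataFrame(rows)


def _values(group: "GroupSummary | Sequence[float]") -> np.ndarray:
    if isinstance(group, GroupSummary):
        return np.asarray(group.values, dtype=np.float64)
    return np.asarray(list(group), dtype=np.float64)


def compare_groups(
    a: "GroupSummary | Sequence[float]",
    b: "GroupSummary | Sequence[float]",
    *,
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sample Student's t-test between two groups of per-image ratios.

    Returns ``(t, two-sided p, degrees of freedom)``.  The default is the
    classical pooled-variance test with ``n_a + n_b - 2`` degrees of freedom;
    ``welch=True`` drops the equal-variance assumption.

    Raises ``ValueError`` when either group has fewer than two values or when
    every value in both groups is identical (zero pooled variance — a p-value
    of 0 would be meaningless).
    """
    va, vb = _values(a), _values(b)
    if va.size < 2 or vb.size < 2:
        raise ValueError("each group needs at least two images with defined ratios")
    if np.ptp(va) == 0 and np.ptp(vb) == 0:
        raise ValueError("zero pooled variance: all values identical in both groups")
    result = sps.ttest_ind(va, vb, equal_var=not welch)
    return float(result.statistic), float(result.pvalue), float(result.df)


def plot_group_bars(
    summaries: Sequence[GroupSummary], path: str, *, ylabel: str = "ectopic mtDNA dots / cell"
) -> None:
    """Bar plot of group means with SEM error bars (one bar per condition)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1.5, 3.2))
    names = [s.condition for s in summaries]
    means = [s.mean_dots_per_cell for s in summaries]
    sems = [0.0 if np.isnan(s.sem_dots_per_cell) else s.sem_dots_per_cell for s in summaries]
    ax.bar(names, means, yerr=sems, capsize=4, color="0.7", edgecolor="black")
    for i, s in enumerate(summaries):
        ax.scatter([i] * len(s.values), s.values, s=12, color="black", zorder=3)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
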