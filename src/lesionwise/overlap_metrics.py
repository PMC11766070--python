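"""Whole-abnormal-volume evaluation.

Case-level voxelwise metrics between a detection mask A and a ground-truth
mask B:

    DSC        = 2|A∩B| / (|A| + |B|)
    sensitivity = TP / (TP + FN)     (recall)
    precision   = TP / (TP + FP)

plus cohort statistics, volume strata, and the GT-vs-detected volume
correlation. A metric whose denominator is zero is *undefined*, carried as
NaN, and excluded from every aggregate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid_io import BinaryMask, EvaluationConfig

__all__ = [
    "ConfusionCounts",
    "CaseMetrics",
    "CohortStats",
    "confusion_counts",
    "case_metrics",
    "volume_group_label",
    "volume_group_labels",
    "summarize",
    "cohort_stats",
    "stats_table",
    "grouped_metrics",
    "pooled_metrics",
    "volume_correlation",
]

METRIC_NAMES = ("dsc", "sensitivity", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise TP / FP / FN counts between detection and ground truth."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class CaseMetrics:
    case_id: str
    dsc: float
    sensitivity: float
    precision: float
    gt_volume_cm3: float
    detected_volume_cm3: float
    volume_group: str


@dataclass(frozen=True)
class CohortStats:
    """Summary statistics over the defined values of one metric."""

    mean: float
    std: float
    median: float
    q25: float
    q75: float
    min: float
    max: float
    n: int


def confusion_counts(gt: BinaryMask, det: BinaryMask) -> ConfusionCounts:
    """Exact voxelwise set counts; raises on geometry mismatch."""
    if not gt.grid.same_geometry(det.grid):
        raise ValueError(
            f"geometry mismatch: gt {gt.shape}/{gt.spacing} vs detection {det.shape}/{det.spacing}"
        )
    a = det.values
    b = gt.values
    tp = int(np.count_nonzero(a & b))
    return ConfusionCounts(tp=tp, fp=int(np.count_nonzero(a)) - tp, fn=int(np.count_nonzero(b)) - tp)


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def dsc_from_counts(counts: ConfusionCounts) -> float:
    return _ratio(2.0 * counts.tp, 2.0 * counts.tp + counts.fp + counts.fn)


def volume_group_label(volume_cm3: float, edges: Sequence[float]) -> str:
    """Stratum label for a case GT volume.

    With edges ``(e1, .., en)`` the strata are ``[0, e1)``, lower-inclusive
    interior intervals, ``[e_{n-1}, e_n]`` and ``(e_n, inf)`` — so with the
    default edges (10, 100): ``<10``, ``10-100`` (both edges in), ``>100``.
    """
    edges = tuple(edges)
    if volume_cm3 > edges[-1]:
        return f">{edges[-1]:g}"
    idx = int(np.searchsorted(edges, volume_cm3, side="right"))
    idx = min(idx, len(edges) - 1)
    if idx == 0:
        return f"<{edges[0]:g}"
    return f"{edges[idx - 1]:g}-{edges[idx]:g}"


def volume_group_labels(edges: Sequence[float]) -> list[str]:
    """All stratum labels in ascending volume order."""
    edges = tuple(edges)
    labels = [f"<{edges[0]:g}"]
    labels += [f"{edges[i]:g}-{edges[i + 1]:g}" for i in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g}")
    return labels


def case_metrics(
    counts: ConfusionCounts,
    gt: BinaryMask,
    det: BinaryMask,
    config: EvaluationConfig | None = None,
    case_id: str = "",
) -> CaseMetrics:
    config = config or EvaluationConfig()
    gt_cm3 = gt.volume_cm3
    return CaseMetrics(
        case_id=case_id,
        dsc=dsc_from_counts(counts),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        precision=_ratio(counts.tp, counts.tp + counts.fp),
        gt_volume_cm3=gt_cm3,
        detected_volume_cm3=det.volume_cm3,
        volume_group=volume_group_label(gt_cm3, config.volume_group_edges),
    )


def summarize(values: Iterable[float]) -> CohortStats:
    """Statistics over the defined (finite) values; NaNs are excluded.

    Quantiles use linear interpolation between order statistics; the
    standard deviation is the population one (a single case has std 0).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty value list")
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        nan = math.nan
        return CohortStats(nan, nan, nan, nan, nan, nan, nan, 0)
    return CohortStats(
        mean=float(arr.mean()),
        std=float(arr.std(ddof=0)),
        median=float(np.median(arr)),
        q25=float(np.quantile(arr, 0.25)),
        q75=float(np.quantile(arr, 0.75)),
        min=float(arr.min()),
        max=float(arr.max()),
        n=int(arr.size),
    )


def cohort_stats(metrics: Sequence[CaseMetrics]) -> dict[str, CohortStats]:
    if len(metrics) == 0:
        raise ValueError("cohort_stats needs at least one case")
    return {
        name: summarize(getattr(m, name) for m in metrics) for name in METRIC_NAMES
    }


_STAT_ROWS = (
    ("Mean", "mean"),
    ("STD", "std"),
    ("Median", "median"),
    ("25 Quant.", "q25"),
    ("75 Quant.", "q75"),
    ("Min.", "min"),
    ("Max.", "max"),
)


def stats_table(metrics: Sequence[CaseMetrics]) -> pd.DataFrame:
    """Cohort statistics as a table: statistic rows x metric columns."""
    stats_by_metric = cohort_stats(metrics)
    data = {
        metric: [getattr(stats_by_metric[metric], attr) for _, attr in _STAT_ROWS]
        for metric in METRIC_NAMES
    }
    return pd.DataFrame(data, index=[label for label, _ in _STAT_ROWS])


def grouped_metrics(
    metrics: Sequence[CaseMetrics], config: EvaluationConfig | None = None
) -> dict[str, dict[str, CohortStats] | None]:
    """Cohort statistics per volume stratum (per-case averaging).

    Empty strata map to ``None``. For a voxel-pooled alternative compute
    :func:`pooled_metrics` over each stratum's confusion counts.
    """
    if len(metrics) == 0:
        raise ValueError("grouped_metrics needs at least one case")
    config = config or EvaluationConfig()
    out: dict[str, dict[str, CohortStats] | None] = {}
    for label in volume_group_labels(config.volume_group_edges):
        members = [m for m in metrics if m.volume_group == label]
        out[label] = cohort_stats(members) if members else None
    return out


def pooled_metrics(counts: Iterable[ConfusionCounts]) -> tuple[float, float, float]:
    """DSC, sensitivity, precision from voxel-pooled confusion counts."""
    tp = fp = fn = 0
    for c in counts:
        tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
    return (
        _ratio(2.0 * tp, 2.0 * tp + fp + fn),
        _ratio(tp, tp + fn),
        _ratio(tp, tp + fp),
    )


def volume_correlation(
    gt_volumes: Sequence[float], det_volumes: Sequence[float], method: str = "pearson"
) -> float:
    """Correlation between GT and detected case volumes; NaN when undefined."""
    x = np.asarray(gt_volumes, dtype=float)
    y = np.asarray(det_volumes, dtype=float)
    if x.shape != y.shape:
        raise ValueError("volume lists must have equal length")
    if x.size < 2:
        raise ValueError("correlation needs at least two cases")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "pearson":
            r = stats.pearsonr(x, y).statistic
        elif method == "spearman":
            r = stats.spearmanr(x, y).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    return float(r)
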