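"""Single-component (lesion-wise) evaluation.

Connected components are extracted independently from the ground-truth and
detection masks. Each component's DSC is computed against the *union of all
opposite-side components that share at least one voxel with it* — remote
components never influence the score, and no one-to-one assignment is
enforced (a single detection may render several GT components Found, and
the two sides are classified independently by the same rule).

Categories, with the default thresholds:

    found   DSC >= 0.5   ("Found GT" / "Good Detection")
    partial 0.05 <= DSC < 0.5
    missed  DSC < 0.05   (GT side: false negative; detection side: false positive)

Boundaries are inclusive exactly as written above; a component with no
overlapping counterpart scores DSC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import BinaryMask, EvaluationConfig

__all__ = [
    "CATEGORIES",
    "ComponentSet",
    "OverlapGraph",
    "ComponentRecord",
    "extract_components",
    "overlap_graph",
    "component_dsc",
    "categorize",
    "classify_components",
    "category_table",
    "threshold_sweep",
    "sweep_from_values",
    "display_category",
]

CATEGORIES = ("found", "partial", "missed")

_DISPLAY = {
    ("gt", "found"): "Found GT",
    ("gt", "partial"): "Partially Found GT",
    ("gt", "missed"): "Missed GT",
    ("detection", "found"): "Good Detection",
    ("detection", "partial"): "Partially Good Detection",
    ("detection", "missed"): "Missed Detection",
}


def display_category(side: str, category: str) -> str:
    """Field name of a category, e.g. ('gt', 'found') -> 'Found GT'."""
    return _DISPLAY[(side, category)]


@dataclass(frozen=True)
class ComponentSet:
    """Integer-labelled partition of a binary mask into connected components.

    ``labels`` is 0 on background and k on component k; labels are assigned
    in scan order of each component's first voxel, so the labelling is
    deterministic. ``counts[k]`` is component k's voxel count
    (``counts[0] == 0``).
    """

    labels: np.ndarray
    n_components: int
    connectivity: int
    spacing: tuple[float, float, float]
    counts: np.ndarray

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volumes_mm3(self) -> np.ndarray:
        """Per-label physical volume; index 0 is background (0)."""
        return self.counts * self.voxel_volume_mm3

    def component_mask(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.n_components:
            raise ValueError(f"label {label} outside 1..{self.n_components}")
        return self.labels == label

    def same_geometry(self, other: "ComponentSet") -> bool:
        return self.labels.shape == other.labels.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass(frozen=True)
class OverlapGraph:
    """Bipartite overlap edges between GT and detection components.

    Parallel arrays: edge e connects GT component ``gt_labels[e]`` with
    detection component ``det_labels[e]`` sharing ``shared[e]`` voxels
    (> 0). The sum of ``shared`` equals the whole-volume TP count.
    """

    gt_labels: np.ndarray
    det_labels: np.ndarray
    shared: np.ndarray
    n_gt: int
    n_det: int

    @property
    def total_shared(self) -> int:
        return int(self.shared.sum())


@dataclass(frozen=True)
class ComponentRecord:
    side: str  # "gt" or "detection"
    label: int
    n_voxels: int
    volume_mm3: float
    counterpart_union_voxels: int
    shared_voxels: int
    dsc: float
    category: str


def extract_components(mask: BinaryMask, connectivity: int = 26) -> ComponentSet:
    """Label connected components under the 6- or 26-neighbor rule."""
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    raw, n = ndimage.label(mask.values, structure=structure)
    labels = _relabel_scan_order(raw, n)
    counts = np.bincount(labels.ravel(), minlength=n + 1).astype(np.int64)
    counts[0] = 0
    return ComponentSet(
        labels=labels,
        n_components=int(n),
        connectivity=connectivity,
        spacing=mask.spacing,
        counts=counts,
    )


def _relabel_scan_order(labels: np.ndarray, n: int) -> np.ndarray:
    """Renumber labels by first occurrence in C scan order."""
    if n == 0:
        return labels.astype(np.int64)
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    keep = uniq > 0
    order = np.argsort(first[keep], kind="stable")
    mapping = np.zeros(n + 1, dtype=np.int64)
    mapping[uniq[keep][order]] = np.arange(1, n + 1)
    return mapping[labels]


def overlap_graph(gt_cs: ComponentSet, det_cs: ComponentSet) -> OverlapGraph:
    """Exact shared-voxel counts for every overlapping (gt, det) label pair."""
    if not gt_cs.same_geometry(det_cs):
        raise ValueError("component sets live on different grids")
    both = (gt_cs.labels > 0) & (det_cs.labels > 0)
    g = gt_cs.labels[both].astype(np.int64)
    d = det_cs.labels[both].astype(np.int64)
    width = det_cs.n_components + 1
    pair_counts = np.bincount(g * width + d, minlength=0)
    nz = np.flatnonzero(pair_counts)
    return OverlapGraph(
        gt_labels=nz // width,
        det_labels=nz % width,
        shared=pair_counts[nz].astype(np.int64),
        n_gt=gt_cs.n_components,
        n_det=det_cs.n_components,
    )


def _dsc_arrays(graph: OverlapGraph, gt_counts: np.ndarray, det_counts: np.ndarray):
    """Per-label DSC for both sides (index 0 unused, set to 0)."""

    def one_side(own_labels, other_labels, own_counts, other_counts, n_own):
        shared = np.bincount(own_labels, weights=graph.shared, minlength=n_own + 1)
        union = np.bincount(
            own_labels, weights=other_counts[other_labels], minlength=n_own + 1
        )
        dsc = np.zeros(n_own + 1, dtype=float)
        has = union > 0
        dsc[has] = 2.0 * shared[has] / (own_counts[has] + union[has])
        return dsc

    gt_dsc = one_side(graph.gt_labels, graph.det_labels, gt_counts, det_counts, graph.n_gt)
    det_dsc = one_side(graph.det_labels, graph.gt_labels, det_counts, gt_counts, graph.n_det)
    return gt_dsc, det_dsc


def component_dsc(
    cs: ComponentSet, label: int, graph: OverlapGraph, other_cs: ComponentSet
) -> float:
    """DSC of one component against the union of its overlapping counterparts.

    2·|comp ∩ union| / (|comp| + |union|); 0 when nothing overlaps.
    """
    own_is_gt = cs.n_components == graph.n_gt and other_cs.n_components == graph.n_det
    if own_is_gt:
        own_lab, other_lab = graph.gt_labels, graph.det_labels
    else:
        own_lab, other_lab = graph.det_labels, graph.gt_labels
    sel = own_lab == label
    if not sel.any():
        return 0.0
    shared = int(graph.shared[sel].sum())
    union = int(other_cs.counts[other_lab[sel]].sum())
    return 2.0 * shared / (int(cs.counts[label]) + union)


def categorize(dsc: float, config: EvaluationConfig | None = None) -> str:
    config = config or EvaluationConfig()
    if dsc >= config.tau_found:
        return "found"
    if dsc >= config.tau_partial:
        return "partial"
    return "missed"


def classify_components(
    gt_cs: ComponentSet,
    det_cs: ComponentSet,
    graph: OverlapGraph,
    config: EvaluationConfig | None = None,
) -> tuple[list[ComponentRecord], list[ComponentRecord]]:
    """Classify every component on both sides; sides are independent."""
    config = config or EvaluationConfig()
    gt_dsc, det_dsc = _dsc_arrays(graph, gt_cs.counts, det_cs.counts)

    def records(side, cs, dsc_arr, own_labels, other_labels, other_counts):
        shared = np.bincount(own_labels, weights=graph.shared, minlength=cs.n_components + 1)
        union = np.bincount(
            own_labels, weights=other_counts[other_labels], minlength=cs.n_components + 1
        )
        voxvol = cs.voxel_volume_mm3
        return [
            ComponentRecord(
                side=side,
                label=lab,
                n_voxels=int(cs.counts[lab]),
                volume_mm3=float(cs.counts[lab]) * voxvol,
                counterpart_union_voxels=int(union[lab]),
                shared_voxels=int(shared[lab]),
                dsc=float(dsc_arr[lab]),
                category=categorize(float(dsc_arr[lab]), config),
            )
            for lab in range(1, cs.n_components + 1)
        ]

    gt_records = records("gt", gt_cs, gt_dsc, graph.gt_labels, graph.det_labels, det_cs.counts)
    det_records = records(
        "detection", det_cs, det_dsc, graph.det_labels, graph.gt_labels, gt_cs.counts
    )
    return gt_records, det_records


def category_table(records: Sequence[ComponentRecord]) -> pd.DataFrame:
    """Per-category count, % of components and % of side volume, + total row.

    Percentages are raw floats; round to one decimal at rendering time.
    """
    if len(records) == 0:
        raise ValueError("category_table needs at least one component record")
    total_n = len(records)
    total_vol = sum(r.volume_mm3 for r in records)
    rows = {}
    for cat in CATEGORIES:
        members = [r for r in records if r.category == cat]
        vol = sum(r.volume_mm3 for r in members)
        rows[cat] = {
            "n": len(members),
            "pct_components": 100.0 * len(members) / total_n,
            "pct_volume": 100.0 * vol / total_vol if total_vol else float("nan"),
            "volume_mm3": vol,
        }
    rows["total"] = {
        "n": total_n,
        "pct_components": 100.0,
        "pct_volume": 100.0 if total_vol else float("nan"),
        "volume_mm3": total_vol,
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def sweep_from_values(
    gt_dsc: np.ndarray,
    gt_volumes_mm3: np.ndarray,
    det_dsc: np.ndarray,
    det_volumes_mm3: np.ndarray,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Counts and cumulative volumes of components with DSC >= tau, per tau."""
    thresholds = [float(t) for t in thresholds]
    if any(not (0.0 < t <= 1.0) for t in thresholds) or thresholds != sorted(set(thresholds)):
        raise ValueError("sweep thresholds must be strictly increasing in (0, 1]")
    gt_dsc = np.asarray(gt_dsc, dtype=float)
    det_dsc = np.asarray(det_dsc, dtype=float)
    gt_vol = np.asarray(gt_volumes_mm3, dtype=float)
    det_vol = np.asarray(det_volumes_mm3, dtype=float)
    rows = []
    for tau in thresholds:
        g = gt_dsc >= tau
        d = det_dsc >= tau
        rows.append(
            {
                "threshold": tau,
                "gt_count": int(g.sum()),
                "gt_volume_mm3": float(gt_vol[g].sum()),
                "det_count": int(d.sum()),
                "det_volume_mm3": float(det_vol[d].sum()),
            }
        )
    return pd.DataFrame(rows)


def threshold_sweep(
    gt_cs: ComponentSet,
    det_cs: ComponentSet,
    graph: OverlapGraph,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Fig.-6-style DSC-threshold sweep for a single case."""
    gt_dsc, det_dsc = _dsc_arrays(graph, gt_cs.counts, det_cs.counts)
    return sweep_from_values(
        gt_dsc[1:], gt_cs.volumes_mm3[1:], det_dsc[1:], det_cs.volumes_mm3[1:], thresholds
    )
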