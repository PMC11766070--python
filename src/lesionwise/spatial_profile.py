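"""Positional analysis of components relative to the brain center.

Offsets are signed physical displacements (mm) of a component's
voxel-count centroid from the brain center, following the package's fixed
orientation convention: +X = left, +Y = anterior, +Z = superior. Half-brain
percentage differences use

    100 * (N_positive - N_negative) / (N_positive + N_negative)

per axis and category; components sitting exactly on the dividing plane
belong to neither half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_io import AXIS_NAMES, BinaryMask
from .component_engine import ComponentSet

__all__ = [
    "BrainCenter",
    "PositionRecord",
    "brain_center",
    "component_centroids",
    "component_offsets",
    "half_brain_differences",
    "axis_histograms",
]


@dataclass(frozen=True)
class BrainCenter:
    center_mm: np.ndarray  # (3,) physical coordinates


@dataclass(frozen=True)
class PositionRecord:
    side: str
    label: int
    category: str
    offset_mm: np.ndarray  # (3,) signed


def brain_center(brain: BinaryMask, mode: str = "centroid") -> BrainCenter:
    """Center of the brain mask: tissue centroid (default) or bbox center."""
    idx = np.argwhere(brain.values)
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    spacing = np.asarray(brain.spacing)
    if mode == "centroid":
        center = idx.mean(axis=0) * spacing
    elif mode == "bbox":
        center = (idx.min(axis=0) + idx.max(axis=0)) / 2.0 * spacing
    else:
        raise ValueError(f"unknown brain-center mode {mode!r}")
    return BrainCenter(center_mm=center)


def component_centroids(cs: ComponentSet) -> np.ndarray:
    """(n_components+1, 3) voxel-count centroids in mm; row 0 is NaN."""
    out = np.full((cs.n_components + 1, 3), np.nan)
    if cs.n_components == 0:
        return out
    idx = np.argwhere(cs.labels > 0)
    labs = cs.labels[cs.labels > 0]
    sums = np.zeros((cs.n_components + 1, 3))
    np.add.at(sums, labs, idx)
    counts = cs.counts.astype(float)[:, None]
    out[1:] = sums[1:] / counts[1:] * np.asarray(cs.spacing)
    return out


def component_offsets(
    cs: ComponentSet,
    center: BrainCenter,
    categories: Mapping[int, str] | None = None,
    side: str = "gt",
) -> list[PositionRecord]:
    """Per-component centroid minus brain center, in mm."""
    centroids = component_centroids(cs)
    categories = categories or {}
    return [
        PositionRecord(
            side=side,
            label=lab,
            category=categories.get(lab, ""),
            offset_mm=centroids[lab] - center.center_mm,
        )
        for lab in range(1, cs.n_components + 1)
    ]


def half_brain_differences(records: Sequence[PositionRecord]) -> pd.DataFrame:
    """Per axis and category: counts per half and their percentage difference.

    Rows are (axis, side, category); `pct_diff` is NaN when a category has
    no off-plane component on that axis (undefined, reported as such).
    """
    rows = []
    keys = sorted({(r.side, r.category) for r in records})
    for axis_i, axis in enumerate(AXIS_NAMES):
        for side, cat in keys:
            offs = np.array(
                [r.offset_mm[axis_i] for r in records if r.side == side and r.category == cat]
            )
            n_pos = int(np.count_nonzero(offs > 0))
            n_neg = int(np.count_nonzero(offs < 0))
            total = n_pos + n_neg
            rows.append(
                {
                    "axis": axis,
                    "side": side,
                    "category": cat,
                    "n_positive": n_pos,
                    "n_negative": n_neg,
                    "pct_diff": 100.0 * (n_pos - n_neg) / total if total else math.nan,
                }
            )
    return pd.DataFrame(rows)


def axis_histograms(
    records: Sequence[PositionRecord], bin_width_mm: float = 10.0
) -> pd.DataFrame:
    """Binned per-axis offset counts, bins centered on 0.

    Bin k covers [k*w - w/2, k*w + w/2); the row key is the bin center k*w.
    Per-category bin totals equal the category's record count.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin width must be positive")
    rows = []
    keys = sorted({(r.side, r.category) for r in records})
    for axis_i, axis in enumerate(AXIS_NAMES):
        for side, cat in keys:
            offs = np.array(
                [r.offset_mm[axis_i] for r in records if r.side == side and r.category == cat]
            )
            bins = np.floor(offs / bin_width_mm + 0.5).astype(int)
            for b, count in zip(*np.unique(bins, return_counts=True)):
                rows.append(
                    {
                        "axis": axis,
                        "side": side,
                        "category": cat,
                        "bin_center_mm": float(b) * bin_width_mm,
                        "count": int(count),
                    }
                )
    return pd.DataFrame(rows, columns=["axis", "side", "category", "bin_center_mm", "count"])
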