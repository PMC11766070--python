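"""Intensity-difference analysis against a healthy white-matter VOI.

For a component with mean intensity m and a healthy reference VOI with
mean v (same modality), the intensity difference is

    ID = 100 * (m - v) / v   [percent]

ID is invariant under a pure positive rescaling of the modality but *not*
under affine maps with an offset — so it matters whether it is computed
before or after the 12-bit stretch. The toolkit computes it on the grids as
given (post-stretch when the stretch is enabled upstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid_io import BinaryMask, VoxelGrid
from .component_engine import ComponentSet

__all__ = [
    "VOIStats",
    "voi_stats",
    "component_mean",
    "intensity_difference",
    "intensity_records",
    "volume_intensity_table",
]


@dataclass(frozen=True)
class VOIStats:
    modality: str
    mean: float
    n_voxels: int


def voi_stats(voi: BinaryMask, modality: VoxelGrid, name: str = "") -> VOIStats:
    """Arithmetic mean of the modality over the healthy-VOI voxels."""
    if not voi.grid.same_geometry(modality):
        raise ValueError("VOI and modality grids have different geometry")
    n = voi.n_voxels
    if n == 0:
        raise ValueError("healthy VOI is empty")
    return VOIStats(modality=name, mean=float(modality.values[voi.values].mean()), n_voxels=n)


def component_mean(cs: ComponentSet, label: int, modality: VoxelGrid) -> float:
    if cs.labels.shape != modality.shape:
        raise ValueError("component set and modality grids have different shapes")
    return float(modality.values[cs.labels == label].mean())


def intensity_difference(component_mean_value: float, voi: VOIStats) -> float:
    """Percent deviation of a component mean from the VOI mean (signed)."""
    if voi.mean == 0:
        return math.nan
    return 100.0 * (component_mean_value - voi.mean) / voi.mean


def intensity_records(
    cs: ComponentSet,
    modalities: Mapping[str, VoxelGrid],
    voi: BinaryMask,
    side: str = "gt",
) -> pd.DataFrame:
    """Long-form table: one row per (component, modality) with mean and ID."""
    rows = []
    labels = np.arange(1, cs.n_components + 1)
    for name, grid in modalities.items():
        stats = voi_stats(voi, grid, name)
        if cs.n_components:
            means = ndimage.mean(grid.values, labels=cs.labels, index=labels)
        else:
            means = []
        for lab, m in zip(labels, means):
            rows.append(
                {
                    "side": side,
                    "label": int(lab),
                    "modality": name,
                    "mean_intensity": float(m),
                    "voi_mean": stats.mean,
                    "id_percent": intensity_difference(float(m), stats),
                }
            )
    return pd.DataFrame(
        rows, columns=["side", "label", "modality", "mean_intensity", "voi_mean", "id_percent"]
    )


def volume_intensity_table(joined: pd.DataFrame) -> pd.DataFrame:
    """Joint volume-vs-ID summary per (side, category, modality).

    Expects the long-form join of component records with intensity records:
    columns ``side, category, modality, volume_mm3, id_percent``. Emits ID
    range, ID inter-decile range, volume range and the member count.
    """
    required = {"side", "category", "modality", "volume_mm3", "id_percent"}
    missing = required - set(joined.columns)
    if missing:
        raise ValueError(f"joined table is missing columns: {sorted(missing)}")
    if len(joined) == 0:
        raise ValueError("volume_intensity_table needs a non-empty join")

    def _agg(g: pd.DataFrame) -> pd.Series:
        ids = g["id_percent"].to_numpy(dtype=float)
        vols = g["volume_mm3"].to_numpy(dtype=float)
        defined = ids[np.isfinite(ids)]
        return pd.Series(
            {
                "n": len(g),
                "id_min": defined.min() if defined.size else math.nan,
                "id_max": defined.max() if defined.size else math.nan,
                "id_p10": float(np.quantile(defined, 0.10)) if defined.size else math.nan,
                "id_p90": float(np.quantile(defined, 0.90)) if defined.size else math.nan,
                "volume_min_mm3": float(vols.min()),
                "volume_max_mm3": float(vols.max()),
            }
        )

    out = (
        joined.groupby(["side", "category", "modality"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
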