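"""Voxel-grid data model, NIfTI I/O, intensity normalization, run configuration.

All volumes are handled on one fixed anatomical orientation: axis 0 (X)
increases toward the anatomical *left*, axis 1 (Y) toward *anterior*
(front), axis 2 (Z) toward *superior* (upper) — "LAS". Files are reoriented
on load using their NIfTI affine, so the sign conventions used by the
positional analyses are deterministic regardless of how the input volumes
were stored on disk.

The framework is strictly 3D: 2D inputs are rejected rather than promoted,
because connected components, centroid offsets, and volumes are all defined
volumetrically here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AXIS_NAMES",
    "AXIS_POSITIVE_DIRECTION",
    "TWELVE_BIT_MAX",
    "VoxelGrid",
    "BinaryMask",
    "EvaluationConfig",
    "CaseBundle",
    "read_grid",
    "read_mask",
    "write_grid",
    "write_mask",
    "stretch_to_12bit",
    "validate_bundle",
    "read_manifest",
    "load_case",
    "iter_manifest_bundles",
]

AXIS_NAMES = ("X", "Y", "Z")
#: anatomical direction in which each axis index (and offset sign) increases
AXIS_POSITIVE_DIRECTION = ("left", "anterior", "superior")

TWELVE_BIT_MAX = 4095.0

#: manifest columns that are not modality paths
_RESERVED_MANIFEST_COLUMNS = ("case_id", "gt", "detection", "brain", "voi")


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar lattice with per-axis voxel spacing in millimetres.

    The physical coordinate of voxel index ``(i, j, k)`` is
    ``(i*sx, j*sy, k*sz)`` (voxel-center convention).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(
                f"expected a 3D volume, got {values.ndim}D with shape {values.shape}"
            )
        if min(values.shape) < 1:
            raise ValueError(f"every axis must have at least one voxel, got {values.shape}")
        spacing = tuple(float(s) for s in np.atleast_1d(np.asarray(self.spacing, dtype=float)))
        if len(spacing) != 3 or any(not math.isfinite(s) or s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be three positive numbers, got {self.spacing!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean VoxelGrid with voxel count and physical volume."""

    grid: VoxelGrid

    def __post_init__(self) -> None:
        if self.grid.values.dtype != bool:
            object.__setattr__(self, "grid", replace(self.grid, values=self.grid.values.astype(bool)))

    @classmethod
    def from_array(cls, values: np.ndarray, spacing) -> "BinaryMask":
        return cls(VoxelGrid(np.asarray(values).astype(bool), spacing))

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.grid.values))

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("1", "true", "yes", "on"):
        return True
    if t in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"cannot interpret {text!r} as a boolean")


@dataclass
class EvaluationConfig:
    """Tunable parameters of the evaluation.

    tau_found / tau_partial
        Per-component DSC thresholds: a component is *Found* (GT side) /
        *Good* (detection side) when its DSC >= tau_found, *Partially
        Found/Good* when tau_partial <= DSC < tau_found, and *Missed*
        below tau_partial. Defaults 0.5 and 0.05.
    connectivity
        Voxel neighborhood for component labeling: 6 (faces) or 26
        (faces+edges+corners, the default).
    volume_group_edges
        Case-level GT-volume strata boundaries in cm^3; the defaults split
        cases into <10, 10-100 (both edges inclusive) and >100 cm^3.
    sweep_thresholds
        DSC thresholds for the sweep curves; default 0.05..0.95 step 0.05.
    histogram_bin_mm
        Bin width of the positional axis histograms; bins are centered on 0.
    brain_center_mode
        "centroid" (geometric center of brain tissue, default) or "bbox"
        (bounding-box center).
    correlation_method
        "pearson" (default) or "spearman" for the GT-vs-detected volume
        correlation.
    apply_stretch
        If true, modality volumes are stretched to the 12-bit range before
        any intensity analysis; leave false when inputs are already
        normalized.
    """

    tau_found: float = 0.5
    tau_partial: float = 0.05
    connectivity: int = 26
    volume_group_edges: tuple[float, ...] = (10.0, 100.0)
    sweep_thresholds: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 20))
    histogram_bin_mm: float = 10.0
    brain_center_mode: str = "centroid"
    correlation_method: str = "pearson"
    apply_stretch: bool = False

    def __post_init__(self) -> None:
        self.volume_group_edges = tuple(float(e) for e in self.volume_group_edges)
        self.sweep_thresholds = tuple(float(t) for t in self.sweep_thresholds)
        if not (0.0 < self.tau_partial < self.tau_found <= 1.0):
            raise ValueError(
                f"need 0 < tau_partial < tau_found <= 1, got {self.tau_partial}, {self.tau_found}"
            )
        if self.connectivity not in (6, 26):
            raise ValueError(f"connectivity must be 6 or 26, got {self.connectivity}")
        edges = self.volume_group_edges
        if len(edges) < 1 or any(e <= 0 for e in edges) or list(edges) != sorted(set(edges)):
            raise ValueError(f"volume_group_edges must be positive and strictly increasing: {edges}")
        th = self.sweep_thresholds
        if len(th) == 0 or any(not (0.0 < t <= 1.0) for t in th) or list(th) != sorted(set(th)):
            raise ValueError(f"sweep thresholds must be strictly increasing in (0, 1]: {th}")
        if self.histogram_bin_mm <= 0:
            raise ValueError("histogram_bin_mm must be positive")
        if self.brain_center_mode not in ("centroid", "bbox"):
            raise ValueError(f"brain_center_mode must be 'centroid' or 'bbox', got {self.brain_center_mode!r}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError(f"correlation_method must be 'pearson' or 'spearman'")

    @classmethod
    def from_file(cls, path) -> "EvaluationConfig":
        """Read ``key = value`` overrides from a plain-text config file."""
        kwargs: dict = {}
        field_types = {f.name: f for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in field_types:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            if key in ("volume_group_edges", "sweep_thresholds"):
                kwargs[key] = tuple(float(v) for v in value.replace(",", " ").split())
            elif key == "connectivity":
                kwargs[key] = int(value)
            elif key == "apply_stretch":
                kwargs[key] = _parse_bool(value)
            elif key in ("brain_center_mode", "correlation_method"):
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "tau_found": self.tau_found,
            "tau_partial": self.tau_partial,
            "connectivity": self.connectivity,
            "volume_group_edges": list(self.volume_group_edges),
            "sweep_thresholds": list(self.sweep_thresholds),
            "histogram_bin_mm": self.histogram_bin_mm,
            "brain_center_mode": self.brain_center_mode,
            "correlation_method": self.correlation_method,
            "apply_stretch": self.apply_stretch,
        }


@dataclass
class CaseBundle:
    """All co-registered volumes of one examination."""

    gt: BinaryMask
    detection: BinaryMask
    brain: BinaryMask
    healthy_voi: BinaryMask
    modalities: Mapping[str, VoxelGrid]
    case_id: str = ""

    def members(self) -> Iterator[tuple[str, VoxelGrid]]:
        yield "gt", self.gt.grid
        yield "detection", self.detection.grid
        yield "brain", self.brain.grid
        yield "healthy_voi", self.healthy_voi.grid
        for name, grid in self.modalities.items():
            yield name, grid


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_las(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS+
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not math.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing in header: {zooms}")
    # RAS -> LAS: flip the X axis so index growth points to anatomical left
    data = np.ascontiguousarray(data[::-1])
    return data, zooms


def read_grid(path) -> VoxelGrid:
    """Read a NIfTI scalar volume, reoriented to the LAS convention."""
    data, zooms = _load_las(path)
    return VoxelGrid(data.astype(np.float64, copy=False), zooms)


def read_mask(path, threshold: float = 0.5) -> BinaryMask:
    """Read a NIfTI volume and binarize it at ``value > threshold``.

    The default threshold of 0.5 tolerates interpolation residue in masks
    that were resampled at some point of their life.
    """
    data, zooms = _load_las(path)
    return BinaryMask.from_array(data > threshold, zooms)


def _write_las(values: np.ndarray, spacing, path) -> None:
    data = np.ascontiguousarray(values[::-1])  # LAS -> RAS
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_grid(grid: VoxelGrid, path, dtype=np.float32) -> None:
    _write_las(grid.values.astype(dtype), grid.spacing, path)


def write_mask(mask: BinaryMask, path) -> None:
    _write_las(mask.grid.values.astype(np.uint8), mask.grid.spacing, path)


# ---------------------------------------------------------------------------
# Intensity normalization


def stretch_to_12bit(grid: VoxelGrid) -> VoxelGrid:
    """Linearly map the grid's [min, max] onto the 12-bit range [0, 4095].

    Constant grids map to all zeros (there is no contrast to stretch).
    """
    values = grid.values.astype(np.float64)
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax == vmin:
        return replace(grid, values=np.zeros_like(values))
    # divide before scaling: a subnormal range must not overflow to inf
    stretched = (values - vmin) / (vmax - vmin) * TWELVE_BIT_MAX
    return replace(grid, values=stretched)


# ---------------------------------------------------------------------------
# Bundle validation and manifests


def validate_bundle(bundle: CaseBundle) -> list[str]:
    """Return a list of violated bundle invariants (empty list = valid)."""
    problems: list[str] = []
    ref = bundle.gt.grid
    for name, grid in bundle.members():
        if grid.shape != ref.shape:
            problems.append(f"{name}: shape {grid.shape} differs from gt {ref.shape}")
        if not np.allclose(grid.spacing, ref.spacing):
            problems.append(f"{name}: spacing {grid.spacing} differs from gt {ref.spacing}")
    if not problems:
        voi = bundle.healthy_voi.values
        outside = int(np.count_nonzero(voi & ~bundle.brain.values))
        if outside:
            problems.append(f"healthy_voi: {outside} voxels outside the brain mask")
        overlap = int(np.count_nonzero(voi & bundle.gt.values))
        if overlap:
            problems.append(f"healthy_voi: overlaps gt by {overlap} voxels")
    return problems


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest (delimited text, header row).

    Required columns: ``case_id, gt, detection, brain, voi``; every further
    column is treated as a modality name whose cells hold volume paths.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _RESERVED_MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required columns: {missing}")
    modalities = [c for c in df.columns if c not in _RESERVED_MANIFEST_COLUMNS]
    if not modalities:
        raise ValueError(f"manifest {path} lists no modality columns")
    return df


def load_case(row: Mapping, root=None, threshold: float = 0.5) -> CaseBundle:
    """Load one manifest row into a CaseBundle. Paths resolve against root."""
    base = Path(root) if root is not None else Path(".")

    def _p(cell) -> Path:
        p = Path(str(cell))
        return p if p.is_absolute() else base / p

    modalities = {
        name: read_grid(_p(row[name]))
        for name in row.keys()
        if name not in _RESERVED_MANIFEST_COLUMNS
    }
    return CaseBundle(
        gt=read_mask(_p(row["gt"]), threshold),
        detection=read_mask(_p(row["detection"]), threshold),
        brain=read_mask(_p(row["brain"]), threshold),
        healthy_voi=read_mask(_p(row["voi"]), threshold),
        modalities=modalities,
        case_id=str(row["case_id"]),
    )


def iter_manifest_bundles(
    manifest: pd.DataFrame, root=None, threshold: float = 0.5
) -> Iterator[tuple[str, "CaseBundle | None", str | None]]:
    """Yield ``(case_id, bundle, error)`` per manifest row; errors don't raise."""
    for _, row in manifest.iterrows():
        case_id = str(row["case_id"])
        try:
            yield case_id, load_case(row, root=root, threshold=threshold), None
        except Exception as exc:  # noqa: BLE001 - skip-and-warn contract
            yield case_id, None, f"{type(exc).__name__}: {exc}"
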