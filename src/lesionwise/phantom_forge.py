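"""Seeded synthetic phantom generator.

Produces complete CaseBundles with known truth for every downstream
statistic: a spherical "brain", ellipsoidal lesions with controllable
volume, position and per-modality intensity contrast, detection masks
perturbed to requested per-component DSC values, spurious (false-positive)
detection components, and a healthy reference VOI placed analytically at
maximal distance from every lesion.

Lesion realization. A lesion with target volume V is voxelized as the N
closest voxels to its center under the ellipsoid norm (N = V / voxel
volume, stable scan-order tie-breaks), which lands the realized volume
within half a voxel of the target and the centroid within a fraction of a
voxel of the requested position. A detection perturbed toward target DSC t
takes a *nested* prefix (shrink) or superset (grow) of the same ordering:
for a shrink of n_det voxels inside n GT voxels the component DSC is
exactly 2·n_det/(n + n_det), so n_det is solved from t in closed form and
the realized DSC differs from the plan only by count granularity. The whole
construction is a pure function of the spec, so one seed gives bit-identical
bundles.

Intensities. Modality grids are background-level inside the brain, zero
outside, and background·(1 + ID/100) on each lesion, with the healthy VOI
untouched — so the planned ID is realized exactly before noise, and
Gaussian noise (masks stay clean) shrinks the measurement error as lesion
volume grows. Grids are emitted on a 12-bit-like scale and are meant to be
evaluated without re-stretching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_io import BinaryMask, CaseBundle, VoxelGrid, write_grid, write_mask

__all__ = [
    "PerturbationPlan",
    "LesionSpec",
    "FalsePositiveSpec",
    "PhantomSpec",
    "CohortTemplate",
    "generate_bundle",
    "generate_cohort",
    "write_cohort",
    "truth_with_labels",
]

DEFAULT_MODALITIES = ("flair", "t2", "t1ce")


@dataclass(frozen=True)
class PerturbationPlan:
    """How the detection counterpart of a lesion is derived from its GT.

    target_dsc None (with zero translation) means an exact copy; drop=True
    suppresses the detection entirely (a planned Missed GT).
    """

    target_dsc: float | None = None
    grow: bool = False
    translation_vox: tuple[int, int, int] = (0, 0, 0)
    drop: bool = False

    def __post_init__(self) -> None:
        if self.target_dsc is not None and not (0.0 < self.target_dsc <= 1.0):
            raise ValueError(f"target_dsc must be in (0, 1], got {self.target_dsc}")


@dataclass(frozen=True)
class LesionSpec:
    volume_mm3: float
    offset_mm: tuple[float, float, float]
    intensity_diffs: Mapping[str, float] = field(default_factory=dict)
    semi_axes_mm: tuple[float, float, float] | None = None  # None = sphere
    plan: PerturbationPlan = field(default_factory=PerturbationPlan)


@dataclass(frozen=True)
class FalsePositiveSpec:
    volume_mm3: float
    offset_mm: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius_mm: float = 42.0
    lesions: tuple[LesionSpec, ...] = ()
    false_positives: tuple[FalsePositiveSpec, ...] = ()
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    background: float = 1000.0
    noise_sigma: float = 0.0
    voi_radius_mm: float = 8.0
    seed: int = 0
    case_id: str = "phantom"


def _grid_center_mm(shape, spacing) -> np.ndarray:
    return (np.asarray(shape, dtype=float) - 1.0) / 2.0 * np.asarray(spacing, dtype=float)


def _ball(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    axes = [
        (np.arange(shape[i]) * spacing[i] - center_mm[i]) ** 2 for i in range(3)
    ]
    d2 = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    return d2 <= radius_mm**2 + 1e-9


def _ordered_voxels(shape, spacing, center_mm, semi_axes_mm, n: int) -> np.ndarray:
    """Indices (n, 3) of the n voxels closest to center under the ellipsoid
    norm, ordered by distance with stable global-scan-order tie-breaks.

    The ordering is a function of the center and semi-axes only, so a
    request for fewer/more voxels at the same center yields a strict
    prefix/superset — the property the DSC-targeted perturbation relies on.
    """
    shape = np.asarray(shape)
    spacing = np.asarray(spacing, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    axes_mm = np.asarray(semi_axes_mm, dtype=float)
    voxvol = float(np.prod(spacing))
    base_vol = 4.0 / 3.0 * math.pi * float(np.prod(axes_mm))
    scale = (max(n, 1) * voxvol / base_vol) ** (1.0 / 3.0)
    for attempt in range(8):
        radii = axes_mm * scale * (1.3 + 0.3 * attempt) + 2.0 * spacing
        lo = np.maximum(np.floor((center - radii) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((center + radii) / spacing).astype(int), shape - 1)
        coords = [np.arange(lo[i], hi[i] + 1) for i in range(3)]
        u = [
            ((coords[i] * spacing[i] - center[i]) / axes_mm[i]) ** 2 for i in range(3)
        ]
        u2 = u[0][:, None, None] + u[1][None, :, None] + u[2][None, None, :]
        if u2.size < n:
            if np.all(lo == 0) and np.all(hi == shape - 1):
                raise ValueError(f"cannot place {n} voxels: grid too small")
            scale *= 1.5
            continue
        # must not be truncated by the bbox: the n-th best distance has to
        # beat the best distance excluded by the box on any clipped face
        order = np.argsort(u2.ravel(), kind="stable")[:n]
        worst = float(u2.ravel()[order[-1]])
        clipped = False
        for i in range(3):
            # a voxel just beyond a non-boundary bbox face must be farther
            # than the worst voxel we kept, else the bbox truncated the set
            lo_excl = ((lo[i] - 1) * spacing[i] - center[i]) / axes_mm[i]
            hi_excl = ((hi[i] + 1) * spacing[i] - center[i]) / axes_mm[i]
            if lo[i] > 0 and lo_excl**2 <= worst:
                clipped = True
            if hi[i] < shape[i] - 1 and hi_excl**2 <= worst:
                clipped = True
        if clipped:
            scale *= 1.4
            continue
        local = np.stack(np.unravel_index(order, u2.shape), axis=1)
        return local + lo
    raise ValueError("could not voxelize lesion within the grid")


def _semi_axes(lesion: LesionSpec, spacing) -> np.ndarray:
    if lesion.semi_axes_mm is not None:
        return np.asarray(lesion.semi_axes_mm, dtype=float)
    r = (3.0 * lesion.volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return np.full(3, max(r, float(min(spacing)) / 2.0))


def _det_count(n: int, plan: PerturbationPlan) -> int:
    t = plan.target_dsc
    if t is None or t >= 1.0:
        return n
    if plan.grow:
        return max(n, int(round(n * (2.0 - t) / t)))
    return int(min(n, max(1, round(n * t / (2.0 - t)))))


def generate_bundle(spec: PhantomSpec) -> tuple[CaseBundle, pd.DataFrame]:
    """Realize a PhantomSpec into a CaseBundle plus its truth table.

    Raises ValueError for unrealizable specs: lesions outside the brain,
    lesions (or detections) that merge into fewer connected components than
    planned, or no room left for a disjoint healthy VOI.
    """
    from . import component_engine as ce  # local import to avoid cycles

    shape = tuple(int(s) for s in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    voxvol = float(np.prod(spacing))
    center = _grid_center_mm(shape, spacing)

    brain = _ball(shape, spacing, center, spec.brain_radius_mm)
    if not brain.any():
        raise ValueError("brain sphere does not intersect the grid")

    gt = np.zeros(shape, dtype=bool)
    det = np.zeros(shape, dtype=bool)
    lesion_voxels: list[np.ndarray] = []
    det_voxels: list[np.ndarray | None] = []
    rows: list[dict] = []

    for li, lesion in enumerate(spec.lesions, start=1):
        axes_mm = _semi_axes(lesion, spacing)
        lcenter = center + np.asarray(lesion.offset_mm, dtype=float)
        reach = float(np.linalg.norm(lesion.offset_mm)) + float(axes_mm.max())
        if reach > spec.brain_radius_mm + max(spacing):
            raise ValueError(
                f"lesion {li} (reach {reach:.1f} mm) extends outside the "
                f"{spec.brain_radius_mm:.1f} mm brain radius"
            )
        n = max(1, int(round(lesion.volume_mm3 / voxvol)))
        plan = lesion.plan
        n_det = 0 if plan.drop else _det_count(n, plan)
        n_order = max(n, n_det)
        ordered = _ordered_voxels(shape, spacing, lcenter, axes_mm, n_order)
        g_idx = ordered[:n]
        gt[tuple(g_idx.T)] = True
        lesion_voxels.append(g_idx)

        d_idx: np.ndarray | None = None
        if not plan.drop:
            d_idx = ordered[:n_det]
            tvec = np.asarray(plan.translation_vox, dtype=int)
            if tvec.any():
                d_idx = d_idx + tvec
                if (d_idx < 0).any() or (d_idx >= np.asarray(shape)).any():
                    raise ValueError(f"lesion {li}: translated detection leaves the grid")
            det[tuple(d_idx.T)] = True
        det_voxels.append(d_idx)

        if d_idx is None:
            realized_dsc = 0.0
        else:
            g_set = set(map(tuple, g_idx))
            shared = sum(1 for v in map(tuple, d_idx) if v in g_set)
            realized_dsc = 2.0 * shared / (len(g_idx) + len(d_idx))
        if plan.drop:
            planned_cat = "missed"
        else:
            planned_cat = ce.categorize(realized_dsc)
        centroid = g_idx.mean(axis=0) * np.asarray(spacing)
        row = {
            "case_id": spec.case_id,
            "component_id": li,
            "kind": "lesion",
            "planned_category": planned_cat,
            "target_dsc": math.nan if plan.drop else (plan.target_dsc if plan.target_dsc is not None else 1.0),
            "realized_dsc": realized_dsc,
            "target_volume_mm3": lesion.volume_mm3,
            "realized_volume_mm3": n * voxvol,
            "n_voxels": n,
            "dropped": plan.drop,
            "offset_x_mm": centroid[0] - center[0],
            "offset_y_mm": centroid[1] - center[1],
            "offset_z_mm": centroid[2] - center[2],
        }
        for mod in spec.modalities:
            row[f"id_{mod}"] = float(lesion.intensity_diffs.get(mod, 0.0))
        rows.append(row)

    if np.count_nonzero(gt & ~brain):
        raise ValueError("lesion voxels fall outside the brain mask")

    fp_voxels: list[np.ndarray] = []
    for fi, fp in enumerate(spec.false_positives, start=1):
        fcenter = center + np.asarray(fp.offset_mm, dtype=float)
        r = (3.0 * fp.volume_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        n = max(1, int(round(fp.volume_mm3 / voxvol)))
        idx = _ordered_voxels(shape, spacing, fcenter, np.full(3, max(r, min(spacing) / 2)), n)
        det[tuple(idx.T)] = True
        fp_voxels.append(idx)
        centroid = idx.mean(axis=0) * np.asarray(spacing)
        row = {
            "case_id": spec.case_id,
            "component_id": len(spec.lesions) + fi,
            "kind": "false_positive",
            "planned_category": "missed",  # detection-side false positive
            "target_dsc": 0.0,
            "realized_dsc": 0.0,
            "target_volume_mm3": fp.volume_mm3,
            "realized_volume_mm3": n * voxvol,
            "n_voxels": n,
            "dropped": False,
            "offset_x_mm": centroid[0] - center[0],
            "offset_y_mm": centroid[1] - center[1],
            "offset_z_mm": centroid[2] - center[2],
        }
        for mod in spec.modalities:
            row[f"id_{mod}"] = math.nan
        rows.append(row)

    # components must not merge: the spec's lesion list is the truth
    gt_cs = ce.extract_components(BinaryMask.from_array(gt, spacing), 26)
    if gt_cs.n_components != len(spec.lesions):
        raise ValueError(
            f"unrealizable spec: {len(spec.lesions)} lesions merge into "
            f"{gt_cs.n_components} GT components"
        )
    n_det_expected = sum(1 for d in det_voxels if d is not None) + len(fp_voxels)
    det_cs = ce.extract_components(BinaryMask.from_array(det, spacing), 26)
    if det_cs.n_components != n_det_expected:
        raise ValueError(
            f"unrealizable spec: expected {n_det_expected} detection components, "
            f"got {det_cs.n_components}"
        )

    voi = _place_voi(spec, shape, spacing, center, brain, gt, det, lesion_voxels + fp_voxels)

    rng = np.random.default_rng(spec.seed)
    modalities: dict[str, VoxelGrid] = {}
    for mod in spec.modalities:
        arr = np.zeros(shape, dtype=np.float64)
        arr[brain] = spec.background
        for lesion, g_idx in zip(spec.lesions, lesion_voxels):
            contrast = float(lesion.intensity_diffs.get(mod, 0.0))
            arr[tuple(g_idx.T)] = spec.background * (1.0 + contrast / 100.0)
        if spec.noise_sigma > 0:
            arr = arr + rng.normal(0.0, spec.noise_sigma, size=shape)
        modalities[mod] = VoxelGrid(arr, spacing)

    bundle = CaseBundle(
        gt=BinaryMask.from_array(gt, spacing),
        detection=BinaryMask.from_array(det, spacing),
        brain=BinaryMask.from_array(brain, spacing),
        healthy_voi=voi,
        modalities=modalities,
        case_id=spec.case_id,
    )
    columns = list(rows[0].keys()) if rows else [
        "case_id", "component_id", "kind", "planned_category", "target_dsc",
        "realized_dsc", "target_volume_mm3", "realized_volume_mm3", "n_voxels",
        "dropped", "offset_x_mm", "offset_y_mm", "offset_z_mm",
    ]
    return bundle, pd.DataFrame(rows, columns=columns)


def _place_voi(spec, shape, spacing, center, brain, gt, det, blobs) -> BinaryMask:
    """Spherical healthy VOI at maximal clearance from every lesion/FP."""
    spacing_arr = np.asarray(spacing, dtype=float)
    margin = spec.voi_radius_mm + float(spacing_arr.max())
    stride = 2
    cand_idx = np.argwhere(brain[::stride, ::stride, ::stride]) * stride
    cand_mm = cand_idx * spacing_arr
    keep = np.linalg.norm(cand_mm - center, axis=1) <= spec.brain_radius_mm - margin
    cand_mm = cand_mm[keep]
    if cand_mm.size == 0:
        raise ValueError("brain too small to host the healthy VOI")
    score = np.full(len(cand_mm), np.inf)
    for idx in blobs:
        bc = idx.mean(axis=0) * spacing_arr
        reach = float(np.linalg.norm(idx * spacing_arr - bc, axis=1).max()) if len(idx) else 0.0
        score = np.minimum(score, np.linalg.norm(cand_mm - bc, axis=1) - reach)
    best = cand_mm[int(np.argmax(score))]
    voi = _ball(shape, spacing, best, spec.voi_radius_mm) & brain
    if np.count_nonzero(voi & (gt | det)):
        raise ValueError("no room for a healthy VOI disjoint from all components")
    return BinaryMask.from_array(voi, spacing)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class CohortTemplate:
    """Randomized-cohort conditions (see docs/methods.md for rationale).

    Volumes are drawn log-uniformly. Category assignment mirrors the
    clinical pattern the framework is built to expose: components above
    ``found_volume_cutoff_mm3`` are always planned Found (models detect the
    big ones), while smaller components split between Partially Found and
    Missed in the proportion implied by ``category_probs`` — so Found
    components span every volume, Missed and Partial concentrate at small
    volumes, and most of the total volume is detected. Lesions too small to
    hold an intermediate DSC target at voxel-count granularity (below
    ``min_perturb_voxels``) degrade their plan to exact-copy (Found) or
    drop (Missed); the truth table records the degraded plan.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_radius_mm: float = 42.0
    n_lesions_range: tuple[int, int] = (3, 12)
    volume_range_mm3: tuple[float, float] = (1.0, 3.0e4)
    category_probs: tuple[float, float, float] = (0.49, 0.27, 0.24)  # found/partial/missed
    found_volume_cutoff_mm3: float = 200.0
    found_dsc_range: tuple[float, float] = (0.65, 0.95)
    partial_dsc_range: tuple[float, float] = (0.12, 0.42)
    grow_fraction: float = 0.3
    min_perturb_voxels: int = 30
    n_fp_range: tuple[int, int] = (1, 6)
    fp_volume_range_mm3: tuple[float, float] = (1.0, 100.0)
    id_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"flair": (25.0, 65.0), "t2": (0.0, 70.0), "t1ce": (-30.0, 20.0)}
    )
    background: float = 1000.0
    noise_sigma: float = 0.0
    voi_radius_mm: float = 8.0


def _log_uniform(rng, lo, hi) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sample_case(rng: np.random.Generator, t: CohortTemplate, case_id: str, seed: int) -> PhantomSpec:
    spacing = np.asarray(t.spacing, dtype=float)
    voxvol = float(np.prod(spacing))
    placed: list[tuple[np.ndarray, float]] = []  # (offset, reach)
    margin = 2.0 * float(spacing.max())

    def place(reach: float) -> np.ndarray | None:
        max_r = t.brain_radius_mm - reach - margin
        if max_r <= 0:
            return None
        for _ in range(60):
            direction = rng.normal(size=3)
            norm = np.linalg.norm(direction)
            if norm == 0:
                continue
            offset = direction / norm * max_r * rng.random() ** (1.0 / 3.0)
            ok = all(
                np.linalg.norm(offset - prev) >= reach + prev_reach + margin
                for prev, prev_reach in placed
            )
            if ok:
                return offset
        return None

    lesions: list[LesionSpec] = []
    n_lesions = int(rng.integers(t.n_lesions_range[0], t.n_lesions_range[1] + 1))
    for _ in range(n_lesions):
        volume = _log_uniform(rng, *t.volume_range_mm3)
        if volume > t.found_volume_cutoff_mm3:
            cat = "found"
        else:
            p_partial = t.category_probs[1] / (t.category_probs[1] + t.category_probs[2])
            cat = "partial" if rng.random() < p_partial else "missed"
        ids = {m: float(rng.uniform(lo, hi)) for m, (lo, hi) in t.id_ranges.items()}
        for _shrink in range(6):
            n_vox = max(1, int(round(volume / voxvol)))
            if n_vox < t.min_perturb_voxels and cat == "partial":
                cat = "found" if rng.random() < 0.5 else "missed"
            if cat == "missed":
                plan = PerturbationPlan(drop=True)
            elif n_vox < t.min_perturb_voxels:  # found, tiny: exact copy
                plan = PerturbationPlan()
            else:
                rng_lo, rng_hi = t.found_dsc_range if cat == "found" else t.partial_dsc_range
                target = float(rng.uniform(rng_lo, rng_hi))
                grow = bool(rng.random() < t.grow_fraction)
                plan = PerturbationPlan(target_dsc=target, grow=grow)
            r_gt = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
            reach = r_gt
            if plan.target_dsc is not None and plan.grow:
                reach = r_gt * ((2.0 - plan.target_dsc) / plan.target_dsc) ** (1.0 / 3.0)
            offset = place(reach + float(spacing.max()))
            if offset is not None:
                placed.append((offset, reach + float(spacing.max())))
                lesions.append(
                    LesionSpec(
                        volume_mm3=volume,
                        offset_mm=tuple(offset),
                        intensity_diffs=ids,
                        plan=plan,
                    )
                )
                break
            volume /= 4.0  # could not fit: retry smaller

    fps: list[FalsePositiveSpec] = []
    n_fp = int(rng.integers(t.n_fp_range[0], t.n_fp_range[1] + 1))
    for _ in range(n_fp):
        volume = _log_uniform(rng, *t.fp_volume_range_mm3)
        r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        offset = place(r + float(spacing.max()))
        if offset is None:
            continue
        placed.append((offset, r + float(spacing.max())))
        fps.append(FalsePositiveSpec(volume_mm3=volume, offset_mm=tuple(offset)))

    return PhantomSpec(
        shape=t.shape,
        spacing=t.spacing,
        brain_radius_mm=t.brain_radius_mm,
        lesions=tuple(lesions),
        false_positives=tuple(fps),
        modalities=tuple(t.id_ranges.keys()),
        background=t.background,
        noise_sigma=t.noise_sigma,
        voi_radius_mm=t.voi_radius_mm,
        seed=seed,
        case_id=case_id,
    )


def generate_cohort(
    n_cases: int, template: CohortTemplate | None = None, seed: int = 0
) -> list[tuple[CaseBundle, pd.DataFrame]]:
    """Reproducible randomized cohort; same seed, same bundles."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    template = template or CohortTemplate()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cases):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _sample_case(rng, template, case_id=f"case{i + 1:03d}", seed=case_seed)
        out.append(generate_bundle(spec))
    return out


def write_cohort(cases: Sequence[tuple[CaseBundle, pd.DataFrame]], out_dir) -> Path:
    """Write NIfTI bundles, a combined truth table, and a manifest.

    Returns the manifest path; the manifest is directly loadable by
    :func:`lesionwise.grid_io.read_manifest`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truths = []
    for bundle, truth in cases:
        cdir = out / bundle.case_id
        cdir.mkdir(exist_ok=True)
        paths = {
            "gt": cdir / "gt.nii.gz",
            "detection": cdir / "detection.nii.gz",
            "brain": cdir / "brain.nii.gz",
            "voi": cdir / "voi.nii.gz",
        }
        write_mask(bundle.gt, paths["gt"])
        write_mask(bundle.detection, paths["detection"])
        write_mask(bundle.brain, paths["brain"])
        write_mask(bundle.healthy_voi, paths["voi"])
        row = {"case_id": bundle.case_id}
        row.update({k: str(p.relative_to(out)) for k, p in paths.items()})
        for mod, grid in bundle.modalities.items():
            p = cdir / f"{mod}.nii.gz"
            write_grid(grid, p)
            row[mod] = str(p.relative_to(out))
        manifest_rows.append(row)
        truths.append(truth)
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)
    pd.concat(truths, ignore_index=True).to_csv(out / "truth.csv", index=False)
    return manifest


def truth_with_labels(
    truth: pd.DataFrame, bundle: CaseBundle, connectivity: int = 26
) -> pd.DataFrame:
    """Attach the evaluated component labels to a case's truth rows.

    Each truth row is matched to the GT (lesions) or detection (false
    positives and non-dropped lesions) component whose labelled region
    contains the row's realized centroid.
    """
    from . import component_engine as ce
    from .spatial_profile import brain_center

    gt_cs = ce.extract_components(bundle.gt, connectivity)
    det_cs = ce.extract_components(bundle.detection, connectivity)
    center = brain_center(bundle.brain).center_mm
    spacing = np.asarray(bundle.gt.spacing)

    def lookup(labels: np.ndarray, offset) -> int:
        idx = np.round((np.asarray(offset, dtype=float) + center) / spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(labels.shape) - 1)
        lab = int(labels[tuple(idx)])
        if lab:
            return lab
        # centroid fell just outside (possible for thin shapes): search nearby
        for r in (1, 2, 3):
            lo = np.maximum(idx - r, 0)
            hi = np.minimum(idx + r + 1, labels.shape)
            window = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            nz = window[window > 0]
            if nz.size:
                return int(np.bincount(nz).argmax())
        return 0

    out = truth.copy()
    gt_labels, det_labels = [], []
    for _, row in out.iterrows():
        offset = (row["offset_x_mm"], row["offset_y_mm"], row["offset_z_mm"])
        if row["kind"] == "lesion":
            gt_labels.append(lookup(gt_cs.labels, offset))
            det_labels.append(0 if row.get("dropped", False) else lookup(det_cs.labels, offset))
        else:
            gt_labels.append(0)
            det_labels.append(lookup(det_cs.labels, offset))
    out["gt_label"] = gt_labels
    out["det_label"] = det_labels
    return out
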