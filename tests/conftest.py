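"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np
import pytest

from lesionwise.grid_io import BinaryMask
from lesionwise.phantom_forge import (
    LesionSpec,
    PerturbationPlan,
    PhantomSpec,
    generate_bundle,
)


def mask_from_coords(coords, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    arr = np.zeros(shape, dtype=bool)
    for c in coords:
        arr[tuple(c)] = True
    return BinaryMask.from_array(arr, spacing)


def flood_fill_label(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """Brute-force BFS connected-component labelling (the labelling oracle).

    Labels are assigned in C scan order of each component's first voxel,
    matching the production convention so arrays compare equal directly.
    """
    if connectivity == 6:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if sum(abs(x) for x in d) == 1]
    else:
        neigh = [d for d in product((-1, 0, 1), repeat=3) if any(d)]
    labels = np.zeros(mask.shape, dtype=np.int64)
    n = 0
    for idx in np.ndindex(*mask.shape):
        if not mask[idx] or labels[idx]:
            continue
        n += 1
        queue = deque([idx])
        labels[idx] = n
        while queue:
            cur = queue.popleft()
            for d in neigh:
                nb = tuple(c + o for c, o in zip(cur, d))
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)):
                    if mask[nb] and not labels[nb]:
                        labels[nb] = n
                        queue.append(nb)
    return labels, n


def pairwise_overlap_oracle(gt_labels: np.ndarray, det_labels: np.ndarray) -> dict:
    """Exhaustive voxel-by-voxel shared-count oracle for the overlap graph."""
    counts: dict[tuple[int, int], int] = {}
    for idx in np.ndindex(*gt_labels.shape):
        g, d = int(gt_labels[idx]), int(det_labels[idx])
        if g and d:
            counts[(g, d)] = counts.get((g, d), 0) + 1
    return counts


@pytest.fixture(scope="session")
def three_lesion_bundle():
    """Deterministic phantom: found (DSC 0.7), partial (0.2), missed (drop)."""
    spec = PhantomSpec(
        lesions=(
            LesionSpec(
                volume_mm3=5000.0,
                offset_mm=(10.0, 5.0, -8.0),
                intensity_diffs={"flair": 40.0, "t2": 20.0, "t1ce": -10.0},
                plan=PerturbationPlan(target_dsc=0.7),
            ),
            LesionSpec(
                volume_mm3=300.0,
                offset_mm=(-15.0, -10.0, 12.0),
                intensity_diffs={"flair": 30.0, "t2": 10.0, "t1ce": 5.0},
                plan=PerturbationPlan(target_dsc=0.2),
            ),
            LesionSpec(
                volume_mm3=50.0,
                offset_mm=(0.0, 20.0, 5.0),
                intensity_diffs={"flair": 50.0, "t2": 35.0, "t1ce": -20.0},
                plan=PerturbationPlan(drop=True),
            ),
        ),
        seed=11,
        case_id="fixture3",
    )
    return generate_bundle(spec)


@pytest.fixture(scope="session")
def identity_bundle():
    """Phantom whose detection equals its GT exactly."""
    spec = PhantomSpec(
        lesions=(
            LesionSpec(volume_mm3=2000.0, offset_mm=(8.0, -6.0, 4.0),
                       intensity_diffs={"flair": 45.0}),
            LesionSpec(volume_mm3=120.0, offset_mm=(-14.0, 10.0, -10.0),
                       intensity_diffs={"flair": 30.0}),
        ),
        modalities=("flair",),
        seed=3,
        case_id="identity",
    )
    return generate_bundle(spec)
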