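"""Component extraction, overlap matching, per-component DSC,
classification, category tables, and the threshold sweep."""

import numpy as np
import pytest

from lesionwise.component_engine import (
    ComponentRecord,
    categorize,
    category_table,
    classify_components,
    component_dsc,
    extract_components,
    overlap_graph,
    sweep_from_values,
    threshold_sweep,
)
from lesionwise.grid_io import BinaryMask, EvaluationConfig

from conftest import flood_fill_label, mask_from_coords, pairwise_overlap_oracle


def components_of(coords_or_array, connectivity=26, shape=(8, 8, 8)):
    if isinstance(coords_or_array, np.ndarray):
        mask = BinaryMask.from_array(coords_or_array, (1, 1, 1))
    else:
        mask = mask_from_coords(coords_or_array, shape=shape)
    return extract_components(mask, connectivity)


class TestExtractComponents:
    def test_single_voxel(self):
        cs = components_of([(3, 3, 3)])
        assert cs.n_components == 1
        assert cs.counts[1] == 1

    def test_empty_mask(self):
        cs = components_of([])
        assert cs.n_components == 0

    def test_corner_touch_distinguishes_connectivity(self):
        coords = [(0, 0, 0), (1, 1, 1)]  # share only a cube corner
        assert components_of(coords, connectivity=26).n_components == 1
        assert components_of(coords, connectivity=6).n_components == 2

    def test_edge_touch_distinguishes_connectivity(self):
        coords = [(0, 0, 0), (1, 1, 0)]  # share only a cube edge
        assert components_of(coords, connectivity=26).n_components == 1
        assert components_of(coords, connectivity=6).n_components == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            components_of([(0, 0, 0)], connectivity=18)

    def test_labels_follow_scan_order(self):
        coords = [(5, 5, 5), (0, 0, 0)]  # two isolated voxels
        cs = components_of(coords)
        assert cs.labels[0, 0, 0] == 1
        assert cs.labels[5, 5, 5] == 2

    def test_matches_flood_fill_on_random_grids(self):
        rng = np.random.default_rng(42)
        for connectivity in (6, 26):
            for _ in range(25):
                arr = rng.random((5, 5, 5)) > 0.6
                cs = components_of(arr, connectivity)
                oracle_labels, oracle_n = flood_fill_label(arr, connectivity)
                assert cs.n_components == oracle_n
                assert np.array_equal(cs.labels, oracle_labels)


class TestOverlapGraph:
    def test_disjoint_sets_empty_graph(self):
        gt = components_of([(0, 0, 0)])
        det = components_of([(5, 5, 5)])
        g = overlap_graph(gt, det)
        assert len(g.shared) == 0
        assert g.total_shared == 0

    def test_one_detection_covering_two_gts(self):
        gt = components_of([(0, 0, 0), (4, 0, 0)])  # two isolated GT voxels
        det = components_of([(i, 0, 0) for i in range(5)])  # one long detection
        g = overlap_graph(gt, det)
        assert g.n_gt == 2 and g.n_det == 1
        assert sorted(zip(g.gt_labels, g.det_labels)) == [(1, 1), (2, 1)]

    def test_weights_match_exhaustive_pair_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.random((6, 6, 6)) > 0.55
            b = rng.random((6, 6, 6)) > 0.55
            gt = components_of(a)
            det = components_of(b)
            g = overlap_graph(gt, det)
            oracle = pairwise_overlap_oracle(gt.labels, det.labels)
            got = {
                (int(gl), int(dl)): int(s)
                for gl, dl, s in zip(g.gt_labels, g.det_labels, g.shared)
            }
            assert got == oracle

    def test_total_shared_equals_whole_volume_tp(self):
        rng = np.random.default_rng(8)
        a = rng.random((8, 8, 8)) > 0.5
        b = rng.random((8, 8, 8)) > 0.5
        g = overlap_graph(components_of(a), components_of(b))
        assert g.total_shared == int(np.count_nonzero(a & b))


class TestComponentDsc:
    def test_no_counterpart_scores_zero(self):
        gt = components_of([(0, 0, 0)])
        det = components_of([(5, 5, 5)])
        g = overlap_graph(gt, det)
        assert component_dsc(gt, 1, g, det) == 0.0

    def test_perfect_counterpart_scores_one(self):
        coords = [(i, 0, 0) for i in range(10)]
        gt = components_of(coords, shape=(12, 2, 2))
        det = components_of(coords, shape=(12, 2, 2))
        g = overlap_graph(gt, det)
        assert component_dsc(gt, 1, g, det) == 1.0

    def test_union_against_set_arithmetic(self):
        """GT of 8 voxels; overlapping detection union of 12 with 6 shared."""
        gt_coords = [(i, 0, 0) for i in range(8)]
        det_coords = [(i, 0, 0) for i in range(2, 8)] + [(i, 0, 2) for i in range(6)]
        gt = components_of(gt_coords)
        det = components_of(det_coords)
        assert det.n_components == 2
        g = overlap_graph(gt, det)
        # union = overlapping det component (6 voxels) only; remote one excluded
        assert component_dsc(gt, 1, g, det) == pytest.approx(2 * 6 / (8 + 6))

    def test_remote_components_do_not_distort(self):
        gt = components_of([(0, 0, 0), (0, 1, 0)])
        det_coords = [(0, 0, 0), (0, 1, 0)] + [(6, 6, 6), (6, 6, 7)]
        det = components_of(det_coords)
        g = overlap_graph(gt, det)
        assert component_dsc(gt, 1, g, det) == 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "dsc,category",
        [
            (0.5, "found"),  # boundary inclusive
            (0.5001, "found"),
            (0.4999, "partial"),
            (0.05, "partial"),  # lower boundary inclusive
            (0.049, "missed"),
            (0.0, "missed"),
            (1.0, "found"),
        ],
    )
    def test_threshold_boundaries(self, dsc, category):
        assert categorize(dsc, EvaluationConfig()) == category

    def test_both_sides_classified_independently(self):
        # one det covering two gt voxels and a stray FP
        gt = components_of([(0, 0, 0), (4, 0, 0)])
        det = components_of([(i, 0, 0) for i in range(5)] + [(7, 7, 7)])
        g = overlap_graph(gt, det)
        gt_recs, det_recs = classify_components(gt, det, g, EvaluationConfig())
        assert len(gt_recs) == 2 and len(det_recs) == 2
        # each gt voxel vs the 5-voxel det: dsc = 2/6
        assert all(r.dsc == pytest.approx(1 / 3) for r in gt_recs)
        assert {r.category for r in gt_recs} == {"partial"}
        fp = [r for r in det_recs if r.dsc == 0.0]
        assert len(fp) == 1 and fp[0].category == "missed"

    def test_category_partition_is_complete(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.random((8, 8, 8)) > 0.6
            b = rng.random((8, 8, 8)) > 0.6
            gt = components_of(a)
            det = components_of(b)
            g = overlap_graph(gt, det)
            gt_recs, det_recs = classify_components(gt, det, g)
            assert len(gt_recs) == gt.n_components
            assert len(det_recs) == det.n_components
            for recs in (gt_recs, det_recs):
                for r in recs:
                    assert r.category in ("found", "partial", "missed")

    def test_gt_component_without_edges_contributes_no_tp(self):
        gt = components_of([(0, 0, 0), (5, 5, 5)])
        det = components_of([(0, 0, 0)])
        g = overlap_graph(gt, det)
        gt_recs, _ = classify_components(gt, det, g)
        isolated = [r for r in gt_recs if r.dsc == 0.0]
        assert len(isolated) == 1
        assert isolated[0].shared_voxels == 0

    def test_classification_invariant_under_relabeling(self):
        """Permuting which lesion comes first in scan order must not change
        the multiset of (n_voxels, dsc, category)."""
        coords_a = [(0, 0, 0), (0, 0, 1)]
        coords_b = [(6, 6, 6)]
        det_coords = [(0, 0, 0), (6, 6, 6)]

        def run(gt_coords):
            gt = components_of(gt_coords)
            det = components_of(det_coords)
            g = overlap_graph(gt, det)
            recs, _ = classify_components(gt, det, g)
            return sorted((r.n_voxels, round(r.dsc, 9), r.category) for r in recs)

        assert run(coords_a + coords_b) == run(coords_b + coords_a)


class TestCategoryTable:
    def test_printed_count_percentages(self):
        """Percentages recomputed from the published component counts."""
        recs = (
            [ComponentRecord("gt", i, 1, 1.0, 0, 0, 0.9, "found") for i in range(423)]
            + [ComponentRecord("gt", i, 1, 1.0, 0, 0, 0.2, "partial") for i in range(235)]
            + [ComponentRecord("gt", i, 1, 1.0, 0, 0, 0.0, "missed") for i in range(209)]
        )
        table = category_table(recs)
        assert table.loc["total", "n"] == 867
        assert round(table.loc["found", "pct_components"], 1) == 48.8
        assert round(table.loc["partial", "pct_components"], 1) == 27.1
        assert round(table.loc["missed", "pct_components"], 1) == 24.1

    def test_all_found(self):
        recs = [ComponentRecord("gt", i, 1, 1.0, 0, 0, 1.0, "found") for i in range(5)]
        table = category_table(recs)
        assert table.loc["found", "pct_components"] == 100.0
        assert table.loc["partial", "n"] == 0
        assert table.loc["missed", "pct_volume"] == 0.0

    def test_volume_percentages_hand_summed(self):
        recs = [
            ComponentRecord("gt", 1, 10, 10.0, 0, 0, 0.9, "found"),
            ComponentRecord("gt", 2, 30, 30.0, 0, 0, 0.8, "found"),
            ComponentRecord("gt", 3, 60, 60.0, 0, 0, 0.0, "missed"),
        ]
        table = category_table(recs)
        assert table.loc["found", "pct_volume"] == pytest.approx(40.0)
        assert table.loc["missed", "pct_volume"] == pytest.approx(60.0)
        assert table.loc["total", "volume_mm3"] == pytest.approx(100.0)

    def test_counts_sum_to_total(self):
        recs = [
            ComponentRecord("gt", i, 1, 1.0, 0, 0, d, c)
            for i, (d, c) in enumerate(
                [(0.9, "found"), (0.3, "partial"), (0.0, "missed"), (0.7, "found")]
            )
        ]
        table = category_table(recs)
        assert (
            table.loc["found", "n"] + table.loc["partial", "n"] + table.loc["missed", "n"]
            == table.loc["total", "n"]
        )

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            category_table([])


class TestThresholdSweep:
    def _case(self):
        gt = components_of([(0, 0, 0), (0, 0, 1), (4, 0, 0), (7, 7, 7)])
        det = components_of([(0, 0, 0), (0, 0, 1), (4, 0, 0), (4, 0, 1)])
        g = overlap_graph(gt, det)
        return gt, det, g

    def test_low_threshold_counts_any_overlap(self):
        gt, det, g = self._case()
        sweep = threshold_sweep(gt, det, g, [0.01])
        # gt comp 3 has zero overlap: 2 of 3 gt comps counted
        assert sweep.loc[0, "gt_count"] == 2

    def test_tau_one_only_perfect(self):
        gt, det, g = self._case()
        sweep = threshold_sweep(gt, det, g, [1.0])
        assert sweep.loc[0, "gt_count"] == 1  # only the exactly-matched pair

    def test_counts_match_filter_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.random((8, 8, 8)) > 0.55
        b = rng.random((8, 8, 8)) > 0.55
        gt = components_of(a)
        det = components_of(b)
        g = overlap_graph(gt, det)
        gt_recs, det_recs = classify_components(gt, det, g)
        thresholds = [0.1, 0.3, 0.5, 0.7, 0.9]
        sweep = threshold_sweep(gt, det, g, thresholds)
        for i, tau in enumerate(thresholds):
            assert sweep.loc[i, "gt_count"] == sum(1 for r in gt_recs if r.dsc >= tau)
            assert sweep.loc[i, "det_count"] == sum(1 for r in det_recs if r.dsc >= tau)
            assert sweep.loc[i, "gt_volume_mm3"] == pytest.approx(
                sum(r.volume_mm3 for r in gt_recs if r.dsc >= tau)
            )

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(10)
        a = rng.random((8, 8, 8)) > 0.5
        b = rng.random((8, 8, 8)) > 0.5
        gt = components_of(a)
        det = components_of(b)
        g = overlap_graph(gt, det)
        sweep = threshold_sweep(gt, det, g, [round(0.05 * k, 2) for k in range(1, 20)])
        for col in ("gt_count", "det_count", "gt_volume_mm3", "det_volume_mm3"):
            assert (np.diff(sweep[col].to_numpy()) <= 1e-9).all()

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            sweep_from_values([0.5], [1.0], [0.5], [1.0], [0.5, 0.3])
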