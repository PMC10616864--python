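"""Motor-node extraction, masked degrees, ratios and hub identification."""

import numpy as np
import pytest

from hubshift import graph_metrics as gm
from hubshift import hub_analysis as ha
from hubshift.errors import ValidationError
from hubshift.types import BinaryNetwork, CentralityPanel, ConnectivityMatrix


def _cm(values, **kw):
    return ConnectivityMatrix(np.asarray(values, dtype=float), **kw)


def _panel(degree, timepoints=None):
    degree = np.asarray(degree, dtype=float)
    return CentralityPanel(
        degree,
        tuple(f"s{i}" for i in range(degree.shape[1])),
        timepoints or tuple(f"t{i}" for i in range(degree.shape[2])),
        0.1,
    )


class TestMotorExtraction:
    def test_either_seed_suffices(self):
        v = np.zeros((4, 4))
        v[0, 3] = v[3, 0] = 0.15   # left M1 - node 3
        v[1, 3] = v[3, 1] = 0.02   # right M1 - node 3
        v[1, 2] = v[2, 1] = 0.05
        mask = ha.extract_motor_nodes({"s0": _cm(v)}, (0, 1), 0.10)
        assert mask.subject_masks["s0"][3]
        assert not mask.subject_masks["s0"][2]
        # seeds always included in their own mask
        assert mask.subject_masks["s0"][0] and mask.subject_masks["s0"][1]

    def test_group_union_excludes_only_never_connected(self):
        v1, v2 = np.zeros((4, 4)), np.zeros((4, 4))
        v1[0, 2] = v1[2, 0] = 0.2
        v2[1, 3] = v2[3, 1] = 0.0  # node 3 below threshold in all subjects
        mask = ha.extract_motor_nodes({"a": _cm(v1), "b": _cm(v2)}, (0, 1), 0.10)
        assert mask.group_union[2]       # included via subject a
        assert not mask.group_union[3]

    def test_threshold_minus_one_includes_every_node(self):
        rng = np.random.default_rng(0)
        cms = {f"s{i}": _cm((lambda a: (a + a.T) / 2)(rng.uniform(-1, 1, (8, 8))))
               for i in range(3)}
        mask = ha.extract_motor_nodes(cms, (0, 1), -1.0)
        for m in mask.subject_masks.values():
            assert m.all()

    def test_synthetic_cohort_union_covers_all_nodes(self, desk_cohort):
        """Under the planted scenario every node clears the M1 threshold in at
        least one subject, so the whole parcellation enters the analysis."""
        cms = desk_cohort["cms"]
        pre = {c.subject_id: c for c in cms if c.timepoint == "pre"}
        seeds = desk_cohort["truth"].motor_hub_ids[:2]
        mask = ha.extract_motor_nodes(pre, tuple(seeds), 0.10)
        assert mask.group_union.sum() == desk_cohort["scenario"].n_nodes

    def test_seed_out_of_range(self):
        with pytest.raises(ValidationError):
            ha.extract_motor_nodes({"s": _cm(np.zeros((4, 4)))}, (0, 9), 0.1)


class TestMaskedDegree:
    def test_full_mask_identity(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-1, 1, (10, 10))
        bn = gm.binarize(_cm((a + a.T) / 2), 0.1)
        np.testing.assert_array_equal(
            ha.masked_degree_centrality(bn, np.ones(10, bool)),
            gm.degree_centrality(bn).astype(float))

    def test_star_without_center_is_edgeless(self):
        star = np.zeros((5, 5), bool)
        star[0, 1:] = star[1:, 0] = True
        bn = BinaryNetwork(star, 0.0)
        mask = np.array([False, True, True, True, True])
        deg = ha.masked_degree_centrality(bn, mask)
        assert np.isnan(deg[0])
        np.testing.assert_array_equal(deg[1:], 0.0)

    def test_matches_subgraph_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-1, 1, (15, 15))
        bn = gm.binarize(_cm((a + a.T) / 2), 0.0)
        mask = rng.random(15) < 0.6
        mask[0] = True
        deg = ha.masked_degree_centrality(bn, mask)
        for i in range(15):
            if not mask[i]:
                assert np.isnan(deg[i])
                continue
            expected = sum(1 for j in range(15)
                           if j != i and mask[j] and bn.adjacency[i, j])
            assert deg[i] == expected

    def test_all_false_mask_rejected(self):
        bn = BinaryNetwork(np.zeros((4, 4), bool), 0.0)
        with pytest.raises(ValidationError):
            ha.masked_degree_centrality(bn, np.zeros(4, bool))


class TestCentralityRatio:
    def test_halving_and_baseline_column(self):
        deg = np.zeros((31, 1, 2))
        deg[0, 0] = [30.0, 15.0]
        ratio = ha.centrality_ratio(_panel(deg), "t0")
        assert ratio[0, 0, 0] == 1.0
        assert ratio[0, 0, 1] == 0.5

    def test_zero_baseline_flagged(self):
        deg = np.zeros((6, 1, 2))
        deg[0, 0] = [0.0, 5.0]
        deg[1, 0] = [4.0, 2.0]
        ratio = ha.centrality_ratio(_panel(deg), "t0")
        assert np.isnan(ratio[0, 0]).all()
        assert ratio[1, 0, 1] == 0.5

    def test_null_cohort_mean_ratio_near_one(self):
        from hubshift.connectivity import cohort_connectivity
        from hubshift.synthetic import null_scenario, simulate_cohort
        sessions, _ = simulate_cohort(null_scenario(seed=3))
        cms = cohort_connectivity(sessions)
        panel = gm.build_centrality_panel(cms, 0.10)
        ratio = ha.centrality_ratio(panel, "pre")
        mean_final = np.nanmean(ratio[:, :, 1])
        assert mean_final == pytest.approx(1.0, abs=0.1)


class TestHighCentrality:
    def test_single_outlier_selected(self):
        rng = np.random.default_rng(4)
        deg = 50 + rng.integers(-1, 2, (120, 6, 1)).astype(float)
        deg[7] = 100.0
        hubs = ha.high_centrality_nodes(_panel(deg), "t0", k=2)
        assert hubs.node_ids == (7,)
        assert hubs.cutoff < 100

    def test_uniform_panel_empty(self):
        deg = np.full((10, 4, 1), 5.0)
        with pytest.warns(UserWarning):
            hubs = ha.high_centrality_nodes(_panel(deg), "t0", k=2)
        assert hubs.node_ids == ()

    def test_invariant_to_node_reordering(self):
        rng = np.random.default_rng(5)
        deg = rng.integers(5, 20, (25, 5, 1)).astype(float)
        deg[[3, 11]] = 24.0
        panel = _panel(deg)
        perm = rng.permutation(25)
        permuted = _panel(deg[perm])
        hubs = ha.high_centrality_nodes(panel, "t0", 2)
        hubs_p = ha.high_centrality_nodes(permuted, "t0", 2)
        mapped = sorted(int(np.flatnonzero(perm == i)[0]) for i in hubs.node_ids)
        assert sorted(hubs_p.node_ids) == mapped

    def test_planted_hubs_recovered(self, desk_cohort):
        panel = desk_cohort["panel"]
        truth = desk_cohort["truth"]
        base = ha.high_centrality_nodes(panel, "pre", 2)
        final = ha.high_centrality_nodes(panel, "14wpi", 2)
        assert base.jaccard(truth.motor_hub_ids) >= 0.8
        assert final.jaccard(truth.subcortical_hub_ids) >= 0.8


class TestHubShiftReport:
    def test_static_panel_identical_sets_no_decline(self):
        rng = np.random.default_rng(6)
        base = rng.integers(10, 40, (60, 5)).astype(float)
        base[4] = 58  # one stable hub
        deg = np.stack([base, base], axis=2)
        report = ha.hub_shift_report(_panel(deg, ("pre", "14wpi")),
                                     "pre", "14wpi")
        assert report.baseline_hubs == report.final_hubs
        assert not report.baseline_declines and not report.final_declines

    def test_shift_cohort_report(self, desk_cohort):
        report = ha.hub_shift_report(desk_cohort["panel"], "pre", "14wpi")
        truth = desk_cohort["truth"]
        assert set(report.baseline_hubs) & set(truth.motor_hub_ids)
        assert report.baseline_declines
        assert not report.final_declines

    def test_json_round_trip(self, desk_cohort, tmp_path):
        report = ha.hub_shift_report(desk_cohort["panel"], "pre", "14wpi")
        p = tmp_path / "report.json"
        report.to_json(p)
        back = ha.HubShiftReport.from_json(p)
        assert back == report
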