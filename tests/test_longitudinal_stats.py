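"""Change matrices, paired tests and the mixed ANOVA vs hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hubshift import graph_metrics as gm
from hubshift import longitudinal_stats as ls
from hubshift.errors import InsufficientDataError, ShapeError, ValidationError
from hubshift.types import CentralityPanel, ConnectivityMatrix


def _cm(values, **kw):
    return ConnectivityMatrix(np.asarray(values, dtype=float), **kw)


def _random_cm(rng, n):
    a = rng.uniform(-1, 1, (n, n))
    return _cm((a + a.T) / 2)


def _panel(degree, subjects=None, timepoints=None, threshold=0.1):
    degree = np.asarray(degree, dtype=float)
    subjects = subjects or tuple(f"s{i}" for i in range(degree.shape[1]))
    timepoints = timepoints or tuple(f"t{i}" for i in range(degree.shape[2]))
    return CentralityPanel(degree, tuple(subjects), tuple(timepoints), threshold)


class TestChangeMatrix:
    def test_zero_when_identical(self):
        rng = np.random.default_rng(0)
        cm = _random_cm(rng, 6)
        d = ls.change_matrix(cm, cm)
        assert np.nanmax(np.abs(d.values)) == 0.0

    def test_entrywise_difference(self):
        a = _cm([[0, 0.30], [0.30, 0]])
        b = _cm([[0, 0.45], [0.45, 0]])
        assert ls.change_matrix(a, b).values[0, 1] == pytest.approx(-0.15)

    def test_strength_linearity(self):
        rng = np.random.default_rng(1)
        a, b = _random_cm(rng, 9), _random_cm(rng, 9)
        d = ls.change_matrix(a, b)
        iu = np.triu_indices(9, 1)
        assert d.values[iu].sum() == pytest.approx(
            gm.strength(a) - gm.strength(b), abs=1e-9)

    def test_telescoping(self):
        rng = np.random.default_rng(2)
        a, b, c = (_random_cm(rng, 7) for _ in range(3))
        lhs = ls.change_matrix(a, c).values
        rhs = ls.change_matrix(a, b).values + ls.change_matrix(b, c).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_shape_mismatch(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ShapeError):
            ls.change_matrix(_random_cm(rng, 5), _random_cm(rng, 6))


class TestStrengthDelta:
    def test_hand_mean_and_sem(self):
        wide = pd.DataFrame({"pre": [10.0, 10.0], "14wpi": [11.0, 13.0]},
                            index=["a", "b"])
        out = ls.strength_delta_series(wide, "vs_baseline", "pre")
        row = out[out.timepoint == "14wpi"].iloc[0]
        assert row.mean_delta == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0)

    def test_reference_self_is_zero(self):
        wide = pd.DataFrame({"pre": [3.0, 4.0, 5.0]}, index=list("abc"))
        wide["1wpi"] = wide["pre"]
        out = ls.strength_delta_series(wide, "vs_baseline", "pre")
        assert out.mean_delta.iloc[0] == 0.0

    def test_planted_trend_recovered(self, desk_cohort):
        """The planted cohort rises above baseline at 1 wpi and ends below it."""
        cms = desk_cohort["cms"]
        df = pd.DataFrame({"subject": [c.subject_id for c in cms],
                           "timepoint": [c.timepoint for c in cms],
                           "strength": [gm.strength(c) for c in cms]})
        wide = df.pivot(index="subject", columns="timepoint", values="strength")
        out = ls.strength_delta_series(wide[list(desk_cohort["panel"].timepoints)],
                                       "vs_baseline", "pre")
        assert out.set_index("timepoint").loc["1wpi", "mean_delta"] > 0
        assert out.set_index("timepoint").loc["14wpi", "mean_delta"] < 0


class TestNodewisePaired:
    def test_identical_panels_nothing_significant(self):
        rng = np.random.default_rng(4)
        deg = rng.integers(0, 8, (8, 5)).astype(float)
        panel = _panel(np.stack([deg, deg], axis=2))
        results, summary = ls.nodewise_paired_test(panel, "t1", "t0")
        assert summary["n_significant_increase"] == 0
        assert summary["n_significant_decrease"] == 0
        assert all(r.direction == "none" for r in results)

    def test_closed_form_t_statistic(self):
        """diffs (-10,-12,-9,-11,-10): t = -10.4/(1.1402/sqrt(5)) ~ -20.4."""
        base = np.zeros((31, 5))
        base[0] = 30.0
        follow = base.copy()
        follow[0] += np.array([-10, -12, -9, -11, -10.0])
        panel = _panel(np.stack([base, follow], axis=2))
        results, summary = ls.nodewise_paired_test(panel, "t1", "t0", alpha=0.01)
        r = results[0]
        d = (follow - base)[0:1]
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert r.statistic == pytest.approx(expected_t, abs=1e-10)
        assert r.p_value < 0.01 and r.direction == "decrease"
        assert summary["n_significant_decrease"] == 1

    def test_matches_closed_form_on_random_panels(self):
        rng = np.random.default_rng(5)
        deg = rng.integers(0, 10, (10, 6, 2)).astype(float)
        panel = _panel(deg)
        results, _ = ls.nodewise_paired_test(panel, "t1", "t0")
        for r in results:
            d = deg[r.node_id, :, 1] - deg[r.node_id, :, 0]
            if np.allclose(d.std(ddof=1), 0):
                assert r.direction == "none"
                continue
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            assert r.statistic == pytest.approx(t, abs=1e-10)

    def test_zero_variance_node_flagged_none(self):
        deg = np.zeros((10, 5, 2))
        deg[0, :, 1] = 4.0  # constant shift -> zero-variance differences
        deg[1] = np.random.default_rng(6).integers(0, 9, (5, 2))
        results, _ = ls.nodewise_paired_test(_panel(deg), "t1", "t0")
        assert results[0].direction == "none"
        assert not np.isfinite(results[0].p_value)

    def test_planted_decline_detected(self, desk_cohort):
        """Motor hub nodes decline at 14 wpi; most are flagged as decreases."""
        panel = desk_cohort["panel"]
        motor = desk_cohort["truth"].motor_hub_ids
        results, _ = ls.nodewise_paired_test(panel, "14wpi", "pre")
        flagged = sum(results[n].direction == "decrease" for n in motor)
        assert flagged >= 0.8 * len(motor)

    def test_fdr_no_less_conservative(self):
        rng = np.random.default_rng(7)
        deg = rng.integers(0, 30, (30, 8, 2)).astype(float)
        _, raw = ls.nodewise_paired_test(_panel(deg), "t1", "t0")
        _, adj = ls.nodewise_paired_test(_panel(deg), "t1", "t0", fdr=True)
        n_raw = raw["n_significant_increase"] + raw["n_significant_decrease"]
        n_adj = adj["n_significant_increase"] + adj["n_significant_decrease"]
        assert n_adj <= n_raw


class TestMeanCentrality:
    def test_constant_panel_not_significant(self):
        deg = np.tile(np.arange(6.0)[:, None, None], (1, 4, 3))
        out = ls.mean_centrality_comparison(_panel(deg), "t0")
        assert not out.significant.any()

    def test_halved_degrees_significant_decrease(self):
        rng = np.random.default_rng(8)
        base = rng.integers(4, 12, (12, 6)).astype(float)
        deg = np.stack([base, np.floor(base / 2)], axis=2)
        out = ls.mean_centrality_comparison(_panel(deg), "t0")
        row = out[out.timepoint == "t1"].iloc[0]
        assert row.significant and row.t_vs_baseline < 0

    def test_grand_mean_identity(self):
        rng = np.random.default_rng(9)
        deg = rng.integers(0, 7, (7, 5, 2)).astype(float)
        out = ls.mean_centrality_comparison(_panel(deg), "t0")
        assert out.mean_centrality.iloc[0] == pytest.approx(deg[:, :, 0].mean())

    def test_single_subject_rejected(self):
        deg = np.zeros((4, 1, 2))
        with pytest.raises(InsufficientDataError):
            ls.mean_centrality_comparison(_panel(deg), "t0")


def _mixed_anova_oracle(y):
    """Textbook mixed-design SS decomposition; y has shape (g, s, t)."""
    g, s, t = y.shape
    gm_ = y.mean()
    ss_group = s * t * ((y.mean(axis=(1, 2)) - gm_) ** 2).sum()
    subj_means = y.mean(axis=2)                      # (g, s)
    ss_subj = t * ((subj_means - y.mean(axis=(1, 2))[:, None]) ** 2).sum()
    ss_time = g * s * ((y.mean(axis=(0, 1)) - gm_) ** 2).sum()
    cell = y.mean(axis=1)                            # (g, t)
    ss_inter = s * ((cell - y.mean(axis=(1, 2))[:, None]
                     - y.mean(axis=(0, 1))[None, :] + gm_) ** 2).sum()
    ss_total = ((y - gm_) ** 2).sum()
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter
    ms = {
        "group": ss_group / (g - 1),
        "subj": ss_subj / (g * (s - 1)),
        "time": ss_time / (t - 1),
        "inter": ss_inter / ((g - 1) * (t - 1)),
        "err": ss_err / (g * (s - 1) * (t - 1)),
    }
    return {"group": ms["group"] / ms["subj"],
            "time": ms["time"] / ms["err"],
            "interaction": ms["inter"] / ms["err"]}


class TestGroupComparison:
    def test_identical_cohorts_group_effect_null(self):
        rng = np.random.default_rng(10)
        deg = rng.integers(5, 25, (26, 4, 3)).astype(float)
        pa = _panel(deg.copy())
        pb = _panel(deg.copy())
        out = ls.group_rm_comparison(pa, pb, np.arange(6), np.arange(6))
        f_group = out[out.Source == "group"].F.iloc[0]
        assert f_group == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_ss_decomposition(self):
        """Balanced 2 groups x 3 subjects x 2 times toy vs textbook F values."""
        rng = np.random.default_rng(11)
        y = rng.integers(0, 30, (2, 3, 2)).astype(float)
        pa = _panel(np.pad(y[0][None, :, :], ((0, 30), (0, 0), (0, 0))))
        pb = _panel(np.pad(y[1][None, :, :], ((0, 30), (0, 0), (0, 0))))
        out = ls.group_rm_comparison(pa, pb, np.array([0]), np.array([0]))
        oracle = _mixed_anova_oracle(y)
        for source in ("group", "time", "interaction"):
            f = out[out.Source == source].F.iloc[0]
            assert f == pytest.approx(oracle[source], rel=1e-8)

    def test_opposite_trends_give_interaction(self):
        rng = np.random.default_rng(12)
        s, t = 10, 5
        base = 30 + rng.normal(0, 2, (s, t))
        declining = np.round(base - 3 * np.arange(t))
        rising = np.round(base + 3 * np.arange(t))
        pa = _panel(np.pad(declining[None], ((0, 59), (0, 0), (0, 0))))
        pb = _panel(np.pad(rising[None], ((0, 59), (0, 0), (0, 0))))
        out = ls.group_rm_comparison(pa, pb, np.array([0]), np.array([0]))
        assert out[out.Source == "interaction"].p.iloc[0] < 0.001

    def test_single_timepoint_rejected(self):
        deg = np.zeros((3, 4, 1))
        with pytest.raises(InsufficientDataError):
            ls.group_rm_comparison(_panel(deg), _panel(deg),
                                   np.arange(3), np.arange(3))

    def test_mismatched_timepoints_rejected(self):
        a = _panel(np.zeros((3, 4, 2)), timepoints=("pre", "1wpi"))
        b = _panel(np.zeros((3, 4, 2)), timepoints=("pre", "3wpi"))
        with pytest.raises(ValidationError):
            ls.group_rm_comparison(a, b, np.arange(3), np.arange(3))
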