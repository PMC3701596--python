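"""Variance-homogeneity tests, the two-stage screen, and CV/MAD tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from periphsleep import (
    DesignSpec,
    EffectConfig,
    bartlett_test,
    brown_forsythe,
    dispersion_table,
    generate_study,
    trajectory_summary,
    two_stage_screen,
)
from periphsleep.study import DesignError
from conftest import make_study


def bartlett_oracle(groups):
    """Closed-form Bartlett formula, written directly from its definition."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    big_n = ns.sum()
    s2 = np.array([np.var(g, ddof=1) for g in groups])
    sp2 = ((ns - 1) * s2).sum() / (big_n - k)
    c = 1 + ((1 / (ns - 1)).sum() - 1 / (big_n - k)) / (3 * (k - 1))
    chi2 = ((big_n - k) * np.log(sp2) - ((ns - 1) * np.log(s2)).sum()) / c
    return chi2, stats.chi2.sf(chi2, k - 1)


class TestBartlett:
    def test_equal_variances_give_zero(self):
        chi2, p = bartlett_test([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_example(self):
        """Groups (1,2,3,4) and (2,4,6,8): s2 = (5/3, 20/3), C = 7/6."""
        chi2, p = bartlett_test([[1, 2, 3, 4], [2, 4, 6, 8]])
        assert chi2 == pytest.approx(1.1476, abs=2e-4)
        assert p == pytest.approx(0.284, abs=2e-3)

    def test_scale_equivariance(self):
        g = [[1.0, 2.0, 5.0], [0.5, 3.0, 4.0, 9.0]]
        chi2a, _ = bartlett_test(g)
        chi2b, _ = bartlett_test([np.array(x) * 37.5 for x in g])
        assert chi2a == pytest.approx(chi2b, rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 6)
            groups = [rng.normal(0, rng.uniform(0.5, 2), rng.integers(3, 13))
                      for _ in range(k)]
            chi2, p = bartlett_test(groups)
            ref = stats.bartlett(*groups)
            assert chi2 == pytest.approx(ref.statistic, rel=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_zero_variance_degenerate_flag(self):
        with pytest.warns(UserWarning):
            chi2, p = bartlett_test([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        assert p == 0.0 and np.isinf(chi2)


class TestBrownForsythe:
    def test_copied_groups_give_zero(self):
        f, p = brown_forsythe([[1.0, 2.0, 5.0], [1.0, 2.0, 5.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_location_invariance(self):
        a = [1.0, 2.0, 4.0, 8.0]
        b = [0.5, 1.5, 2.5, 3.0]
        f1, _ = brown_forsythe([a, b])
        f2, _ = brown_forsythe([a, np.array(b) + 100.0])
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_anova_on_deviations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.normal(0, rng.uniform(0.5, 3), int(rng.integers(3, 12)))
                      for _ in range(k)]
            f, p = brown_forsythe(groups)
            z = [np.abs(g - np.median(g)) for g in groups]
            ref = stats.f_oneway(*z)
            assert f == pytest.approx(ref.statistic, rel=1e-10)
            # scipy.stats.levene(center='median') is the same test
            lev = stats.levene(*groups, center="median")
            assert f == pytest.approx(lev.statistic, rel=1e-10)
            assert p == pytest.approx(lev.pvalue, rel=1e-8)


def five_group_study(sd_by_time, n=6, seed=0, n_probes=30, mean=8.0):
    rng = np.random.default_rng(seed)
    groups = {("lung", "baseline", 0.0):
              rng.normal(mean, sd_by_time[0], (n_probes, n))}
    for t, sd in zip((3.0, 6.0, 9.0, 12.0), sd_by_time[1:]):
        groups[("lung", "sleep", t)] = rng.normal(mean, sd, (n_probes, n))
        groups[("lung", "deprived", t)] = rng.normal(mean, sd_by_time[0],
                                                     (n_probes, n))
    return make_study(groups)


class TestTwoStageScreen:
    def test_flagged_subset_of_bartlett_survivors(self):
        study = five_group_study([0.25, 0.5, 0.4, 0.2, 0.1], seed=2)
        out = two_stage_screen(study, q1=0.2, p2=0.2)
        assert (out.loc[out["flagged"], "q_bartlett"] < 0.2).all()
        assert (out.loc[out["flagged"], "bf_p"] < 0.2).all()

    def test_uses_only_undisturbed_arm(self):
        # deprived arm wildly heteroscedastic; sleep arm homoscedastic
        rng = np.random.default_rng(3)
        groups = {("lung", "baseline", 0.0): rng.normal(8, 0.2, (20, 6))}
        for t in (3.0, 6.0, 9.0, 12.0):
            groups[("lung", "sleep", t)] = rng.normal(8, 0.2, (20, 6))
            groups[("lung", "deprived", t)] = rng.normal(8, 0.2 * t, (20, 6))
        out = two_stage_screen(make_study(groups))
        assert out["flagged"].sum() == 0

    def test_missing_duration_group_rejected(self):
        groups = {
            ("lung", "baseline", 0.0): np.ones((5, 1)) * 8,
            ("lung", "sleep", 3.0): np.random.default_rng(0).normal(8, 1, (5, 4)),
        }
        with pytest.raises(DesignError):
            two_stage_screen(make_study(groups))


class TestDispersion:
    def test_constant_group_zero_dispersion(self):
        study = five_group_study([0.25] * 5, seed=4)
        study.values[0, :] = 3.0
        disp = dispersion_table(study, scale="log2")
        row0 = disp[disp["probe_id"] == study.probe_ids[0]]
        assert (row0["cv"] == 0).all() and (row0["nmad"] == 0).all()

    def test_linear_cv_hand_example(self):
        """Group (2,4) on the linear scale: cv = sqrt(2)/3."""
        groups = {
            ("lung", "baseline", 0.0): [[np.log2(2.0), np.log2(4.0)]],
            ("lung", "sleep", 3.0): [[1.0, 1.0]],
            ("lung", "deprived", 3.0): [[1.0, 1.0]],
        }
        disp = dispersion_table(make_study(groups), scale="linear")
        base = disp[(disp["arm"] == "baseline")]
        assert base["cv"].iloc[0] == pytest.approx(np.sqrt(2) / 3)

    def test_nmad_hand_example(self):
        """Group (1,2,3): raw MAD = 1, median = 2, nmad = 0.5."""
        groups = {
            ("lung", "baseline", 0.0): [[1.0, 2.0, 3.0]],
            ("lung", "sleep", 3.0): [[1.0, 1.0]],
            ("lung", "deprived", 3.0): [[1.0, 1.0]],
        }
        disp = dispersion_table(make_study(groups), scale="log2")
        base = disp[disp["arm"] == "baseline"]
        assert base["nmad"].iloc[0] == pytest.approx(0.5)

    def test_nonpositive_mean_flagged_missing(self):
        groups = {
            ("lung", "baseline", 0.0): [[-1.0, -3.0]],
            ("lung", "sleep", 3.0): [[1.0, 1.0]],
            ("lung", "deprived", 3.0): [[1.0, 1.0]],
        }
        disp = dispersion_table(make_study(groups), scale="log2")
        base = disp[disp["arm"] == "baseline"]
        assert not base["valid"].iloc[0]
        assert np.isnan(base["cv"].iloc[0])

    @given(st.floats(min_value=0.5, max_value=4.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_linear_cv_scale_invariance(self, c):
        """Multiplying intensities by c (adding log2 c) leaves linear CV fixed."""
        study = five_group_study([0.25] * 5, seed=5, n_probes=5)
        d1 = dispersion_table(study, scale="linear")
        shifted = five_group_study([0.25] * 5, seed=5, n_probes=5)
        shifted.values = shifted.values + np.log2(c)
        d2 = dispersion_table(shifted, scale="linear")
        np.testing.assert_allclose(d1["cv"], d2["cv"], rtol=1e-9)


class TestTrajectory:
    def test_single_probe_subset_single_rows(self):
        study = five_group_study([0.25] * 5, seed=6)
        disp = dispersion_table(study)
        out = trajectory_summary(disp, subset=[study.probe_ids[0]])
        for tab in out["tables"].values():
            assert (tab.groupby("time_h").size() == 1).all()

    def test_empty_subset_empty_tables(self):
        study = five_group_study([0.25] * 5, seed=6)
        disp = dispersion_table(study)
        out = trajectory_summary(disp, subset=[])
        for tab in out["tables"].values():
            assert len(tab) == 0

    def test_planted_cluster_ratio_signs(self):
        """Generator sd multipliers force CV(sleep)/CV(baseline) > 1 early
        and CV(sleep)/CV(deprived) < 1 late."""
        spec = DesignSpec(n_baseline=10, n_per_group=8, tissues=("lung",),
                          n_probes=600)
        effects = EffectConfig(frac_enhanced=0.0, frac_repressed=0.0,
                               frac_var_cluster=0.1)
        studies, truth = generate_study(spec, effects, seed=8)
        cluster = truth.loc[truth["var_cluster"], "probe_id"]
        disp = dispersion_table(studies["lung"])
        out = trajectory_summary(disp, subset=cluster)
        med = out["medians"].set_index(["pairing", "time_h"])["median_log2_ratio"]
        assert med.loc[("sleep_vs_baseline", 3.0)] > 0
        assert med.loc[("sleep_vs_deprived", 12.0)] < 0
        # MAD-based summary shows the same signs (robustness)
        out_mad = trajectory_summary(disp, subset=cluster, measure="nmad")
        med_mad = out_mad["medians"].set_index(["pairing", "time_h"])["median_log2_ratio"]
        assert med_mad.loc[("sleep_vs_baseline", 3.0)] > 0
        assert med_mad.loc[("sleep_vs_deprived", 12.0)] < 0

    def test_null_median_ratio_near_zero(self):
        study = five_group_study([0.25] * 5, seed=9, n_probes=400)
        disp = dispersion_table(study)
        med = trajectory_summary(disp)["medians"]
        assert med["median_log2_ratio"].abs().max() < 0.35  # n=6 groups are noisy
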