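"""Stage-1 state test: ANOVA decomposition, variance shrinkage, the
shrunken F statistic, permutation null, and BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import polygamma

from periphsleep import (
    bh_fdr,
    call_de,
    fit_state_anova,
    fs_statistic,
    permutation_pvalues,
    shrink_variances,
    state_analysis,
)
from periphsleep.study import DesignError
from conftest import make_study


def two_group_study(sleep, dep):
    sleep = np.atleast_2d(sleep)
    dep = np.atleast_2d(dep)
    half_s, half_d = sleep.shape[1] // 2, dep.shape[1] // 2
    return make_study({
        ("heart", "sleep", 3.0): sleep[:, :half_s],
        ("heart", "sleep", 6.0): sleep[:, half_s:],
        ("heart", "deprived", 3.0): dep[:, :half_d],
        ("heart", "deprived", 6.0): dep[:, half_d:],
    })


class TestStateAnova:
    def test_hand_computed_example(self):
        """sleep=[0,1,2], deprived=[3,4,5]: delta=-3, F=13.5 (SSB=13.5, MSW=1)."""
        study = make_study({
            ("heart", "sleep", 3.0): [[0.0, 1.0, 2.0]],
            ("heart", "deprived", 3.0): [[3.0, 4.0, 5.0]],
        })
        res = fit_state_anova(study)
        assert res["delta"].iloc[0] == pytest.approx(-3.0)
        assert res["F"].iloc[0] == pytest.approx(13.5)
        assert res["resid_var"].iloc[0] == pytest.approx(1.0)
        f_ref, _ = stats.f_oneway([0.0, 1.0, 2.0], [3.0, 4.0, 5.0])
        assert res["F"].iloc[0] == pytest.approx(f_ref, rel=1e-12)

    def test_identical_groups_give_zero(self):
        study = two_group_study([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = fit_state_anova(study)
        assert res["delta"].iloc[0] == 0.0
        assert res["F"].iloc[0] == 0.0

    def test_f_equals_squared_pooled_t(self):
        """For two groups, F is the square of the pooled-variance t statistic."""
        rng = np.random.default_rng(0)
        sleep = rng.normal(size=(500, 8))
        dep = rng.normal(0.3, 1.0, size=(500, 8))
        res = fit_state_anova(two_group_study(sleep, dep))
        t_ref = stats.ttest_ind(sleep, dep, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(res["F"], t_ref ** 2, rtol=1e-9)

    def test_baseline_samples_are_excluded(self):
        study = make_study({
            ("heart", "baseline", 0.0): [[100.0, 100.0]],
            ("heart", "sleep", 3.0): [[0.0, 1.0]],
            ("heart", "sleep", 6.0): [[2.0, 2.0]],
            ("heart", "deprived", 3.0): [[3.0, 4.0]],
            ("heart", "deprived", 6.0): [[5.0, 5.0]],
        })
        res = fit_state_anova(study)
        assert res["mean_sleep"].iloc[0] == pytest.approx(1.25)
        assert res["mean_dep"].iloc[0] == pytest.approx(4.25)

    def test_single_sample_state_rejected(self):
        with pytest.raises(DesignError):
            fit_state_anova(make_study({
                ("heart", "sleep", 3.0): [[0.0, 1.0]],
                ("heart", "deprived", 3.0): [[3.0, 4.0]],
            }).subset(arms=("sleep",)))


def shrink_oracle(variances, df, n_probes):
    """Independent one-file oracle of the chosen shrinkage formula."""
    x = np.log(np.asarray(variances, dtype=float))
    xbar = x.mean()
    sumsq = ((x - xbar) ** 2).sum()
    v = float(polygamma(1, df / 2.0))
    lam = 1.0 if sumsq == 0 else min(1.0, max(0.0, (n_probes - 3) * v / sumsq))
    return np.exp(xbar + (1 - lam) * (x - xbar))


class TestShrinkage:
    def test_equal_variances_unchanged(self):
        out, lam = shrink_variances([2.0] * 6, df=10)
        np.testing.assert_array_equal(out, [2.0] * 6)
        assert lam == 1.0

    def test_zero_intensity_is_identity(self):
        v = [0.5, 1.0, 2.0, 4.0]
        out, lam = shrink_variances(v, df=10, intensity=0.0)
        np.testing.assert_array_equal(out, v)
        assert lam == 0.0

    def test_five_probe_toy_matches_oracle(self):
        v = np.array([0.5, 1.0, 1.0, 1.0, 2.0])
        out, _ = shrink_variances(v, df=14)
        np.testing.assert_allclose(out, shrink_oracle(v, 14, 5), atol=1e-12)

    @given(st.lists(st.floats(min_value=0.05, max_value=20.0), min_size=2,
                    max_size=30), st.integers(min_value=2, max_value=40))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_oracle_and_stays_positive(self, variances, df):
        out, lam = shrink_variances(variances, df=df)
        assert 0.0 <= lam <= 1.0
        assert (out > 0).all()
        np.testing.assert_allclose(out, shrink_oracle(variances, df,
                                                      len(variances)),
                                   rtol=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            shrink_variances([1.0, 0.0], df=5)

    def test_single_probe_warns_and_returns_input(self):
        with pytest.warns(UserWarning):
            out, lam = shrink_variances([3.0], df=5)
        assert out[0] == 3.0 and lam == 0.0


class TestFsStatistic:
    def test_fs_equals_f_when_variance_unchanged(self):
        rng = np.random.default_rng(1)
        study = two_group_study(rng.normal(size=(50, 6)), rng.normal(size=(50, 6)))
        res = fit_state_anova(study)
        fs = fs_statistic(res["ss_state"], 1, res["resid_var"])
        np.testing.assert_array_equal(fs, res["F"].to_numpy())

    def test_fs_uses_shrunken_denominator(self):
        fs = fs_statistic(np.array([2.0]), 1, np.array([0.5]))
        assert fs[0] == 4.0


class TestPermutation:
    def test_top_probe_gets_plus_one_estimator_floor(self):
        """A probe beating every pooled null value: p = 1/(1 + n_perm*G)."""
        rng = np.random.default_rng(2)
        sleep = rng.normal(size=(10, 8)) * 0.1
        dep = rng.normal(size=(10, 8)) * 0.1
        sleep[0] += 50.0  # overwhelming effect
        p = permutation_pvalues(two_group_study(sleep, dep), n_perm=100, seed=0)
        assert p.iloc[0] == pytest.approx(1.0 / 1001.0)

    def test_constant_matrix_gives_p_one(self):
        study = two_group_study(np.full((5, 6), 7.0), np.full((5, 6), 7.0))
        p = permutation_pvalues(study, n_perm=30, seed=0)
        assert (p == 1.0).all()

    def test_seeded_determinism_and_probe_order_invariance(self):
        rng = np.random.default_rng(3)
        sleep = rng.normal(size=(40, 6))
        dep = rng.normal(size=(40, 6))
        study = two_group_study(sleep, dep)
        p1 = permutation_pvalues(study, n_perm=50, seed=9)
        p2 = permutation_pvalues(study, n_perm=50, seed=9)
        pd.testing.assert_series_equal(p1, p2)
        # reorder probes: pooled p-values follow their probe
        order = rng.permutation(40)
        shuffled = two_group_study(sleep[order], dep[order])
        p3 = permutation_pvalues(shuffled, n_perm=50, seed=9)
        np.testing.assert_allclose(p3.to_numpy(), p1.to_numpy()[order])

    def test_per_probe_mode(self):
        rng = np.random.default_rng(4)
        study = two_group_study(rng.normal(size=(10, 6)), rng.normal(size=(10, 6)))
        p = permutation_pvalues(study, n_perm=40, seed=1, pooled=False)
        assert ((p >= 1 / 41) & (p <= 1.0)).all()


def bh_oracle(pvals):
    """Brute-force step-up from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(m)
                      if p[order[j]] >= p[order[i]] - 1e-15]
        q[order[i]] = min(min(candidates), 1.0)
    return q


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04], atol=1e-12)

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=12))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_definitional_oracle(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-9)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallDe:
    def test_threshold_is_strict(self):
        tab = pd.DataFrame({"q": [0.005, 0.02], "delta": [1.0, -1.0]})
        out = call_de(tab, fdr_threshold=0.01)
        assert out["is_de"].tolist() == [True, False]
        assert out["direction"].tolist() == [1, -1]

    def test_empty_table(self):
        out = call_de(pd.DataFrame({"q": [], "delta": []}))
        assert len(out) == 0


def test_state_analysis_recovers_planted_effects(small_study):
    studies, truth = small_study
    res = state_analysis(studies["heart"], "heart", n_perm=100, seed=21)
    t_heart = truth[truth["tissue"] == "heart"].set_index("probe_id")
    planted = t_heart.index[t_heart["class_truth"] != "null"]
    called = set(res.index[res["is_de"]])
    assert len(called & set(planted)) / len(planted) >= 0.9
    # direction agrees with the planted state-effect sign
    sign = np.sign(t_heart.loc[res.index, "state_effect"])
    agree = res["direction"][res["is_de"]] == sign[res["is_de"]]
    assert agree.all()
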