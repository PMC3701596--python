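"""Stage 1: per-probe test of sleep vs sleep-deprived state.

The model is the gene-specific fixed-effect one-way ANOVA
``Y = mu + STATE + e`` fitted within each tissue, pooling all sacrifice
times and excluding the baseline group.  Significance uses a shrunken
F statistic ``Fs`` whose denominator variance is pulled toward an
across-probe consensus by James-Stein shrinkage on log residual
variances, a pooled permutation null (state labels shuffled across the
non-baseline samples, statistic recomputed per shuffle including
re-shrinkage), and Benjamini-Hochberg FDR control at 1%.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

from .study import DesignError, ExpressionStudy

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# One-way state ANOVA (vectorized over probes)
# ---------------------------------------------------------------------------

def _state_arrays(study: ExpressionStudy, tissue: str | None):
    sub = study.resolve_tissue(tissue).subset(arms=("sleep", "deprived"))
    is_sleep = (sub.samples["arm"] == "sleep").to_numpy()
    if is_sleep.sum() < 2 or (~is_sleep).sum() < 2:
        raise DesignError("each state needs at least 2 samples")
    return sub.values, is_sleep, sub.probe_ids


def _anova_core(values: np.ndarray, is_sleep: np.ndarray):
    """One-way decomposition over the two state groups for every probe row."""
    n1 = int(is_sleep.sum())
    n2 = values.shape[1] - n1
    m1 = values[:, is_sleep].mean(axis=1)
    m2 = values[:, ~is_sleep].mean(axis=1)
    grand = values.mean(axis=1)
    ss_state = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ss_total = ((values - grand[:, None]) ** 2).sum(axis=1)
    ss_resid = np.maximum(ss_total - ss_state, 0.0)
    df_resid = n1 + n2 - 2
    resid_var = ss_resid / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            resid_var > 0,
            ss_state / np.where(resid_var > 0, resid_var, 1.0),
            np.where(ss_state > 0, np.inf, 0.0),
        )
    return m1, m2, ss_state, resid_var, df_resid, f


def fit_state_anova(study: ExpressionStudy, tissue: str | None = None) -> pd.DataFrame:
    """Per-probe one-way ANOVA of sleep vs deprived state.

    Baseline (time 0) samples are excluded; both arms pool all time
    points.  ``F = MS_state / MS_resid`` with ``df_state = 1``.  Probes
    with zero residual variance get ``F = +inf`` (or 0 if the group means
    are also equal); the permutation stage ranks them rather than doing
    infinity arithmetic.
    """
    values, is_sleep, probes = _state_arrays(study, tissue)
    m1, m2, ss_state, resid_var, df_resid, f = _anova_core(values, is_sleep)
    return pd.DataFrame(
        {
            "mean_sleep": m1,
            "mean_dep": m2,
            "delta": m1 - m2,
            "ss_state": ss_state,
            "df_state": 1,
            "resid_var": resid_var,
            "df_resid": df_resid,
            "F": f,
        },
        index=pd.Index(probes, name="probe_id"),
    )


# ---------------------------------------------------------------------------
# James-Stein shrinkage of log residual variances
# ---------------------------------------------------------------------------

def shrink_variances(resid_vars, df: int, intensity: float | None = None):
    """Shrink per-probe residual variances toward an across-probe consensus.

    Works on ``X_g = ln(s_g^2)``: each value is pulled toward the
    across-probe mean by a James-Stein factor whose strength is set by the
    sampling variance of a log chi-square with ``df`` degrees of freedom,
    ``V = trigamma(df/2)`` — the df-dependent correction that makes the
    shrinkage adaptive: noisy variance estimates (small df) are shrunk
    hard, precise ones barely.

    Parameters
    ----------
    resid_vars : array-like
        Positive residual variances, one per probe.
    df : int
        Residual degrees of freedom shared by all probes.
    intensity : float or None
        Force the shrinkage intensity ``lambda`` in [0, 1] (0 = identity,
        1 = full pooling); ``None`` uses the data-driven James-Stein value
        ``min(1, (G-3) * V / sum((X - Xbar)^2))``.

    Returns
    -------
    (shrunken, lam) : (ndarray, float)
    """
    v = np.asarray(resid_vars, dtype=float)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("all residual variances must be positive and finite")
    if v.size < 2:
        warnings.warn("shrink_variances: fewer than 2 probes; returning input")
        return v.copy(), 0.0
    x = np.log(v)
    xbar = x.mean()
    if intensity is None:
        sumsq = ((x - xbar) ** 2).sum()
        if sumsq == 0.0:
            lam = 1.0
        else:
            vlog = float(polygamma(1, df / 2.0))  # Var[ln chi2_df]
            lam = min(1.0, max(0.0, max(v.size - 3, 0) * vlog / sumsq))
    else:
        if not 0.0 <= intensity <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        lam = float(intensity)
    if lam == 0.0:
        return v.copy(), 0.0
    return np.exp(xbar + (1.0 - lam) * (x - xbar)), lam


def fs_statistic(ss_state, df_state, shrunken_var):
    """Shrunken F: ``Fs = (SS_state / df_state) / shrunken_var``.

    Equals the classical F whenever the shrunken variance equals the raw
    residual variance.
    """
    ss = np.asarray(ss_state, dtype=float)
    sv = np.asarray(shrunken_var, dtype=float)
    if ss.shape != sv.shape:
        raise ValueError("ss_state and shrunken_var must align by probe")
    ms = ss / df_state
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sv > 0, ms / np.where(sv > 0, sv, 1.0),
                        np.where(ms > 0, np.inf, 0.0))


def _fs_for_labels(values, is_sleep, shrink_intensity):
    """F and Fs for one labelling, re-shrinking the permuted variances."""
    _, _, ss_state, resid_var, df_resid, f = _anova_core(values, is_sleep)
    ok = resid_var > 0
    shrunk = resid_var.copy()
    if ok.sum() >= 2:
        shrunk[ok], _ = shrink_variances(resid_var[ok], df_resid,
                                         intensity=shrink_intensity)
    fs = fs_statistic(ss_state, 1, shrunk)
    return f, fs, shrunk


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def permutation_pvalues(study: ExpressionStudy, tissue: str | None = None,
                        statistic: str = "fs", n_perm: int = 1000,
                        seed: int = 0, pooled: bool = True,
                        shrink_intensity: float | None = None,
                        stratify_time: bool = False) -> pd.Series:
    """Permutation p-values for the per-probe state statistic.

    State labels are shuffled across the non-baseline samples (globally by
    default, matching the exchangeability of the ``Y = mu + STATE + e``
    model; ``stratify_time=True`` shuffles within each sacrifice time for
    sensitivity analysis).  The statistic is recomputed per shuffle,
    including re-shrinkage.  With ``pooled=True`` the null aggregates all
    probes' permuted statistics and

        p_g = (1 + #{null >= Fs_g}) / (1 + n_perm * n_probes);

    per-probe nulls use the analogous +1 estimator.  Identical seeds give
    identical p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("fs", "f"):
        raise ValueError("statistic must be 'fs' or 'f'")
    sub = study.resolve_tissue(tissue).subset(arms=("sleep", "deprived"))
    values = sub.values
    is_sleep = (sub.samples["arm"] == "sleep").to_numpy()
    times = sub.samples["time_h"].to_numpy()
    g = values.shape[0]

    f, fs, _ = _fs_for_labels(values, is_sleep, shrink_intensity)
    obs = fs if statistic == "fs" else f

    if n_perm * g < 100:
        log.warning(
            "permutation null has only %d values; p-value resolution is coarse",
            n_perm * g,
        )
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, g))
    for b in range(n_perm):
        perm_labels = _shuffle_labels(is_sleep, times, stratify_time, rng)
        pf, pfs, _ = _fs_for_labels(values, perm_labels, shrink_intensity)
        null[b] = pfs if statistic == "fs" else pf
        if (b + 1) % 200 == 0:
            log.info("permutation %d/%d", b + 1, n_perm)

    if pooled:
        flat = np.sort(null.ravel())
        count_ge = flat.size - np.searchsorted(flat, obs, side="left")
        p = (1.0 + count_ge) / (1.0 + flat.size)
    else:
        count_ge = (null >= obs[None, :]).sum(axis=0)
        p = (1.0 + count_ge) / (1.0 + n_perm)
    return pd.Series(p, index=pd.Index(sub.probe_ids, name="probe_id"),
                     name="p_perm")


def _shuffle_labels(is_sleep, times, stratify_time, rng):
    out = np.empty_like(is_sleep)
    if stratify_time:
        for t in np.unique(times):
            idx = np.flatnonzero(times == t)
            out[idx] = is_sleep[idx][rng.permutation(idx.size)]
    else:
        out[:] = is_sleep[rng.permutation(is_sleep.size)]
    return out


# ---------------------------------------------------------------------------
# FDR and calling
# ---------------------------------------------------------------------------

def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / j`` — monotone in p, ties
    share a q.  Inputs must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(table: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Flag differential expression at ``q < fdr_threshold`` and record sign."""
    out = table.copy()
    out["is_de"] = out["q"] < fdr_threshold
    out["direction"] = np.sign(out["delta"]).astype(int)
    return out


def state_analysis(study: ExpressionStudy, tissue: str | None = None,
                   fdr_threshold: float = 0.01, n_perm: int = 1000,
                   seed: int = 0, pooled: bool = True,
                   shrink_intensity: float | None = None,
                   stratify_time: bool = False) -> pd.DataFrame:
    """Full stage-1 analysis: ANOVA, shrinkage, Fs, permutation p, BH q, calls."""
    res = fit_state_anova(study, tissue)
    ok = res["resid_var"] > 0
    shrunk = res["resid_var"].to_numpy().copy()
    if ok.sum() >= 2:
        shrunk[ok.to_numpy()], lam = shrink_variances(
            res.loc[ok, "resid_var"], int(res["df_resid"].iloc[0]),
            intensity=shrink_intensity,
        )
        log.info("shrinkage intensity lambda = %.4f", lam)
    res["shrunken_var"] = shrunk
    res["Fs"] = fs_statistic(res["ss_state"], 1, res["shrunken_var"])
    res["p_perm"] = permutation_pvalues(
        study, tissue, statistic="fs", n_perm=n_perm, seed=seed, pooled=pooled,
        shrink_intensity=shrink_intensity, stratify_time=stratify_time,
    )
    res["q"] = bh_fdr(res["p_perm"])
    res = call_de(res, fdr_threshold)
    log.info("stage 1: %d/%d probes DE at q < %g",
             int(res["is_de"].sum()), len(res), fdr_threshold)
    return res
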