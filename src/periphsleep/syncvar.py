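"""Variance-homogeneity screen and dispersion trajectories.

Sleep may synchronize peripheral gene expression across animals: for a
cluster of genes, inter-animal variability rises during early sleep and
collapses by the end of the sleep period.  This module screens for such
probes with a two-stage test on the five undisturbed-sleep duration groups
(baseline 0 h and spontaneous sleep for 3, 6, 9, 12 h):

1. Bartlett's test of homoscedasticity on log2 intensities, BH-corrected
   across probes, retaining q < 0.01;
2. the more robust Brown-Forsythe test (one-way ANOVA on absolute
   deviations from group medians) as confirmation at p < 0.01.

A probe is *flagged* only when it passes both stages.  The module also
computes the coefficient-of-variation and normalized-MAD trajectory
tables that visualize the synchronization geometry (sleep vs baseline,
deprivation vs baseline, sleep vs deprivation, per time point).

Bartlett and Brown-Forsythe are vectorized across probes here for speed;
unit tests cross-check them against scipy's scalar implementations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .diffstate import bh_fdr
from .study import DesignError, ExpressionStudy

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Core tests, vectorized over probe rows
# ---------------------------------------------------------------------------

def _bartlett_rows(groups):
    """Bartlett chi-square and p per probe; ``groups`` are (G, n_i) arrays.

    chi2 = [(N-k) ln s_p^2 - sum (n_i-1) ln s_i^2] / C with
    C = 1 + (sum 1/(n_i-1) - 1/(N-k)) / (3 (k-1)); p from chi2_{k-1}.
    Probes with a zero within-group variance are degenerate: chi2 = +inf,
    p = 0, with a warning (never NaN).
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    if k < 2 or np.any(ns < 2):
        raise DesignError("Bartlett needs >= 2 groups with >= 2 values each")
    big_n = int(ns.sum())
    variances = np.column_stack([g.var(axis=1, ddof=1) for g in groups])
    sp2 = (variances * (ns - 1)).sum(axis=1) / (big_n - k)
    c = 1.0 + ((1.0 / (ns - 1)).sum() - 1.0 / (big_n - k)) / (3.0 * (k - 1))
    degenerate = (variances <= 0).any(axis=1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) have a zero within-group "
            "variance; Bartlett p set to 0 for them"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (big_n - k) * np.log(sp2) - ((ns - 1) * np.log(variances)).sum(axis=1)
    chi2 = np.where(degenerate, np.inf, num / c)
    # exact homoscedasticity can give tiny negative values through rounding
    chi2 = np.where(np.isfinite(chi2), np.maximum(chi2, 0.0), chi2)
    p = np.where(degenerate, 0.0, stats.chi2.sf(np.where(degenerate, 1.0, chi2), k - 1))
    return chi2, p, variances, ns


def _brown_forsythe_rows(groups):
    """Brown-Forsythe F and p per probe: ANOVA on |x - group median|."""
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    if k < 2 or np.any(ns < 2):
        raise DesignError("Brown-Forsythe needs >= 2 groups with >= 2 values each")
    big_n = int(ns.sum())
    z = [np.abs(g - np.median(g, axis=1, keepdims=True)) for g in groups]
    means = np.column_stack([zi.mean(axis=1) for zi in z])
    grand = (means * ns).sum(axis=1) / big_n
    ssb = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ssw = np.column_stack(
        [((zi - mi[:, None]) ** 2).sum(axis=1) for zi, mi in zip(z, means.T)]
    ).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (big_n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(msw > 0, msb / np.where(msw > 0, msw, 1.0),
                     np.where(msb > 0, np.inf, 0.0))
    p = np.where(np.isinf(f), 0.0, stats.f.sf(np.where(np.isinf(f), 1.0, f),
                                              k - 1, big_n - k))
    p = np.where(f == 0.0, 1.0, p)
    return f, p


def bartlett_test(groups):
    """Bartlett's test for k samples of log2 values: returns (chi2, p)."""
    rows = [np.asarray(g, dtype=float)[None, :] for g in groups]
    chi2, p, _, _ = _bartlett_rows(rows)
    return float(chi2[0]), float(p[0])


def brown_forsythe(groups):
    """Brown-Forsythe (median-centred Levene) test: returns (F, p)."""
    rows = [np.asarray(g, dtype=float)[None, :] for g in groups]
    f, p = _brown_forsythe_rows(rows)
    return float(f[0]), float(p[0])


# ---------------------------------------------------------------------------
# Two-stage screen over the undisturbed-sleep duration groups
# ---------------------------------------------------------------------------

def _duration_groups(study: ExpressionStudy, tissue: str | None):
    """Split the undisturbed data (baseline + sleeping arm) by duration."""
    sub = study.resolve_tissue(tissue).subset(arms=("baseline", "sleep"))
    times = np.sort(sub.samples["time_h"].unique())
    groups, labels = [], []
    for t in times:
        mask = (sub.samples["time_h"] == t).to_numpy()
        if mask.sum() < 2:
            raise DesignError(f"duration group t={t} has < 2 samples")
        groups.append(sub.values[:, mask])
        labels.append(float(t))
    if len(groups) < 2:
        raise DesignError("need at least 2 duration groups")
    return groups, labels, sub.probe_ids


def two_stage_screen(study: ExpressionStudy, tissue: str | None = None,
                     q1: float = 0.01, p2: float = 0.01) -> pd.DataFrame:
    """Bartlett (BH q < q1) then Brown-Forsythe (p < p2) screen.

    Only baseline and spontaneously sleeping animals are used, grouped by
    sleep duration.  The Brown-Forsythe column is filled for every probe
    (so the full table is available), but ``flagged`` follows the published
    two-stage order: it requires the probe to survive the Bartlett stage
    first, hence the flagged set is always a subset of the Bartlett
    survivors.
    """
    groups, labels, probes = _duration_groups(study, tissue)
    chi2, p_bart, variances, ns = _bartlett_rows(groups)
    q_bart = bh_fdr(np.clip(p_bart, np.finfo(float).tiny, 1.0))
    f_bf, p_bf = _brown_forsythe_rows(groups)
    out = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    for j, t in enumerate(labels):
        out[f"var_{int(t)}"] = variances[:, j]
        out[f"n_{int(t)}"] = ns[j]
    out["bartlett_chi2"] = chi2
    out["bartlett_p"] = p_bart
    out["q_bartlett"] = q_bart
    out["bf_stat"] = f_bf
    out["bf_p"] = p_bf
    out["flagged"] = (q_bart < q1) & (p_bf < p2)
    log.info("variance screen: %d Bartlett survivors (q<%g), %d flagged",
             int((q_bart < q1).sum()), q1, int(out["flagged"].sum()))
    return out


# ---------------------------------------------------------------------------
# Dispersion trajectories (CV and normalized MAD)
# ---------------------------------------------------------------------------

def dispersion_table(study: ExpressionStudy, tissue: str | None = None,
                     scale: str = "linear") -> pd.DataFrame:
    """CV and normalized MAD per probe and (arm, time) group.

    ``cv = sd / mean`` (sd with n-1 denominator) and ``nmad = MAD / median``
    with the raw MAD — no Gaussian consistency factor, since the
    normalization is by the median, not an sd estimate.  On the default
    ``linear`` scale values are exponentiated base 2 before moments (CV of
    log-scale values is mean-dependent in an uninterpretable way);
    ``scale='log2'`` uses the stored values directly.  Groups with a
    non-positive mean (or median, for nmad) get NaN with ``valid=False``
    rather than propagating arithmetic.
    """
    if scale not in ("linear", "log2"):
        raise ValueError("scale must be 'linear' or 'log2'")
    sub = study.resolve_tissue(tissue)
    rows = []
    for (arm, t), idx in sub.samples.groupby(["arm", "time_h"]).groups.items():
        vals = sub.values[:, np.asarray(idx)]
        if scale == "linear":
            vals = np.exp2(vals)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1)
        med = np.median(vals, axis=1)
        mad = np.median(np.abs(vals - med[:, None]), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
            nmad = np.where(med > 0, mad / np.where(med > 0, med, 1.0), np.nan)
        rows.append(pd.DataFrame({
            "probe_id": sub.probe_ids,
            "arm": arm,
            "time_h": float(t),
            "cv": cv,
            "nmad": nmad,
            "valid": (mean > 0) & (med > 0),
        }))
    return pd.concat(rows, ignore_index=True)


_PAIRINGS = {
    "sleep_vs_baseline": ("sleep", "baseline"),
    "deprived_vs_baseline": ("deprived", "baseline"),
    "sleep_vs_deprived": ("sleep", "deprived"),
}


def trajectory_summary(disp: pd.DataFrame, subset=None,
                       measure: str = "cv") -> dict:
    """Per-time paired dispersion tables and their median log-ratios.

    For each pairing (sleep vs baseline, deprivation vs baseline, sleep vs
    deprivation) and each non-zero time point, returns the paired
    ``(x, y)`` dispersion values for the probes in ``subset`` (``None`` =
    all probes) plus the subset's median log2 ratio ``x / y`` — the
    quantitative skeleton of the counter-clockwise rotation of the
    synchronized cluster.  Baseline pairings use the t = 0 group as ``y``.
    """
    if measure not in ("cv", "nmad"):
        raise ValueError("measure must be 'cv' or 'nmad'")
    d = disp
    if subset is not None:
        subset = pd.Index(subset)
        d = d[d["probe_id"].isin(subset)]
    wide = d.pivot_table(index="probe_id", columns=["arm", "time_h"],
                         values=measure, aggfunc="first")
    times = sorted({t for a, t in wide.columns
                    if a in ("sleep", "deprived") and t > 0})
    tables = {}
    med_rows = []
    for name, (arm_x, arm_y) in _PAIRINGS.items():
        frames = []
        for t in times:
            col_x = (arm_x, t)
            col_y = (arm_y, 0.0) if arm_y == "baseline" else (arm_y, t)
            if col_x not in wide.columns or col_y not in wide.columns:
                continue
            pair = pd.DataFrame({
                "probe_id": wide.index,
                "time_h": t,
                "x": wide[col_x].to_numpy(),
                "y": wide[col_y].to_numpy(),
            }).dropna()
            frames.append(pair)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.log2(pair["x"].to_numpy() / pair["y"].to_numpy())
            ratio = ratio[np.isfinite(ratio)]
            med_rows.append({
                "pairing": name,
                "time_h": t,
                "median_log2_ratio": float(np.median(ratio)) if ratio.size else np.nan,
                "n": len(pair),
            })
        tables[name] = (pd.concat(frames, ignore_index=True) if frames
                        else pd.DataFrame(columns=["probe_id", "time_h", "x", "y"]))
    return {"tables": tables, "medians": pd.DataFrame(med_rows)}
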