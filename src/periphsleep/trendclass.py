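"""Stage 2: baseline-anchored trend regression and strict classification.

Probes passing stage 1 are fit to the common-intercept model

    y(t) = alpha0 + beta_sleep * t * 1[sleep] + beta_dep * t * 1[deprived] + eps

over the baseline (t = 0) samples and both arms, time continuous.  The
baseline samples anchor the shared intercept (t = 0 annihilates both slope
columns).  A probe is a *strict sleep-enhanced* gene when it is
differentially expressed with the sleeping arm higher AND its expression
rises significantly over the spontaneous-sleep time course (slope FDR
< 1%), with the slope sign concordant with the state difference; strict
sleep-repressed is the mirror image.  Discordant or non-significant
probes stay unclassified.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffstate import bh_fdr
from .study import DesignError, ExpressionStudy

log = logging.getLogger(__name__)

LABELS = ("sleep_enhanced", "sleep_repressed", "unclassified")


def _design_matrix(samples: pd.DataFrame, arms: str):
    t = samples["time_h"].to_numpy(dtype=float)
    is_sleep = (samples["arm"] == "sleep").to_numpy(dtype=float)
    is_dep = (samples["arm"] == "deprived").to_numpy(dtype=float)
    if arms == "both":
        x = np.column_stack([np.ones_like(t), t * is_sleep, t * is_dep])
    elif arms == "sleep_only":
        x = np.column_stack([np.ones_like(t), t * is_sleep])
    else:
        raise ValueError("arms must be 'both' or 'sleep_only'")
    return x


def fit_trend(study: ExpressionStudy, tissue: str | None = None,
              probes=None, arms: str = "both",
              fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Common-intercept, per-arm-slope OLS fit for each probe.

    Parameters
    ----------
    probes : sequence or None
        Restrict to these probe ids (normally the stage-1 DE set); ``None``
        fits every probe.  The slope FDR is computed over the fitted set.
    arms : str
        ``"both"`` (canonical) fits baseline + sleeping + deprived samples
        with one slope per arm; ``"sleep_only"`` drops the deprived arm and
        its slope column.

    Returns a DataFrame with ``alpha0``, ``beta_sleep``, ``beta_dep``,
    ``se_beta_sleep``, ``t_slope``, ``p_slope``, ``q_slope`` and
    ``slope_sign`` indexed by probe id.
    """
    sub = study.resolve_tissue(tissue)
    if arms == "sleep_only":
        sub = sub.subset(arms=("baseline", "sleep"))
    values = sub.values
    probe_index = pd.Index(sub.probe_ids, name="probe_id")
    if probes is not None:
        keep = probe_index.isin(pd.Index(probes))
        if keep.sum() != len(set(probes)):
            raise DesignError("requested probes not all present in the study")
        values = values[keep]
        probe_index = probe_index[keep]
    if len(probe_index) == 0:
        return pd.DataFrame(
            columns=["alpha0", "beta_sleep", "beta_dep", "se_beta_sleep",
                     "t_slope", "p_slope", "q_slope", "slope_sign"],
            index=probe_index,
        )

    sleepish = sub.samples["arm"].isin(["baseline", "sleep"])
    n_times = sub.samples.loc[sleepish, "time_h"].nunique()
    if n_times < 3:
        raise DesignError(
            f"need >= 3 distinct times across baseline + sleeping arm, got {n_times}"
        )
    x = _design_matrix(sub.samples, arms)
    n, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = values @ x @ xtx_inv.T          # (G, p)
    resid = values - beta @ x.T
    dof = n - p
    s2 = (resid ** 2).sum(axis=1) / dof
    se_sleep = np.sqrt(s2 * xtx_inv[1, 1])
    b_sleep = beta[:, 1]
    # numerical floor: a slope at rounding-noise level is a flat fit (t = 0,
    # p = 1) even though the residual variance may also be rounding noise;
    # a genuinely non-zero slope with zero residuals fits perfectly (p -> 0)
    scale = np.maximum(np.abs(values).max(axis=1), 1.0)
    flat = np.abs(b_sleep) <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(flat, 0.0,
                          np.where(se_sleep > 0,
                                   b_sleep / np.where(se_sleep > 0, se_sleep, 1.0),
                                   np.inf * np.sign(b_sleep)))
    p_slope = np.where(np.isinf(t_stat), 0.0, 2.0 * stats.t.sf(np.abs(t_stat), dof))
    p_slope = np.clip(p_slope, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "alpha0": beta[:, 0],
            "beta_sleep": b_sleep,
            "beta_dep": beta[:, 2] if arms == "both" else np.nan,
            "se_beta_sleep": se_sleep,
            "t_slope": t_stat,
            "p_slope": p_slope,
        },
        index=probe_index,
    )
    out["q_slope"] = bh_fdr(out["p_slope"])
    out["slope_sign"] = np.sign(out["beta_sleep"]).astype(int)
    log.info("stage 2: %d/%d probes with q_slope < %g",
             int((out["q_slope"] < fdr_threshold).sum()), len(out), fdr_threshold)
    return out


def classify_strict(de: pd.DataFrame, trend: pd.DataFrame,
                    fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Assign strict sleep-enhanced / sleep-repressed / unclassified labels.

    ``de`` is the stage-1 table (needs ``is_de`` and ``delta``); ``trend``
    the stage-2 table (needs ``beta_sleep`` and ``q_slope``) on the same
    probes.  Labels are mutually exclusive and require sign concordance
    between the state difference and the sleep slope.
    """
    if not trend.index.isin(de.index).all():
        raise DesignError("trend probes are not a subset of the DE table")
    merged = de.loc[trend.index, ["is_de", "delta"]].join(
        trend[["beta_sleep", "q_slope"]]
    )
    sig_slope = merged["q_slope"] < fdr_threshold
    enhanced = merged["is_de"] & (merged["delta"] > 0) & sig_slope & (merged["beta_sleep"] > 0)
    repressed = merged["is_de"] & (merged["delta"] < 0) & sig_slope & (merged["beta_sleep"] < 0)
    label = np.where(enhanced, "sleep_enhanced",
                     np.where(repressed, "sleep_repressed", "unclassified"))
    out = merged.copy()
    out["label"] = label
    return out


def summarize_strict(labels_by_tissue: dict, probe_to_gene: pd.Series | None = None) -> dict:
    """Probe- and unique-gene-level counts of strict calls per tissue.

    ``labels_by_tissue`` maps tissue name to a :func:`classify_strict`
    table.  With a probe-to-gene map, unique-gene counts are included;
    unmapped probes count only at probe level.  Cross-tissue intersections
    are reported over strict (enhanced or repressed) sets.
    """
    out = {"per_tissue": {}, "intersection": {}}
    strict_probes = {}
    strict_genes = {}
    for tissue, tab in labels_by_tissue.items():
        strict = tab.index[tab["label"] != "unclassified"]
        strict_probes[tissue] = set(strict)
        entry = {
            "probes_enhanced": int((tab["label"] == "sleep_enhanced").sum()),
            "probes_repressed": int((tab["label"] == "sleep_repressed").sum()),
            "probes_strict": len(strict),
        }
        if probe_to_gene is not None:
            genes = probe_to_gene.reindex(strict).dropna()
            strict_genes[tissue] = set(genes)
            entry["genes_strict"] = len(strict_genes[tissue])
        out["per_tissue"][tissue] = entry
    tissues = list(labels_by_tissue)
    if len(tissues) >= 2:
        inter_p = set.intersection(*strict_probes.values())
        out["intersection"]["probes"] = len(inter_p)
        if probe_to_gene is not None and strict_genes:
            out["intersection"]["genes"] = len(set.intersection(*strict_genes.values()))
    return out
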