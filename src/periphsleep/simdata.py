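"""Seeded synthetic-data generator emulating the study design.

The experiment this package analyses compares two arms of mice — one
allowed uninterrupted sleep, one kept awake by gentle handling — sacrificed
after 3, 6, 9 and 12 hours of sleep opportunity, plus an undisturbed
baseline group sacrificed at lights-on (time 0), with two peripheral
tissues (heart, lung) profiled per animal.  The generator reproduces that
design and plants three kinds of signal:

* a per-gene *state effect* ``a_g`` — the mean log2 sleep-minus-deprived
  difference over the time course, realized as a divergence that grows
  linearly from the shared baseline (each arm receives an extra slope of
  ``+/- a_g / (2 tbar)`` where ``tbar`` is the mean sacrifice time, so the
  arm difference averages exactly ``a_g`` across the course);
* per-arm *temporal slopes* (log2 units per hour) added on top of that
  divergence;
* a *variance cluster* — probes whose inter-animal residual standard
  deviation changes with sleep duration, emulating sleep-driven
  synchronization of expression.

The generative law for a sample of probe ``g`` in arm ``A`` at time ``t`` is

    y = mu_g + beta_{A,g} * t + eps,   eps ~ Normal(0, sd_profile(g, A, t)),

where ``beta_{A,g}`` is the arm's *total* slope (planted slope plus the
state-divergence term); baseline samples sit at the common intercept
``mu_g``.  Because every arm is exactly linear through the shared
intercept, the common-intercept trend model fitted downstream is literally
true under the generator and its coefficients are recoverable to machine
precision in the noiseless limit.  The truth table records the total
per-arm slopes.

Noise is Gaussian on the log2 scale, the conventional behaviour of
RMA-summarized array intensities.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .study import ActivityTrace, ExpressionStudy

CLASS_LABELS = ("sleep_enhanced", "sleep_repressed", "null")


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


@dataclasses.dataclass(frozen=True)
class DesignSpec:
    """Sampling design: group sizes, sacrifice times, tissues, probe count.

    Defaults mirror the emulated study: a baseline group of 10 animals at
    time 0, 8 animals per (arm, time) cell at 3/6/9/12 h, two tissues.
    """

    n_baseline: int = 10
    n_per_group: int = 8
    times_h: tuple = (3.0, 6.0, 9.0, 12.0)
    tissues: tuple = ("heart", "lung")
    n_probes: int = 20000
    epoch_s: int = 10

    def __post_init__(self):
        if self.n_baseline < 2:
            raise ParameterError("n_baseline must be >= 2")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        t = np.asarray(self.times_h, dtype=float)
        if len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ParameterError("times_h must be strictly increasing and exclude 0")
        if self.n_probes < 1:
            raise ParameterError("n_probes must be >= 1")
        if self.epoch_s <= 0 or 60 % self.epoch_s != 0:
            raise ParameterError("epoch_s must be a positive divisor of 60")


@dataclasses.dataclass(frozen=True)
class EffectConfig:
    """Planted-signal configuration.

    ``frac_enhanced``/``frac_repressed`` are the fractions of probes given a
    positive/negative state effect with a sign-concordant sleep slope;
    ``frac_shared`` of those planted probes are common to all tissues.
    ``frac_var_cluster`` probes (disjoint from the state-effect probes) get
    the heteroscedastic sd profile: the sleeping-arm multipliers rise early
    and fall late (variance synchronization), the deprived-arm multipliers
    do the reverse.
    """

    frac_enhanced: float = 0.05
    frac_repressed: float = 0.05
    frac_var_cluster: float = 0.02
    frac_shared: float = 0.30
    state_effect: float = 0.5
    slope: float = 0.05
    baseline_sd: float = 0.25
    baseline_mean_range: tuple = (6.0, 12.0)
    var_mult_sleep: tuple = (1.5, 1.2, 0.8, 0.6)
    var_mult_dep: tuple = (0.8, 0.9, 1.1, 1.5)

    def __post_init__(self):
        for name in ("frac_enhanced", "frac_repressed", "frac_var_cluster",
                     "frac_shared"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_enhanced + self.frac_repressed + self.frac_var_cluster > 1.0:
            raise ParameterError("planted fractions sum to more than 1")
        if self.baseline_sd < 0:
            raise ParameterError("baseline_sd must be non-negative")
        if any(m <= 0 for m in self.var_mult_sleep + self.var_mult_dep):
            raise ParameterError("variance multipliers must be positive")


TRUTH_COLUMNS = [
    "tissue", "probe_id", "gene", "baseline_mean", "state_effect",
    "slope_sleep", "slope_dep", "class_truth", "var_cluster",
]


def probe_annotation(n_probes: int) -> pd.DataFrame:
    """Deterministic probe-to-gene map with some multi-probe genes.

    Every block of five consecutive probes maps to four genes (the last two
    probes of the block share one), giving the probe/unique-gene ratio seen
    on expression arrays.
    """
    probes = _probe_ids(n_probes)
    gene_idx = np.arange(n_probes) * 4 // 5
    genes = np.array([f"GENE{i:05d}" for i in gene_idx], dtype=object)
    return pd.DataFrame({"probe_id": probes, "gene": genes})


def _probe_ids(n: int) -> np.ndarray:
    return np.array([f"P{i:06d}" for i in range(n)], dtype=object)


def _plant_indices(spec: DesignSpec, effects: EffectConfig, rng):
    """Assign planted classes to probe indices, with cross-tissue sharing.

    Returns per-tissue dicts of index arrays plus the variance-cluster
    index set (shared across tissues).
    """
    g = spec.n_probes
    n_enh = int(round(effects.frac_enhanced * g))
    n_rep = int(round(effects.frac_repressed * g))
    n_var = int(round(effects.frac_var_cluster * g))
    n_tis = len(spec.tissues)
    sh_enh = int(round(effects.frac_shared * n_enh))
    sh_rep = int(round(effects.frac_shared * n_rep))
    need = n_var + sh_enh + sh_rep + n_tis * ((n_enh - sh_enh) + (n_rep - sh_rep))
    if need > g:
        raise ParameterError(
            f"cannot allocate {need} planted probes among {g}; "
            "reduce fractions or raise n_probes"
        )
    perm = rng.permutation(g)
    pos = 0

    def take(n):
        nonlocal pos
        out = perm[pos:pos + n]
        pos += n
        return out

    var_idx = np.sort(take(n_var))
    shared_enh = take(sh_enh)
    shared_rep = take(sh_rep)
    per_tissue = {}
    for tissue in spec.tissues:
        enh = np.sort(np.concatenate([shared_enh, take(n_enh - sh_enh)]))
        rep = np.sort(np.concatenate([shared_rep, take(n_rep - sh_rep)]))
        per_tissue[tissue] = {"enhanced": enh.astype(int), "repressed": rep.astype(int)}
    return per_tissue, var_idx.astype(int)


def _sample_sheet(spec: DesignSpec, tissue: str) -> pd.DataFrame:
    rows = []
    prefix = tissue[:2].upper()
    animal = 0
    for _ in range(spec.n_baseline):
        animal += 1
        rows.append((f"{tissue}_b{animal:02d}", tissue, "baseline", 0.0,
                     f"{prefix}{animal:03d}"))
    for arm in ("sleep", "deprived"):
        for t in spec.times_h:
            for _ in range(spec.n_per_group):
                animal += 1
                rows.append((f"{tissue}_{arm[0]}{int(t):02d}_{animal:02d}", tissue,
                             arm, float(t), f"{prefix}{animal:03d}"))
    return pd.DataFrame(
        rows, columns=["sample_id", "tissue", "arm", "time_h", "animal_id"]
    )


def _sd_matrix(spec: DesignSpec, effects: EffectConfig, var_idx,
               samples: pd.DataFrame) -> np.ndarray:
    """Per-(probe, sample) residual sd implied by the variance-cluster plan."""
    g = spec.n_probes
    sd = np.full((g, len(samples)), effects.baseline_sd, dtype=float)
    mult = {("sleep", t): m for t, m in zip(spec.times_h, effects.var_mult_sleep)}
    mult.update({("deprived", t): m
                 for t, m in zip(spec.times_h, effects.var_mult_dep)})
    for j, row in samples.iterrows():
        m = mult.get((row["arm"], row["time_h"]), 1.0)
        if m != 1.0:
            sd[var_idx, j] = effects.baseline_sd * m
    return sd


def generate_study(spec: DesignSpec, effects: EffectConfig | None = None,
                   seed: int = 0):
    """Generate one synthetic study per tissue plus the planted ground truth.

    Returns ``(studies, truth)`` where ``studies`` maps tissue name to
    :class:`~periphsleep.study.ExpressionStudy` and ``truth`` is a tidy
    DataFrame (one row per tissue x probe) recording every planted
    parameter, including the per-group residual sd profile.
    Identical ``(spec, effects, seed)`` give bit-identical output.
    """
    effects = effects if effects is not None else EffectConfig()
    rng = np.random.default_rng(seed)
    g = spec.n_probes
    probes = _probe_ids(g)
    ann = probe_annotation(g)
    baseline_mean = rng.uniform(*effects.baseline_mean_range, size=g)
    planted, var_idx = _plant_indices(spec, effects, rng)

    studies = {}
    truth_frames = []
    for tissue in spec.tissues:
        samples = _sample_sheet(spec, tissue)
        state_effect = np.zeros(g)
        slope_sleep = np.zeros(g)
        slope_dep = np.zeros(g)
        class_truth = np.full(g, "null", dtype=object)
        enh, rep = planted[tissue]["enhanced"], planted[tissue]["repressed"]
        t_mean = float(np.mean(spec.times_h))
        state_effect[enh] = effects.state_effect
        state_effect[rep] = -effects.state_effect
        # total per-arm slopes: planted slope plus the state divergence
        # a_g/(2 tbar), so the arm difference averages a_g over the course
        slope_sleep[enh] = effects.slope + effects.state_effect / (2 * t_mean)
        slope_sleep[rep] = -effects.slope - effects.state_effect / (2 * t_mean)
        slope_dep[enh] = -effects.slope - effects.state_effect / (2 * t_mean)
        slope_dep[rep] = effects.slope + effects.state_effect / (2 * t_mean)
        class_truth[enh] = "sleep_enhanced"
        class_truth[rep] = "sleep_repressed"

        t = samples["time_h"].to_numpy(dtype=float)
        is_sleep = (samples["arm"] == "sleep").to_numpy(dtype=float)
        is_dep = (samples["arm"] == "deprived").to_numpy(dtype=float)
        mean = (
            baseline_mean[:, None]
            + np.outer(slope_sleep, t * is_sleep)
            + np.outer(slope_dep, t * is_dep)
        )
        sd = _sd_matrix(spec, effects, var_idx, samples)
        values = mean if effects.baseline_sd == 0 else mean + rng.normal(size=mean.shape) * sd
        studies[tissue] = ExpressionStudy(probe_ids=probes, samples=samples,
                                          values=values)

        tf = pd.DataFrame({
            "tissue": tissue,
            "probe_id": probes,
            "gene": ann["gene"].to_numpy(),
            "baseline_mean": baseline_mean,
            "state_effect": state_effect,
            "slope_sleep": slope_sleep,
            "slope_dep": slope_dep,
            "class_truth": class_truth,
            "var_cluster": np.isin(np.arange(g), var_idx),
        })
        tf["sd_baseline"] = effects.baseline_sd
        for time, m in zip(spec.times_h, effects.var_mult_sleep):
            col = np.full(g, effects.baseline_sd)
            col[var_idx] = effects.baseline_sd * m
            tf[f"sd_sleep_{int(time)}"] = col
        for time, m in zip(spec.times_h, effects.var_mult_dep):
            col = np.full(g, effects.baseline_sd)
            col[var_idx] = effects.baseline_sd * m
            tf[f"sd_deprived_{int(time)}"] = col
        truth_frames.append(tf)

    truth = pd.concat(truth_frames, ignore_index=True)
    return studies, truth


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------

def generate_activity(spec: DesignSpec, bout_schedule, seed: int = 0,
                      total_s: int | None = None,
                      wake_rate: float = 5.0) -> ActivityTrace:
    """Generate a beam-break trace realizing a known sleep/wake schedule.

    ``bout_schedule`` is a list of ``(start_s, duration_s, state)`` with
    ``state`` in ``{"sleep", "wake"}``; bouts must be non-overlapping,
    ordered, and aligned to epoch boundaries so the schedule is exactly
    recoverable by the inactivity scorer.  Epochs not covered by a sleep
    bout are wake; wake epochs draw counts from ``1 + Poisson(wake_rate)``
    (support >= 1, so wake never masquerades as inactivity).
    """
    rng = np.random.default_rng(seed)
    ep = spec.epoch_s
    prev_end = -1
    for start, dur, state in bout_schedule:
        if state not in ("sleep", "wake"):
            raise ParameterError(f"unknown bout state {state!r}")
        if dur <= 0:
            raise ParameterError("bout duration must be positive")
        if start % ep or dur % ep:
            raise ParameterError(
                f"bout ({start}, {dur}) not aligned to the {ep}-s epoch grid"
            )
        if start < prev_end:
            raise ParameterError("bout schedule overlaps or is unordered")
        prev_end = start + dur
    end_s = max(prev_end, 0) if total_s is None else total_s
    if end_s <= 0:
        raise ParameterError("schedule is empty and no total_s given")
    n = end_s // ep
    counts = 1 + rng.poisson(wake_rate, size=n)
    for start, dur, state in bout_schedule:
        if state == "sleep":
            counts[start // ep: (start + dur) // ep] = 0
    return ActivityTrace(epoch_s=ep, counts=counts)


# ---------------------------------------------------------------------------
# Truth table round-trip
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path) -> pd.DataFrame:
    # keep_default_na so the literal class label "null" survives parsing
    truth = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise ParameterError(f"{path}: missing truth columns {missing}")
    if truth["var_cluster"].dtype != bool:
        truth["var_cluster"] = truth["var_cluster"].map(
            {"True": True, "False": False, True: True, False: False}
        ).astype(bool)
    return truth
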