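# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `periphsleep`.

## Study design being emulated

Mice in a 12:12 light/dark cycle are either allowed uninterrupted sleep
or sleep-deprived by gentle handling starting at lights-on.  A baseline
group (default n = 10) is sacrificed at time 0 (lights-on); both arms are
sampled at 3, 6, 9 and 12 h (default n = 8 per arm × time cell).  Two
tissues (heart, lung) are profiled per animal.  Input to every stage is a
probe-by-sample matrix of log2 expression intensities plus the sample
sheet (tissue, arm, time, animal).  Normalization from probe-level data
is out of scope: the pipeline consumes already-summarized log2 matrices
and the generator emits them.

## Stage 1 — state effect

Per probe, a one-way fixed-effect decomposition over the two states
(sleep vs deprived), pooling all times and excluding baseline:
`F = MS_state / MS_resid` with 1 and `N − 2` degrees of freedom.

**Variance shrinkage.**  The test statistic is `Fs = MS_state / σ̃²_g`
where `σ̃²_g` is a James–Stein estimate on the log scale: with
`X_g = ln s²_g`, the shrunken value is
`X̃_g = X̄ + (1 − λ)(X_g − X̄)`,
`λ = min(1, (G − 3) V / Σ(X_g − X̄)²)`, and `V = ψ′(df/2)` is the
sampling variance of a log chi-square with the residual degrees of
freedom — the df-dependent term that adapts the pooling strength to the
precision of the per-probe variance estimates.  Consequences that the
tests rely on: λ = 0 (or equal raw variances) reproduces the classical F
exactly, and λ ∈ [0, 1] always.  Probes with zero residual variance are
excluded from shrinkage and given `Fs = +∞` (or 0 when the group means
are also equal); the permutation rank handles them without infinity
arithmetic.

**Permutation null.**  State labels are shuffled globally across the
non-baseline samples, because the stage-1 model itself ignores time; a
`stratify_time` flag shuffles within sacrifice times for sensitivity
analysis (the choice is not asserted as the original analysis, which did
not state stratification).  The statistic is recomputed per shuffle
*including re-shrinkage*.  The pooled null aggregates all probes'
permuted statistics and `p_g = (1 + #{null ≥ Fs_g}) / (1 + B·G)` — the
+1 estimator never returns 0 and keeps the p-values valid.  BH step-up
FDR (delegated to `statsmodels.multipletests`, cross-checked in the
tests against a brute-force implementation of the definition) at q < 0.01
defines the DE set.  Default B = 1000 shuffles; the test-suite and
acceptance runs use B = 200, which at G ≥ 2000 probes still gives the
pooled null ≥ 4·10⁵ values and p-value resolution far below the BH
threshold.

## Stage 2 — strict classification

DE probes are refit over baseline + both arms with design
`[1, t·1(sleep), t·1(deprived)]`: a common intercept and one slope per
arm, time continuous.  Baseline samples (t = 0) contribute only to the
intercept.  Slope significance is the analytic t-test on `β_sleep`
followed by BH over the refitted (DE-restricted) set — a permutation
alternative is deliberately not the default because what to shuffle in a
continuous-time regression is underdetermined; the DE-restriction of the
FDR is the default, with `probes=None` fitting all probes instead.  The
joint two-slope fit is canonical; `arms="sleep_only"` reproduces the
narrower baseline+sleep variant.  The deprived-arm slope is estimated but
never used for classification.

A probe is **strict sleep-enhanced** iff `is_de ∧ δ > 0 ∧ q_slope < 0.01
∧ β_sleep > 0`, strict sleep-repressed with all signs flipped; everything
else — including DE probes with significant but discordant slopes — is
unclassified.  Strict sets are therefore subsets of DE sets and mutually
exclusive by construction.

Numerical floor: with zero residual variance, a slope below
`1e-10 × max(1, |y|_max)` is reported as t = 0, p = 1 (a perfectly flat
perfect fit), while a larger slope with zero residuals gets p → 0.

## Variance screen and dispersion trajectories

Only undisturbed animals (baseline + sleeping arm) enter, grouped by
sleep duration {0, 3, 6, 9, 12 h}.  Stage 1: Bartlett's chi-square
`[(N−k) ln s_p² − Σ(n_i−1) ln s_i²]/C`, `C = 1 + (Σ1/(n_i−1) −
1/(N−k))/(3(k−1))`, BH across probes, q < 0.01.  Stage 2: Brown–Forsythe
(one-way ANOVA on |x − group median|), p < 0.01, computed for all probes
but applied as a *confirmation*: `flagged` requires both, so the flagged
set is always inside the Bartlett survivor set.  Both tests are
vectorized across probes here (the screen visits every probe); unit
tests cross-check them against `scipy.stats.bartlett` and
`scipy.stats.levene(center="median")` to 1e-10.  A zero within-group
variance is a degenerate case reported as chi² = ∞, p = 0 with a
warning, never NaN.

**Dispersion.**  Per (arm, time) group: `cv = sd/mean` and
`nmad = MAD/median` with the *raw* MAD (no 1.4826 factor — the
normalization is by the median, not an sd estimate).  Default scale is
linear intensity (2^y) with a `log2` option: the CV of log-scale values
is mean-dependent in a way that has no clean interpretation, and either
convention is defensible for the trajectory plots, so the scale is a
config option rather than a hard-coded choice.  Non-positive means or
medians yield NaN plus a `valid=False` flag.  `trajectory_summary`
produces, per time point, the paired dispersion tables (sleep vs
baseline, deprived vs baseline, sleep vs deprived) restricted to any
probe subset, plus the subset's median log2 ratio per pairing — the
quantitative skeleton of the cluster's counter-clockwise rotation
(variance up in early sleep, down by the end of the sleep period).  No
formal test of the rotation is attempted; the module reproduces the
underlying tables only.

## Sleep scoring

An epoch is asleep iff it lies in a maximal run of zero-count epochs
spanning ≥ 40 s (inclusive, and configurable; the threshold must be a
multiple of the epoch length — no silent rounding).  Runs truncated by
the trace boundary count only their observed duration.  Percent sleep
per window is a direct epoch count; a partial trailing window is
reported with `complete=False` rather than dropped.  Raising the
threshold can only remove sleep (tested as a property).  The epoch
length is a required input — typical beam-break systems use 10 s, the
generator's default.

## Gene-set operations

Probe→gene collapsing uses rule `any` (a gene carries a call if any of
its probes does) with `all` as the alternative; unmapped probes stay at
probe level.  Overlap testing and term enrichment are one-tailed
Fisher/hypergeometric (`scipy.stats.fisher_exact`), with fold enrichment
`(k/n)/(K/N)`, BH over tested terms, and the background defaulting to
the assayed genes rather than the genome.  An optional EASE-style
discount evaluates the tail at k − 1 hits (conservative upper bound);
it is off by default because the exact external convention is not pinned
down.  Terms with no background genes after intersection are skipped.

## Heatmap ordering and products

For probes strict-labeled in both tissues, the 8-dimensional vector of
sleep-minus-deprived mean log2 differences — (heart, lung) × (3, 6, 9,
12 h), positive = higher in sleep — is ordered by agglomerative
clustering (Euclidean distance, average linkage by default, tie-breaks
by input index via scipy).  Clustering is presentational: it only orders
rows, claims no cluster structure, and the exact leaf order under a
different linkage is not a contract.  `export_products` writes every
table as TSV plus a manifest (versions, config, per-stage seeds, sha256
of each file); reruns with the same config are byte-identical.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions
under which the pipeline's operating characteristics are measured.

Generative law per probe g, arm A, time t:
`y = μ_g + β_{A,g} t + ε`, `ε ~ N(0, sd(g, A, t))`, with baseline
samples at the common intercept μ_g (drawn uniform on [6, 12] log2
units, the typical RMA intensity range).  The state effect `a_g`
(default |a| = 0.5 log2) is realized as a divergence growing linearly
from the shared baseline: each arm's slope gains `±a_g/(2 t̄)` (t̄ = mean
sacrifice time), so the sleep-minus-deprived difference averages exactly
`a_g` over the course and the stage-2 common-intercept model is *exactly
true* under the generator — noiseless runs recover all coefficients to
machine precision.  Planted enhanced/repressed probes additionally get
mirrored slopes ±0.05 log2/h; defaults plant 5% + 5% of probes with 30%
shared between tissues.  Noise is Gaussian on the log2 scale (the
conventional behaviour of RMA-summarized intensities), default sd 0.25.

The variance cluster (default 2% of probes, disjoint from the planted DE
set) multiplies the sleeping-arm sd by (1.5, 1.2, 0.8, 0.6) at t = (3,
6, 9, 12) and the deprived-arm sd by (0.8, 0.9, 1.1, 1.5): variance
rises in early sleep and collapses late, while deprivation does the
reverse.  These multipliers are illustrative — the magnitude of real
inter-animal variance modulation is not calibrated to any archived
dataset.

**Power note.**  At these default multipliers and n = 8–10 per group,
the two-stage screen's *per-probe* sensitivity is very low (raw Bartlett
power at p < 0.01 is ≈ 24%, and the BH + Brown–Forsythe conjunction
drives the flagged fraction toward zero); detecting individual cluster
members at FDR 1% would need roughly twice the variance contrast.  The
cluster's *geometry*, however, is robustly recovered: the median CV and
MAD ratios of the planted cluster show the early-rise/late-fall sign
pattern in every seed tested.  This is an honest property of Bartlett
screening at this sample size, not an implementation artifact.

Activity traces realize a user-given bout schedule (aligned to the epoch
grid, so the 40-s rule recovers it exactly when sleep bouts are ≥ 40 s):
sleep epochs have count 0 and wake epochs draw `1 + Poisson(5)` beam
breaks, so wake never masquerades as inactivity.

**What the generator does not emulate** — probe-level hybridization
artifacts, batch effects, correlated probes within a gene, heavy-tailed
or intensity-dependent noise, circadian structure independent of sleep
state, and annotation noise.  Passing recovery tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not performance on real arrays.

## Problem sizes and seeds

The pipeline defaults mirror the design (20,000 probes, 1,000
permutations).  The test suite and acceptance script run at 2,000–5,000
probes and 200 permutations — sizes chosen so the pooled permutation
null still has ≥ 4·10⁵ values and the BH thresholds are resolvable,
while a full run stays in seconds.  All randomness flows from explicit
seeds; the pipeline expands one global seed into per-stage child seeds
(kept below 2³¹) so stages can be rerun in isolation.

## Known limitations

- Permutation p-values at B = 200 have granularity 1/(1 + BG); single-
  probe studies should raise B.
- The stage-2 significance is analytic, not permutation-based; with
  heavy-tailed residuals the slope p-values inherit normal-theory
  assumptions.
- The Bartlett stage is powerful but outlier-sensitive; the
  Brown–Forsythe confirmation guards the flag set, at a real cost in
  sensitivity (see the power note).
- Gene-level collapsing treats probes as exchangeable evidence; no
  probe-quality weighting.
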