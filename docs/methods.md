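# Methods

## Correction model

For each sample the package fits, over the paired normalization control
probes, an ordinary least-squares regression of the natural log of the
red-channel intensities on the natural log of the green-channel
intensities (green is the independent variable). With fitted intercept
`b0` and slope `b1`, every green-channel intensity `I` on the array —
Type II methylated values and both values of Type I green loci — is
mapped through `exp(b1 * log(I) + b0)`; red-channel values are returned
bit-identical. The exponential form guarantees positive outputs, and a
positive slope guarantees a strictly increasing map, so within-sample
rank order of green intensities is preserved. Fits with non-positive
slope are rejected with an error rather than applied. Samples are fitted
independently; no information is shared across an experiment.

Plain OLS (`numpy.polyfit`) is the default; a Theil–Sen robust fit
(`scipy.stats.theilslopes`) is available behind `robust=True` for arrays
with outlying control probes, but is off by default because the standard
formulation of the method is a least-squares fit. Natural logarithms are
used throughout; any base would be self-consistent, but natural log
matches the exponential adjustment form directly.

Because measurement noise also affects the predictor (green) channel, the
OLS slope is attenuated toward zero relative to the generative slope
(errors-in-variables); at the default noise level (log-sd 0.1) a true
slope of 1.3 fits near 1.25. The correction built from the fitted
coefficients is the best least-squares description of the observed
red–green relationship, which is what the method prescribes; tests that
assert exact coefficient recovery do so at zero noise, where the fit is
exact.

## Comparator methods

* **Channel scaling with a referent** (`scale_normalize`): each sample's
  intensities are divided, per channel, by that channel's control-probe
  mean — this equalizes the two channels and is the dye-bias correction
  step — then multiplied by a channel-pooled referent target so values
  stay on the fluorescence scale. Referent conventions: the first sample
  (GenomeStudio-style), the sample with the smallest |red − green|
  control-mean difference (methylumi-style), or the grand mean of all
  samples' channel means (all-sample-mean normalization, ASMN; the
  simplest referent satisfying its description). The pooled target
  `(ref_red + ref_green)/2` is used rather than per-channel referent
  means: a per-channel referent would make the referent a fixed point and
  so preserve any dye bias the referent itself carries, leaving a bias
  common to all samples uncorrected — observably not how these methods
  behave. With one constant per channel per sample, the family assumes a
  constant red/green ratio and therefore under-adjusts large and
  over-adjusts small intensities when the true bias varies with
  intensity.
* **Between-channel quantile normalization** (`quantile_between_channels`):
  per sample, the methylated and unmethylated vectors over all probes
  jointly are each mapped to the mean of the two sorted vectors at their
  within-channel ranks, making the two empirical distributions identical.
  Tied input values share the average of their target values
  (mean-of-ties policy). This presumes the two channel distributions
  *should* be identical — false for samples whose overall methylation is
  far from 50%, which is exactly where the method fails in benchmarks.
* **Simple scaling** (`simple_scaling`): per sample, greens are multiplied
  by the single constant `mean_red / mean_green` of that sample's control
  probes; reds unchanged. This is an approximation of lumi's simple
  scaling normalization, whose exact internals are not published in a
  form reproduced here; it is labeled as such. The lumi smooth-quantile
  method is not implemented, so benchmark tables compare five correction
  methods plus raw data.

## Beta values and mode estimation

`compute_beta` is `M / (M + U + c)` elementwise with offset `c = 100` by
default (0 ≤ beta < 1 for non-negative inputs; strictly increasing in M
at fixed U; at offset 0 it equals the methylated fraction exactly). The
offset biases betas slightly toward 0 at realistic intensities (a
~3000-unit total shrinks beta by a factor ≈ T/(T+100) ≈ 0.97); this
affects all methods identically in comparisons.

The beta-distribution mode is the argmax of a Gaussian KDE
(`scipy.stats.gaussian_kde`, Silverman bandwidth rule) evaluated on a
fixed 512-point grid over [0, 1]; plateau ties resolve to the smallest
grid point, so the estimate is deterministic for fixed input. Degenerate
samples (all values identical) return the common value directly, since a
KDE bandwidth is undefined there. The grid pins resolution at 1/511 ≈
0.002. Because the Silverman factor scales as n^(-1/5), duplicating a
sample changes the bandwidth slightly and can move the argmax by a grid
step or two; the estimator is exactly invariant to sample order but only
grid-level invariant to duplication. `density_mode` applies the same
estimator on the observed data range for unbounded quantities such as
red/green control ratios.

## Synthetic data generator

The generator emulates a dilution-series experiment on a two-color
array. Defaults, chosen once as the package's standard study conditions:

| parameter | default | meaning |
|---|---|---|
| probes | 14,400 II / 3,700 I-red / 1,900 I-green | 20,000 probes at 450K-like proportions (~72% Type II; Type I red ≈ 2× Type I green) |
| control pairs | 93 | 450K count; 85 reproduces EPIC |
| levels × replicates | (0, 5, 10, 20, 40, 50, 60, 80, 100)% × (10, 3, 2, 3, 3, 2, 3, 3, 10) | 39-sample standard-control design |
| bias (b0, b1) | (−0.5, 1.3) | visible green compression; realistic magnitudes on production arrays are not established, so these are nominal |
| log_total_mean, log_total_sd | 8.0, 0.8 | lognormal total intensity per locus, median ≈ 3,000 a.u. |
| noise_log_sd | 0.1 | multiplicative lognormal measurement noise |
| probe_level_sd | 0.05 | per-probe scatter of the true methylation fraction around the mixture level, clipped to [0, 1] |

Per sample with mixture level p: true per-probe beta =
clip(p + N(0, probe_level_sd), 0, 1); a lognormal total splits into
methylated and unmethylated parts; every green-channel value g becomes
`exp((log(max(g, 1)) − b0) / b1) · exp(N(0, noise_log_sd))` (the exact
inverse of the correction map, plus noise); red values receive only the
noise factor. Control pairs share one true intensity per pair per
sample, observed unbiased in red and biased in green. Noise is
multiplicative lognormal (log-additive), consistent with fitting in log
space. A per-probe jitter on the bias intercept is available
(`bias_probe_jitter_sd`, off by default) for robustness experiments
where the uniform-bias assumption is deliberately broken.

The generator applies one bias map to *all* green values, which is the
regime where regression on control probes is exactly the right
correction; clipping rather than resampling at the [0, 1] boundary
skews per-probe betas at extreme levels; and no probe-type beta
differences, background fluorescence, batch or spatial effects are
modeled. Passing benchmarks therefore demonstrate correctness of the
algorithms and the expected ordering of methods under log-linear bias,
not performance on any real cohort. Two floor-policy consequences worth
knowing: intensities ≤ 0 are floored to 1.0 before any logarithm
(negligible against the thousands-of-units intensity scale), so a truly
zero methylated intensity (mixture level exactly 0 with zero scatter)
is not invertible — correct-then-beta reproduces configured levels
exactly only for levels > 0 — and the floor also guards the control
table, where the regression requires strictly positive values.

## Evaluation protocol

For standard-control data: per sample, the absolute deviation of the
beta-distribution mode from the sample's expected level; per-level
summaries average per-replicate deviations (the alternative — pool a
level's betas and take one mode — is available via `pool_replicates`).
Methods are compared with one-sided paired Student t-tests on the
per-sample deviations across all levels jointly, pairing on samples; an
`assay_type` option restricts scoring to Type I or Type II probes. With
p = P(T_{n−1} ≤ t) on d = a − b, the test is antisymmetric
(p(a,b) + p(b,a) = 1). All-zero differences raise a degenerate-test
error; constant non-zero differences return the limiting p-value (0
or 1), which keeps the direction convention meaningful for degenerate
but informative comparisons. p-values are reported raw, without
multiple-testing correction. Against the simulator's known truth,
`abs_error_vs_truth` flattens |beta − true_beta| over a chosen probe
subset and all samples, mirroring validation against an external
gold-standard assay of a few probes.

Benchmark problem sizes (20,000 probes, 39 samples) keep a full
seven-method run around half a minute on one CPU while preserving the
450K design proportions and the standard dilution design.

## Known limitations

* Control-pair assignment from a bare manifest uses deterministic rank
  pairing of the sorted red-family and green-family probe names;
  Illumina's true pair key is not public, and the OLS fit depends only
  weakly on within-cloud pairing.
* Missing values are rejected, not imputed; input tables must be dense.
* The scaling-family comparators recover absolute intensities only up to
  a per-sample global factor (beta values are unaffected).
* No detection p-values, bead counts, background correction, or
  probe-type (Infinium I/II) bias correction; these are separate
  preprocessing stages.
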