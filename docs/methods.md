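# Methods

## Data model

A session is a trial table: `n_trials x n_units` non-negative responses
(summed spike probability for imaging-style data, spike counts for
ephys-style data) with one stimulus label per trial. Azimuth labels live
on a uniform 13-point grid, −90° to +90° in 15° steps; the grid records
which sign is contralateral to the recorded hemisphere (default:
positive), used only for reporting and deterministic tie-breaking.
Prediction errors are plain absolute differences |true − predicted|; no
wrap-around is applied because the paradigm covers only the frontal
hemifield. Validation requires at least two repetitions of every label so
that no leave-one-out training fold can lose a class.

## Unit-level statistics

**Neuronal signal-to-noise (nS/N).** The best azimuth is the label whose
trials evoke the largest mean response; nS/N is the mean over those
trials divided by their sample standard deviation (ddof = 1), i.e. the
inverse coefficient of variation. An optional per-trial baseline is
subtracted first (useful for spike counts with drifting ongoing
activity); units whose mean becomes non-positive are flagged undefined,
zero-SD units are flagged infinite, and both are excluded from
histograms. An "ongoing" variant is obtained by applying the same
function to a single-pseudo-label dataset built from inter-trial windows.

**Kruskal–Wallis tuning.** Tie-corrected H across the 13 azimuth groups,
referred to χ² with 12 degrees of freedom. A unit whose responses are
identical across all trials scores H = 0, p = 1 rather than erroring.
With heavily zero-inflated responses the massive ties make the test
mildly conservative (false-positive fraction ≈ 0.04 at α = 0.05 in
simulation).

**χ² dependency and ranking.** Each unit's responses are discretized
into 10 equal-width bins over their observed range; empty bins are
dropped and the independence statistic is computed on the remaining
bins × azimuths contingency table with (occupied − 1) × 12 degrees of
freedom. No continuity correction is applied and asymptotic p-values are
used even with sparse cells (a warning is logged when > 20 % of expected
counts fall below 5) — this test is routinely applied to exactly such
zero-inflated data, where it detects distribution changes (e.g. failure
rates that depend on azimuth) that a median test misses. Under flat
tuning at ~260 trials the asymptotic p-values are mildly conservative:
the measured false-positive fraction is ≈ 0.03 at α = 0.05. Units are
ranked by ascending p, ties broken by descending statistic then ascending
index, making the "top-ranked units" fully deterministic.

## Decoding

**Classifier.** Kernel-density naive Bayes: one 1-D KDE per (unit,
class), priors = training class frequencies, MAP decision. Kernels:
uniform, Epanechnikov, Gaussian (default) or triangular. Bandwidths
default to the per-(class, unit) Silverman rule
`0.9 · min(sd, iqr/1.34) · n^(−1/5)`, falling back to the SD when the IQR
collapses under ties and to a small positive constant for constant
values. Scores are accumulated in log space with a density floor of
1e−300 per factor so that zero-likelihood products stay finite; if every
factor bottoms out, the posterior reduces to the priors and a warning is
logged. MAP ties are broken toward the smallest |azimuth|, then the more
contralateral angle. An alternative `tune_bayes` performs a deterministic
grid search (4 kernels × 10 log-spaced bandwidth multipliers of the
per-unit SD, 0.05–2) under stratified inner cross-validation; the default
leave-one-out path uses the Silverman rule directly, which keeps the
per-fold refit cheap and fully reproducible.

**Cross-validation and leakage.** `loo_decode` holds out one trial at a
time and recomputes *everything* data-dependent from the remaining
trials: χ² ranking for `top_ranked:m` selection, PCA means/loadings for
`pca:k`, and all bandwidths. Each fold's selections are stored and can be
reproduced bit-for-bit from the training fold (this is asserted in the
test suite). PCA is column-centered SVD with the component sign fixed so
the largest-magnitude loading is positive; the held-out trial is centered
with training-fold means only.

**Chance model and significance.** The chance error distribution is the
multiset of all 169 absolute differences between (true, predicted) grid
pairs, treated as an equally-weighted empirical sample: median 60°,
mean ≈ 64.6°, P(error = 0) = 13/169. Observed error distributions are
compared to it with two-sided two-sample Kolmogorov–Smirnov tests; when a
performance curve examines several model sizes, p-values are
Šidák-adjusted with m = number of sizes. The KS test is applied to a
discrete, heavily tied support, which makes it slightly conservative;
conclusions in the test suite are asserted with margins that tolerate
this. `performance_curve` flags the smallest size whose adjusted p falls
below α and whether significance is lost again at the largest size
(overfitting: more KDE parameters than the trial count supports).

**KNN alternative.** A majority vote over the k Euclidean nearest
training trials (default k = 5), vote ties resolved by the smaller mean
neighbour distance, then the MAP tie-break. It serves as a decoder that
does not assume conditional independence.

## Noise correlations

Pairwise Kendall tau-b (tie-adjusted, since zero-inflated responses tie
massively) is computed across the repetitions of each azimuth separately
and pooled over azimuths, so tuning differences (signal correlation)
never contaminate it. Decorrelated surrogates permute each unit's
responses independently within each azimuth class: every per-(unit,
class) multiset — hence every single-unit statistic — is preserved
exactly, while the trial-by-trial pairing is destroyed. The shift of the
real pooled tau distribution against surrogate pooling is tested with a
two-sided two-sample KS test. Cross-validated matrix sorting performs
average-linkage hierarchical clustering on d = 1 − tau from a random half
of an azimuth's trials (undefined coefficients enter as d = 1) and
displays the held-out half's matrix in the resulting leaf order.

`correlation_contribution` measures what the correlations do to the
population code operationally: leave-one-out decoding of the data versus
of n (default 20) decorrelated copies, pooled; three Šidák-corrected
(m = 3) KS comparisons (real vs chance, surrogate vs chance, real vs
surrogate) plus the medians and the resulting direction. The direction is
a measurement — the pipeline is validated on constructed populations
where the true sign is known (below) and reports opposite signs on the
two constructions.

## Synthetic data

The generator draws, per trial, a latent multivariate normal vector with
correlation matrix R (validated symmetric PSD with unit diagonal), maps
it through the normal CDF and inverts the per-unit marginal CDF — a
Gaussian copula, so marginals and dependence are controlled
independently. Marginals: gamma with shape `dispersion` and mean from the
tuning curve (imaging-like, continuous), or negative binomial with size
`dispersion` (ephys-like counts). Because the transform is monotone, a
latent correlation r yields Kendall tau = (2/π)·arcsin(r) exactly for
continuous marginals; this is verified against brute-force pair counting
in the tests. Response failures multiply each (trial, unit) by an
independent Bernoulli(1 − p_fail) mask; optionally failures are tied to
the latent variable (low quantiles fail), which correlates silence across
units. Tuning families: sigmoid saturating toward the contralateral side,
Gaussian bumps peaking at central-to-contralateral azimuths, flat, or a
random mix; per-unit peak rates are lognormal.

Presets pin the study conditions: `imaging-like` (600 units, 14
repetitions per azimuth, gamma marginals, p_fail 0.35), `ephys-like` (21
units, 20 repetitions = 260 azimuth trials, negative-binomial counts,
p_fail 0.25), `tone-ephys` (frequency block: 14 pure tones 4–48 kHz in
quarter-octave steps, 10 repetitions), `null` (flat tuning, identity R —
everything detected is a false positive). Failure rates and the default
latent correlation (0.15) are this package's choices of realistic values
for regimes where no published number exists; dispersions are set so that
typical nS/N sits below 1.

**What the generator does not emulate:** calcium-indicator dynamics and
spike-inference artifacts, slow drifts in excitability or attention
(nonstationary correlations), behaviour-locked modulation, and any
specific biophysical source of the correlations. Passing tests therefore
demonstrate that the *analysis* is correct and calibrated under the
assumed statistical structure, not that real recordings satisfy that
structure.

**Known-direction constructions.** Two populations with a near-unity
shared multiplicative gain (latent r = 0.995) on exponential azimuth
tuning fix the ground-truth sign of the correlation contribution:
opposed tuning within each of two 2-unit pairs makes the gain cancel in
the pair contrast (correlations reduce the decoding error; shuffling
raises it), while identical tuning across a 20-unit population lets the
gain mimic an azimuth shift (correlations increase the error; shuffling
averages it out). The signs are established by a 10×-repetitions
ground-truth run (fit on one large sample, decode an independent one) and
the pipeline is required to report them from single-session-sized data.
These constructions are deliberately extreme, and they use 30 repetitions
per azimuth (390 trials, a realistic single session): the error median
moves on a 15° grid and the KS comparison needs a few hundred trials of
power, so only effects of at least one grid step are reliably detectable
per session.

## Problem sizes and numerical choices

Tests and the acceptance script run at the preset scales above or
moderately scaled-down versions of them (e.g. 100–1000 units for null
calibration, 500 units for parameter recovery, 10 000 repetitions for
copula calibration, 20 seeds for the stochastic direction and overfitting
checks), chosen as the smallest sizes at which the Monte-Carlo error is
comfortably below the asserted margins. Child seeds for the pipeline
stages are derived from a single global seed via `SeedSequence.spawn`, so
stages can be re-run in isolation; every simulation, shuffle, split and
permutation is seed-deterministic. Degenerate inputs (constant units,
all-zero trials, classes absent from folds, non-PSD correlation inputs)
are either handled with explicit flags or rejected with a diagnostic
naming the offender, as documented per function.

## Limitations

- The χ² dependency test inherits the sparse-cell conservativeness of
  the asymptotic approximation under the fixed 10-bin equal-width rule;
  sensitivity analyses at 8/12 bins are a one-line change
  (`chi2_dependency(ds, n_bins=...)`) but not part of the default run.
- The KS comparison treats the finite chance multiset as an empirical
  sample and inherits tie conservativeness on the discrete error support.
- The decoder is deliberately naive (conditional independence); it
  measures the effect of correlations on a mismatched but practical
  decoder, not the information-theoretic value of the correlations.
- Decoding is per-session; no pooling across sessions/animals is
  implemented, matching the single-session design of the analysis.
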