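# Methods

This note documents the models, procedures, numerical choices, and known
limitations of `ratesync`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Threshold model and model space

Observations are relative difference thresholds
`d = (rate_comparison − rate_standard)/rate_standard`, one per participant ×
standard rate.  The 8 standard rates are `linspace(4, 15, 8)` Hz (spacing
11/7 Hz).  Thresholds are strictly positive and right-skewed, so the
likelihood is log-normal; records are treated as i.i.d. given the model
parameters, and a single log-scale variance σ² is shared across rates and
groups within a model.

The group-level median threshold as a function of rate index `r` and group
`j` (1 = high, 2 = low synchronizers) is

    median(d) = μ_j + x_{k,j}[r] · β_j,

where `x_k[r] = max(0, r − k + 1)` is the onset indicator switching on a
linear increase at grid index `k ∈ {2..8}` (the 4-Hz entry is always zero).
Five families — constant; group-specific constants; increase; increase with
group baselines; increase with group slopes — with the increase families
enumerating all 7 × 7 onset pairs give 2 + 3·49 = 149 models, each with
prior probability 1/149.  Within each 49-block the outer loop runs over the
high-synchronizer onset and the inner loop over the low-synchronizer onset,
both ascending, so M33 carries (onset_high = 11.86 Hz, onset_low = 8.71 Hz).

**Location convention.**  The log-normal location is `log(μ_j + x·β_j)`
throughout.  Writing the location as the linear predictor itself (without
the log) would put median thresholds at `exp(μ) ≈ 105%` for μ ≈ 0.045, i.e.
on the wrong scale entirely; the log-of-linear-median form keeps all
parameters on the threshold (proportion) scale and nests the constant
families exactly at β = 0.

**Priors.**  μ-parameters: Normal(0.05, 0.1245) truncated at 0 (0.09 prior
mean for the low-synchronizer baseline in group-baseline families);
β-parameters: Normal(0.02, 0.1245) truncated at 0; σ²: Uniform(0, 9.655),
the variance bound implied by thresholds spanning 0.1%–50% on the log scale.
Truncated normal densities are renormalized over [0, ∞), making every prior
proper; an implementation that leaves the truncated densities unnormalized
shifts every log marginal likelihood by a constant per parameter, which
cancels within a family of equal dimension but not across families.  All
posterior quantities reported by this package use the proper (renormalized)
convention.

## Marginal likelihoods

The default estimator is deterministic quadrature.  The parameter space is
at most 4-dimensional, and σ² separates: with per-cell sufficient statistics
(n, Σ log d, Σ (log d)²) the log likelihood is
`−N/2·log(2πσ²) − Σ log d − SS(means)/(2σ²)`, so the integrand factorizes
into a location-parameter mesh and a σ² axis combined by an outer sum.  The
integration grid is centered on the posterior mode (L-BFGS-B from two
starts), spans ±8 posterior SDs (curvature-based, with conservative
fallbacks), clipped to the prior support, with trapezoid weights; defaults
are 32 points per location dimension and 48 for σ².  Halving the resolution
changes log marginal likelihoods by < 10⁻³ on cohort-sized problems, and the
values match a brute-force dense-grid oracle and an independent
bridge-sampling estimator within the tolerances asserted in the tests.

The stochastic cross-check runs the emcee affine-invariant ensemble sampler
(16+ walkers, 2,000 steps, half discarded; split-R̂ reported per parameter)
and applies the iterative Meng–Wong bridge estimator with a moment-matched
Gaussian proposal.  It exists for parity with sampler-based workflows and as
an oracle in the tests; the quadrature path is authoritative because it is
reproducible bit-for-bit.

Parameter posteriors (`fit_parameters`) normalize the same mode-centered
grid and report marginal means and central 95% intervals per parameter; the
MCMC path reports sample quantiles and split-R̂.

## Weighted up-down staircase

Down-step = current step, up-step = 3 × current step, so the stationary
point satisfies `p·s = (1 − p)·3s`, i.e. p = 3/4.  Steps: 1% initially,
halved when the reversal count reaches 6 and again at 12 (values exactly
{1%, 0.5%, 0.25%}).  When `d ≤ step`, a correct response halves `d` instead
of subtracting, which keeps the track strictly positive; this halving counts
as a "down" movement.  The literal reading — an incorrect response at tiny
`d` still adds 3 × step — is implemented as stated.  A reversal is a flip
between consecutive effective movement directions; the first movement sets
the direction and cannot itself reverse.  The reversal value is the level
presented on the flipping trial.  Runs stop at 18 reversals; the threshold
is the mean of the last six reversal levels.

Degenerate response streams (always correct/always wrong) never reverse, so
`run_staircase` additionally bounds a run at 1,000 trials; such runs are
flagged incomplete and estimated from the available tail.  A ceiling of
d = 0.5 (the largest threshold considered plausible) clips runaway tracks,
and clips are counted.  Start values rise linearly 20–27% across the 8
rates; training values add 10 points.

## Psychometric function and fitting

The inner Weibull is parameterized so that F(threshold) = 0.5 and `width`
is the distance between its 0.05 and 0.95 points; the full curve is
`0.5 + (0.5 − λ)·F`.  The *reported* 75%-correct threshold solves the full
curve at 0.75 and is exposed separately (`threshold_75`); it equals the
inner threshold when λ = 0.  Fitting maximizes the binomial likelihood in
(log scale, log shape, lapse) with L-BFGS-B from two starts; a weak
Beta(1, 19) prior keeps the lapse near zero by default (`lapse_prior=None`
gives plain ML), and λ is capped at 0.2.  Wald 95% intervals come from the
numerical Hessian, delta-transformed onto (log threshold, log width, lapse).
Estimates that pin any transformed coordinate to its bound are flagged
`at_boundary` rather than failing.

Goodness of fit is the saturated-vs-fitted binomial deviance compared with
the 95th percentile of deviances from `n_boot` parametric-bootstrap
datasets, *each refit*; refitting makes the test calibrated by construction
(≈95% of self-generated datasets pass), which the tests verify at reduced
`n_boot` with binomial-noise-tolerant bounds.

## Synchronization analysis

Envelopes are resampled to 100 Hz (polyphase), band-passed 3.5–5.5 Hz with a
4th-order zero-phase Butterworth (applied forward–backward), and converted
to phase via the Hilbert transform; 1 s at each end (filter settling) is
excluded from all phase statistics.  PLV is computed in 5-s windows with 2-s
overlap — read as consecutive windows sharing 2 s, i.e. a 3-s hop — and
averaged across windows, then across runs.  Inputs with negligible in-band
power are flagged rather than rejected.  For WAV input the envelope is the
magnitude of the broadband analytic signal low-passed at 10 Hz — a simple
broadband front end standing in for a cochlear filterbank envelope, adequate
because the analysis consumes only the 3.5–5.5 Hz band.

Clustering is 2-means on scalar mean PLVs with 10 seeded restarts; "high"
is the cluster with the larger centroid, and participants whose assignment
varies across restarts are reported as unstable.  Run inconsistency (the
two runs straddling the midpoint between centroids) is flagged as an
exclusion reason in the pipeline.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes:
55 participants (35 high / 20 low synchronizers); thresholds log-normal
around `log(μ_j + x·β_j)` with defaults μ = 4.48%, β = 1.44%/step,
onset_low = 8.71 Hz, onset_high = 11.86 Hz; PLV clusters at 0.74 (SD 0.10)
and 0.34 (SD 0.12), Gaussian within cluster (the within-cluster shape is a
modelling assumption — only means and SDs are constrained).  The log-scale
variance default σ² = 0.16 (log-SD 0.4) was chosen once to match the
relative spread implied by reported MAD/median ratios of roughly 0.3–0.45
for per-participant thresholds.

Simulated observers answer through the same Weibull curve the fitting stage
assumes, with a constant lapse; real listeners drift, learn, and lapse
non-stationarily, so passing recovery tests here demonstrates correctness
of the estimation machinery, not robustness to model misspecification.

Synchronization pairs are raised-cosine amplitude modulations at the
syllable rate (default 4.5 Hz; an optional flag steps 4.3 → 4.7 Hz every 60
syllables like a progressive syllable train).  The produced envelope carries
per-cycle, zero-mean, non-accumulating Gaussian phase perturbations,
smoothed over ~2 cycles so their spectral content survives the 3.5–5.5 Hz
analysis band.  Because 5-s windows contain only a few effective samples of
such a slow perturbation, the windowed PLV statistic is biased upward
relative to the stationary value exp(−σ²/2); the jitter → expected-PLV
mapping is therefore calibrated by pushing signal pairs through the full
analysis chain on a fixed internal seed grid (deterministic, cached) and
inverted by interpolation.  This reproduces the target centroids through
the same estimator applied to real data.  Cochlear processing, speech
acoustics, and articulation are not modelled.

## Pipeline conventions

- Outlier rule: exclude a participant iff their mean threshold deviates from
  the cohort median by strictly more than 3 × scaled MAD (scale 1.4826, the
  normal-consistency constant); a value exactly at the fence is kept.  Both
  raw and scaled MAD are reported.  All-identical inputs warn and exclude
  nobody.
- Cycle-fraction conversion: a relative difference `d` corresponds to
  `d/(1+d)` of the standard period, i.e. `(d/(1+d))·1000/rate` ms.
- Demeaned correlations subtract each cluster's mean from every variable
  before ranking, removing the spurious association a bimodal grouping
  induces; the partial variant regresses the ranked covariate out of both
  ranked variables and correlates residuals.  p-values use the t
  approximation, with a seeded permutation option (automatic below n = 30).
- Every stage draws its seed from a `SeedSequence` spawned off the config
  seed; rerunning a config reproduces the report byte for byte.
- Group rank tests (Wilcoxon/Mann–Whitney) are delegated to scipy and
  included in reports for completeness.

## Problem sizes used in validation

Staircase equilibrium: 500 runs (the convergence check in the unit suite
uses 60).  Model recovery: 20 cohorts of 55 × 8 thresholds, all 149 models
per cohort at 20 location-grid points (indistinguishable from the default
32 to < 10⁻³ log units).  Psychometric calibration: 120 recovery fits and
40 goodness-of-fit replicates at n_boot = 250–500; the analysis driver uses
n_boot = 500 and the API default is 10,000.  PLV null calibration: 300–400
Monte-Carlo draws at N = 500 samples.

## Known limitations

- The quadrature grid assumes a unimodal posterior; with a handful of
  records the σ² posterior is broad and the ±8 SD window can truncate a
  heavy right tail.  The tests cross-check against dense grids and bridge
  sampling on exactly such small tables.
- The bridge estimator inherits Monte-Carlo error from its proposal fit;
  agreement is asserted at 0.1 log units, not exactness.
- k-means on a bimodal mixture assigns genuinely intermediate participants
  to the nearer centroid; with Gaussian clusters at 0.74/0.34 (SDs
  0.10/0.12) roughly one participant in 55 falls on the far side of the
  midpoint, so label "recovery" saturates near, not at, 100%.
- The lapse cap (0.2) and lapse prior make extreme lapse estimates
  impossible by design; data from inattentive observers will fit poorly
  rather than fit with a huge lapse.
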