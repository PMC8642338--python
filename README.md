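# ratesync

Auditory rate-discrimination thresholds, speech-synchronization phase
locking, and Bayesian comparison of threshold-versus-rate models.

## The problem

How finely can listeners discriminate the rate of an isochronous tone
sequence, and does that sensitivity degrade above the theta range (~4–8 Hz)?
And is the degradation point coupled to a listener's spontaneous
auditory-motor synchronization — the tendency to align one's own speech to a
heard syllable train?  `ratesync` implements the complete computational
battery needed to ask these questions of behavioral data, together with a
synthetic-data front end so every stage is testable without any recordings:

- **weighted up-down (WUD) staircase** — an adaptive 2-interval forced-choice
  track on the relative rate difference
  `d = (rate_comparison − rate_standard)/rate_standard`, with a 3:1 up/down
  step weighting that converges on the 75%-correct level; start values
  20–27% across the 8 standard rates (4–15 Hz, linearly spaced), 1% steps
  halved after 6 and 12 reversals, stop at 18 reversals, threshold = mean of
  the last six reversal levels;
- **psychometric fitting** — a Weibull curve
  `p(d) = 0.5 + (0.5 − λ)·F(d; threshold, width)` with fixed 0.5 guess rate
  and lapse rate λ, fit to method-of-constant-stimuli counts (7 log-spaced
  levels at 0.2–3× the adaptive threshold, 30 trials/level), with a
  parametric-bootstrap deviance goodness-of-fit test;
- **phase-locking analysis** — envelopes resampled to 100 Hz, band-passed
  3.5–5.5 Hz, Hilbert phases, `PLV = |Σ exp(i(φ_a − φ_b))|/N` in 5-s windows
  with 2-s overlap, and 2-means clustering of mean PLVs into high/low
  synchronizers;
- **149-model Bayesian comparison** — thresholds `D` modelled as
  `D ~ LogNormal(log(μ_j + x_{k,j}·β_j), σ²)`, where the onset indicator
  `x_k` switches on a linear increase at one of 7 candidate rates per group:
  two constant families plus three increase families × 49 onset pairs = 149
  models with uniform prior 1/149.  Marginal likelihoods by deterministic
  quadrature (bridge-sampling/MCMC cross-check included), posterior model
  probabilities, family and onset marginals, and evidence ratios
  `BF = p/(1 − p)`.

## Worked example

```python
import numpy as np
from ratesync import model_comparison as mc, synthetic_data as synth

# a 55-participant cohort: baseline 4.48%, slope 1.44%/step, increase onsets
# at 8.71 Hz (low synchronizers) and 11.86 Hz (high synchronizers)
table = synth.draw_threshold_dataset(synth.GenerativeSpec(seed=3))

posterior = mc.compare_models(table)          # all 149 models, ~20 s
best, p = posterior.best_model()
print(best.id, best.family, round(p, 4))
# -> 33 INCREASE 0.9687

print({f: round(v, 4) for f, v in posterior.family_probabilities().items()})
# -> {'NULL': 0.0, 'GROUP_BASELINE': 0.0, 'INCREASE': 0.97,
#     'INCREASE_GROUP_BASELINE': 0.0121, 'INCREASE_GROUP_SLOPE': 0.0179}

p_order = mc.marginal_event_probability(
    posterior, lambda s: s.onset_low is not None and s.onset_low < s.onset_high)
print(round(p_order, 4), round(mc.bayes_factor(p_order), 2))
# -> 1.0 84215.02  (onset earlier in low synchronizers, overwhelming here)
```

The winning model M33 is the generating one: a shared baseline with the
increase starting at 11.86 Hz in high and 8.71 Hz in low synchronizers.  Its
posterior probability (0.97 here) is far above the 1/149 ≈ 0.0067 prior; on
real data, where the effect is weaker relative to noise, the same machinery
yields smaller but still decisive family-level probabilities.

The numbered scripts under `analysis/` run the full battery stage by stage
(simulation → staircase validation → psychometric validation → PLV
clustering → model comparison → end-to-end report) and write their tables
under `results/`.  A thin CLI (`ratesync --help`) wraps the same functions.

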