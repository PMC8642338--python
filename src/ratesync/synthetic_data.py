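"""Synthetic cohorts, simulated observers, and envelope-signal pairs.

Everything downstream (staircase, psychometric fits, PLV clustering, model
comparison) is exercised on data drawn from the generative structure the
analysis assumes:

* relative difference thresholds are log-normal around a group-level location
  ``log(mu_j + x_j[r] * beta_j)`` — constant up to a group-specific onset
  rate, then increasing linearly per grid step;
* simulated observers respond through the Weibull psychometric function;
* stimulus/produced envelope pairs are amplitude modulations at the syllable
  rate (~4.5 Hz) whose produced member carries per-cycle, non-accumulating
  phase perturbations, so the mean PLV decreases monotonically with the
  jitter SD.

The defaults mirror the study conditions: 35 high and 20 low synchronizers,
8 standard rates from 4 to 15 Hz, PLV cluster centroids near 0.74 and 0.34.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .model_comparison import indicator_vector, rate_grid
from .psychometric import PsychometricParams, psych_function

__all__ = [
    "FAMILIES",
    "GenerativeSpec",
    "ObserverModel",
    "SyncSignalPair",
    "draw_threshold_dataset",
    "make_observer",
    "synth_sync_pair",
    "jitter_for_target_plv",
    "draw_sync_cohort",
    "render_tone_sequence",
    "write_wav",
]

FAMILIES = (
    "NULL",
    "GROUP_BASELINE",
    "INCREASE",
    "INCREASE_GROUP_BASELINE",
    "INCREASE_GROUP_SLOPE",
)

TONE_FREQ_HZ = 440.0
TONE_DUR_S = 0.015
RAMP_DUR_S = 0.005


@dataclass(frozen=True)
class GenerativeSpec:
    """Ground truth for a simulated cohort of rate-discrimination thresholds."""

    family: str = "INCREASE"
    mu_high: float = 0.0448
    mu_low: float = 0.0448
    beta_high: float = 0.0144
    beta_low: float = 0.0144
    onset_high: int | None = 6      # grid index of the first elevated rate (11.86 Hz)
    onset_low: int | None = 4       # 8.71 Hz
    sigma2: float = 0.16            # log-scale variance
    n_high: int = 35
    n_low: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        for name in ("mu_high", "mu_low", "beta_high", "beta_low", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        has_increase = "INCREASE" in self.family
        for name in ("onset_high", "onset_low"):
            onset = getattr(self, name)
            if has_increase:
                if onset is None or not 2 <= onset <= 8:
                    raise ValueError(
                        f"{name} must lie in 2..8 for family {self.family}, got {onset}"
                    )
            elif onset is not None:
                raise ValueError(f"{name} must be None for family {self.family}")
        if self.family in ("NULL", "INCREASE", "INCREASE_GROUP_SLOPE"):
            if self.mu_high != self.mu_low:
                raise ValueError(f"family {self.family} requires mu_high == mu_low")
        if self.family in ("NULL", "GROUP_BASELINE"):
            if self.beta_high != 0 or self.beta_low != 0:
                raise ValueError(f"family {self.family} requires zero slopes")
        elif self.family != "INCREASE_GROUP_SLOPE" and self.beta_high != self.beta_low:
            raise ValueError(f"family {self.family} requires beta_high == beta_low")


def draw_threshold_dataset(spec: GenerativeSpec) -> pd.DataFrame:
    """Draw one relative difference threshold per participant x standard rate.

    Thresholds in group j at rate index r are log-normal with location
    ``log(mu_j + x_j[r] * beta_j)`` and log-scale variance ``sigma2``, where
    x_j is the group's onset indicator vector (all zeros for families without
    an increase).  Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rates = rate_grid().rates
    rows = []
    for group, j, n, mu, beta, onset in (
        ("high", 1, spec.n_high, spec.mu_high, spec.beta_high, spec.onset_high),
        ("low", 2, spec.n_low, spec.mu_low, spec.beta_low, spec.onset_low),
    ):
        x = indicator_vector(onset) if onset is not None else np.zeros(8)
        locations = np.log(mu + x * beta)
        for p in range(n):
            pid = f"{group[0].upper()}{p + 1:03d}"
            draws = np.exp(rng.normal(locations, np.sqrt(spec.sigma2)))
            for r in range(8):
                rows.append((pid, group, j, r + 1, rates[r], draws[r]))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "group", "group_j", "rate_index",
                 "rate_hz", "threshold"],
    )


@dataclass(frozen=True)
class ObserverModel:
    """Simulated 2IFC participant responding through a Weibull psychometric curve."""

    params: PsychometricParams

    @property
    def true_threshold_75(self) -> float:
        return self.params.threshold

    def p_correct(self, d):
        return psych_function(d, self.params)


def make_observer(true_threshold_75: float, width: float,
                  lapse: float = 0.0) -> ObserverModel:
    """Observer producing 75% correct at ``true_threshold_75`` when lapse = 0."""
    return ObserverModel(PsychometricParams(true_threshold_75, width, lapse))


# ---------------------------------------------------------------------------
# Synchronization signal pairs


@dataclass(frozen=True)
class SyncSignalPair:
    stimulus_envelope: np.ndarray
    produced_envelope: np.ndarray
    sample_rate: float
    true_phase_jitter_sd: float


def synth_sync_pair(duration_s: float, syllable_rate: float = 4.5,
                    phase_jitter_sd: float = 0.0, seed=None,
                    fs: float = 100.0,
                    progressive_rate: bool = False) -> SyncSignalPair:
    """Stimulus/produced envelope pair with controllable phase jitter.

    The stimulus envelope is a raised-cosine amplitude modulation at the
    syllable rate; the produced envelope follows the same modulation with an
    independent N(0, sd^2) phase perturbation per syllable cycle, linearly
    interpolated between cycle centers (non-accumulating, so the mean PLV maps
    monotonically onto the jitter SD).  ``progressive_rate`` emulates a
    syllable train that steps from 4.3 to 4.7 Hz in 0.1-Hz increments every 60
    syllables instead of holding ``syllable_rate`` fixed.
    """
    if duration_s < 15.0:
        raise ValueError("duration must be >= 15 s (at least two analysis windows)")
    if phase_jitter_sd < 0:
        raise ValueError("phase_jitter_sd must be >= 0")
    if not 3.5 <= syllable_rate <= 5.5:
        warnings.warn(
            "syllable rate outside the 3.5-5.5 Hz analysis band; "
            "the PLV of this pair is not meaningful", UserWarning,
        )

    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fs))) / fs
    if progressive_rate:
        inst_rate = np.empty_like(t)
        phase = np.empty_like(t)
        cur_rate, phi, syll = 4.3, 0.0, 0
        for i, _ in enumerate(t):
            inst_rate[i] = cur_rate
            phase[i] = phi
            phi_next = phi + 2 * np.pi * cur_rate / fs
            if phi_next // (2 * np.pi) > phi // (2 * np.pi):
                syll += 1
                if syll % 60 == 0 and cur_rate < 4.7 - 1e-9:
                    cur_rate = round(cur_rate + 0.1, 10)
            phi = phi_next
    else:
        phase = 2 * np.pi * syllable_rate * t

    n_cycles = int(phase[-1] // (2 * np.pi)) + 2
    knots = rng.standard_normal(n_cycles)
    # Smooth the per-cycle perturbations over ~2 cycles so their spectral
    # content stays inside the 3.5-5.5 Hz analysis band around the carrier;
    # rescale to unit marginal variance so the jitter SD is exact.
    if phase_jitter_sd > 0 and n_cycles > 8:
        kernel = np.exp(-0.5 * (np.arange(-6, 7) / _JITTER_SMOOTH_CYCLES) ** 2)
        kernel /= np.sqrt(np.sum(kernel**2))
        knots = np.convolve(knots, kernel, mode="same")
    eps = phase_jitter_sd * np.interp(
        phase / (2 * np.pi), np.arange(n_cycles), knots)

    stim = 0.5 * (1.0 + np.cos(phase))
    prod = 0.5 * (1.0 + np.cos(phase + eps))
    return SyncSignalPair(stimulus_envelope=stim, produced_envelope=prod,
                          sample_rate=fs, true_phase_jitter_sd=phase_jitter_sd)


_JITTER_SMOOTH_CYCLES = 2.0


@lru_cache(maxsize=1)
def _plv_calibration_curve() -> tuple:
    """Monotone mapping jitter SD -> expected mean windowed PLV.

    Computed once by pushing signal pairs at a grid of jitter SDs through the
    same resample/band-pass/Hilbert/windowed-PLV chain used for analysis
    (fixed internal seeds, so the curve is deterministic).  The naive
    stationary-Gaussian value exp(-sd^2/2) understates the measured PLV
    because the 5-s windows contain only a few effective samples of the slow
    phase perturbation, which inflates the windowed resultant length; the
    empirical curve absorbs that bias.
    """
    from . import sync as _sync

    cfg = _sync.SyncConfig()
    sds = np.arange(0.0, 4.01, 0.25)
    means = []
    for i, sd in enumerate(sds):
        vals = []
        for rep in range(6):
            pair = synth_sync_pair(70.0, 4.5, float(sd), seed=90_000 + 97 * i + rep)
            pa = _sync.phase_series(pair.stimulus_envelope, pair.sample_rate, cfg)
            pb = _sync.phase_series(pair.produced_envelope, pair.sample_rate, cfg)
            vals.append(_sync.windowed_plv(pa, pb, cfg).mean_plv)
        means.append(float(np.mean(vals)))
    # enforce strict monotone decrease for a well-posed inverse
    means = np.minimum.accumulate(np.asarray(means))
    keep = np.concatenate([[True], np.diff(means) < -1e-6])
    return tuple(sds[keep]), tuple(means[keep])


def jitter_for_target_plv(target: float) -> float:
    """Jitter SD (radians) whose expected mean windowed PLV equals ``target``.

    Inverts the cached calibration curve of the full analysis chain; targets
    below the curve's floor (near-uniform phase) return the largest
    calibrated SD.
    """
    if not 0 < target <= 1:
        raise ValueError("target PLV must lie in (0, 1]")
    sds, plvs = (np.asarray(a) for a in _plv_calibration_curve())
    if target >= plvs[0]:
        return 0.0
    if target <= plvs[-1]:
        return float(sds[-1])
    return float(np.interp(target, plvs[::-1], sds[::-1]))


def draw_sync_cohort(n_high: int = 35, n_low: int = 20, seed=0,
                     high_mean: float = 0.74, high_sd: float = 0.10,
                     low_mean: float = 0.34, low_sd: float = 0.12) -> pd.DataFrame:
    """Per-participant target PLVs and calibrated jitter SDs for the two clusters.

    Within-cluster PLVs are Gaussian around the cluster centroids (0.74/0.34),
    clipped to (0.02, 0.98).  The returned table carries the jitter SD that
    makes a generated signal pair reproduce each participant's target PLV in
    expectation.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, m, s in (("high", n_high, high_mean, high_sd),
                           ("low", n_low, low_mean, low_sd)):
        targets = np.clip(rng.normal(m, s, size=n), 0.02, 0.98)
        for p, tgt in enumerate(targets):
            rows.append((f"{group[0].upper()}{p + 1:03d}", group, float(tgt),
                         jitter_for_target_plv(float(tgt))))
    return pd.DataFrame(rows, columns=["participant_id", "group",
                                       "target_plv", "jitter_sd"])


# ---------------------------------------------------------------------------
# Tone sequences


def render_tone_sequence(rate: float, n_tones: int, fs: float = 44100.0) -> np.ndarray:
    """Isochronous sequence of 15-ms 440-Hz tones with 5-ms linear ramps.

    Inter-onset interval is 1/rate; the waveform is peak-normalized.  Rates so
    high that consecutive tones would overlap (IOI < tone duration) are
    rejected.
    """
    if rate <= 0 or n_tones < 1:
        raise ValueError("rate must be > 0 and n_tones >= 1")
    ioi = 1.0 / rate
    if ioi < TONE_DUR_S:
        raise ValueError(
            f"rate {rate:g} Hz gives IOI {ioi * 1e3:.1f} ms < tone duration 15 ms"
        )
    n_tone = int(round(TONE_DUR_S * fs))
    n_ramp = int(round(RAMP_DUR_S * fs))
    tt = np.arange(n_tone) / fs
    tone = np.sin(2 * np.pi * TONE_FREQ_HZ * tt)
    ramp = np.ones(n_tone)
    ramp[:n_ramp] = np.arange(n_ramp) / n_ramp          # 5-ms linear rise
    ramp[n_tone - n_ramp:] = np.arange(n_ramp, 0, -1) / n_ramp  # 5-ms linear fall
    tone = tone * ramp
    total = int(round(((n_tones - 1) * ioi + TONE_DUR_S) * fs))
    wave = np.zeros(total)
    for k in range(n_tones):
        start = int(round(k * ioi * fs))
        wave[start:start + n_tone] += tone[: max(0, min(n_tone, total - start))]
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def write_wav(path, wave: np.ndarray, fs: float = 44100.0) -> None:
    """Write a mono waveform as 16-bit PCM WAV."""
    from scipy.io import wavfile

    scaled = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, int(fs), (scaled * 32767).astype(np.int16))
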