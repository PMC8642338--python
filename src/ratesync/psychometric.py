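"""Weibull psychometric function, constant-stimuli design, fitting and goodness of fit.

The psychometric function for a 2-interval forced-choice (2IFC) task maps the
relative rate difference ``d`` to the probability of a correct response:

    p(d) = 0.5 + (0.5 - lapse) * F(d; threshold, width)

where ``F`` is a Weibull cumulative form parameterized so that
``F(threshold) = 0.5`` and ``width`` is the distance between the stimulus
levels at which ``F`` reaches 0.05 and 0.95.  The guess rate is fixed at 0.5
(two-interval chance level).  The *reported* 75%-correct threshold — the level
at which the full curve, including the lapse ceiling, crosses 0.75 — is exposed
separately (:meth:`PsychometricParams.threshold_75`); it coincides with the
inner-function ``threshold`` when ``lapse = 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "PsychometricParams",
    "CSDesign",
    "FitResult",
    "comparison_levels",
    "psych_function",
    "fit_psychometric",
    "deviance_at",
    "goodness_of_fit",
    "simulate_cs_run",
]

_LN20 = np.log(20.0)          # -ln(1 - 0.95)
_LN20_19 = np.log(20.0 / 19.0)  # -ln(0.95)
_LN2 = np.log(2.0)


def _weibull_shape_from_spread(spread: float) -> float:
    """Solve for the Weibull shape k given width/threshold ratio.

    The ratio r(k) = [(ln 20)^(1/k) - (ln 20/19)^(1/k)] / (ln 2)^(1/k)
    is strictly decreasing in k, so a bracketed root always exists for
    spread in (0, inf).
    """

    def ratio(log_k: float) -> float:
        inv_k = np.exp(-log_k)
        return (_LN20**inv_k - _LN20_19**inv_k) / _LN2**inv_k - spread

    lo, hi = -6.0, 8.0
    if ratio(lo) < 0 or ratio(hi) > 0:
        raise ValueError(f"width/threshold ratio {spread:g} out of solvable range")
    return float(np.exp(optimize.brentq(ratio, lo, hi, xtol=1e-12)))


@dataclass(frozen=True)
class PsychometricParams:
    """Weibull psychometric parameters with a fixed 0.5 guess rate."""

    threshold: float
    width: float
    lapse: float = 0.0
    guess: float = field(default=0.5, init=False)

    def __post_init__(self):
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")
        if not self.width > 0:
            raise ValueError(f"width must be > 0, got {self.width}")
        if not 0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must be in [0, 0.5), got {self.lapse}")

    @property
    def shape(self) -> float:
        """Weibull shape parameter implied by threshold and width."""
        return _weibull_shape_from_spread(self.width / self.threshold)

    @property
    def scale(self) -> float:
        """Weibull scale parameter implied by threshold and shape."""
        return self.threshold / _LN2 ** (1.0 / self.shape)

    def threshold_75(self) -> float:
        """Level where the full curve (with lapse) crosses 75% correct.

        Equals ``threshold`` when lapse = 0; undefined (inf) when the lapse
        ceiling 1 - lapse falls below 0.75.
        """
        q = 0.25 / (0.5 - self.lapse)
        if q >= 1.0:
            return np.inf
        return float(self.scale * (-np.log1p(-q)) ** (1.0 / self.shape))


def psych_function(d, params: PsychometricParams):
    """Probability of a correct 2IFC response at relative difference ``d``.

    Non-decreasing in d; bounded in [0.5, 1 - lapse].
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("stimulus level d must be >= 0")
    inner = -np.expm1(-((d / params.scale) ** params.shape))
    return 0.5 + (0.5 - params.lapse) * inner


@dataclass(frozen=True)
class CSDesign:
    """Method-of-constant-stimuli design: 7 levels, 30 trials per level."""

    standard_rate: float
    levels: tuple
    trials_per_level: int = 30

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if lv.size != 7:
            raise ValueError(f"design requires exactly 7 levels, got {lv.size}")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly increasing")
        object.__setattr__(self, "levels", tuple(lv))


def comparison_levels(wud_threshold: float) -> np.ndarray:
    """Seven comparison levels: a log-spaced 0.2–3.0 scale times the adaptive threshold.

    The geometric factor sequence runs from 0.2 to 3.0 with ratio 15^(1/6).
    """
    if not wud_threshold > 0:
        raise ValueError(f"wud_threshold must be > 0, got {wud_threshold}")
    return wud_threshold * np.geomspace(0.2, 3.0, 7)


def simulate_cs_run(observer, design: CSDesign, seed=None) -> np.ndarray:
    """Simulate the full constant-stimuli block for one observer.

    Returns an array of shape (7, 2): per level (n_correct, n_total).
    Trials are Bernoulli draws from the observer's psychometric function,
    30 per level (one per run, 30 runs with mixed presentation — the order
    does not affect the counts).
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(design.levels)
    p = observer.p_correct(levels)
    n = design.trials_per_level
    n_correct = rng.binomial(n, p)
    return np.column_stack([n_correct, np.full(7, n)])


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    params: PsychometricParams
    ci: dict                      # param name -> (lo, hi), Wald 95%
    deviance: float
    log_likelihood: float
    threshold_75: float
    converged: bool
    at_boundary: bool
    n_levels: int


def _nll(theta, log_levels, k_corr, n_tot, lapse_prior):
    # optimized in (log scale, log shape, lapse); no root-solving in the hot loop
    log_scale, log_shape, lapse = theta
    shape = np.exp(log_shape)
    expo = np.clip(shape * (log_levels - log_scale), -700.0, 700.0)
    inner = -np.expm1(-np.exp(expo))
    p = 0.5 + (0.5 - lapse) * inner
    p = np.clip(p, 1e-9, 1 - 1e-9)
    ll = np.sum(k_corr * np.log(p) + (n_tot - k_corr) * np.log1p(-p))
    if lapse_prior is not None:
        a, b = lapse_prior
        ll += (a - 1) * np.log(max(lapse, 1e-12)) + (b - 1) * np.log1p(-lapse)
    return -ll


def _theta_to_params(theta) -> PsychometricParams:
    log_scale, log_shape, lapse = theta
    shape = np.exp(log_shape)
    scale = np.exp(log_scale)
    thr = scale * _LN2 ** (1.0 / shape)
    width = scale * (_LN20 ** (1.0 / shape) - _LN20_19 ** (1.0 / shape))
    return PsychometricParams(thr, width, max(0.0, float(lapse)))


_LAPSE_MAX = 0.2


def fit_psychometric(counts, design: CSDesign, lapse_prior=(1.0, 19.0),
                     compute_ci: bool = True) -> FitResult:
    """Fit the Weibull psychometric function to per-level (n_correct, n_total) counts.

    Maximum a-posteriori estimation of (threshold, width, lapse) with the guess
    rate fixed at 0.5.  By default a weak Beta(1, 19) prior keeps the lapse
    rate concentrated near zero; pass ``lapse_prior=None`` for plain maximum
    likelihood.  Wald 95% intervals are computed on (log threshold, log width,
    lapse) and back-transformed.
    """
    counts = np.asarray(counts, dtype=float)
    levels = np.asarray(design.levels)
    log_levels = np.log(levels)
    k_corr, n_tot = counts[:, 0], counts[:, 1]
    has_data = n_tot > 0
    if np.count_nonzero(has_data) < 2:
        raise ValueError("need data at >= 2 distinct levels")

    # moment-based starting point: level closest to 75% correct
    frac = np.where(has_data, k_corr / np.maximum(n_tot, 1), np.nan)
    idx = np.nanargmin(np.abs(frac - 0.75))
    thr0 = max(levels[idx], 1e-6)
    starts = [
        (np.log(thr0), np.log(3.0), 0.02),
        (np.log(np.median(levels)), np.log(1.2), 0.01),
    ]

    log_shape_bounds = (np.log(0.2), np.log(25.0))
    bounds = [
        (np.log(levels[0] * 1e-3), np.log(levels[-1] * 1e3)),
        log_shape_bounds,
        (0.0, _LAPSE_MAX),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll, x0, args=(log_levels, k_corr, n_tot, lapse_prior),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res

    log_scale, log_shape, lapse = best.x
    params = _theta_to_params(best.x)
    ll = -_nll(best.x, log_levels, k_corr, n_tot, None)
    dev = deviance_at(levels, counts, params)

    at_boundary = bool(
        np.isclose(log_scale, bounds[0][0]) or np.isclose(log_scale, bounds[0][1])
        or np.isclose(log_shape, log_shape_bounds[0])
        or np.isclose(log_shape, log_shape_bounds[1])
        or np.isclose(lapse, _LAPSE_MAX)
    )

    # Wald intervals: Hessian in (log scale, log shape, lapse), delta method
    # onto (log threshold, log width, lapse)
    ci = {}
    if not compute_ci:
        return FitResult(
            params=params, ci=ci, deviance=dev, log_likelihood=ll,
            threshold_75=params.threshold_75(), converged=bool(best.success),
            at_boundary=at_boundary, n_levels=int(np.count_nonzero(has_data)),
        )
    try:
        h = _numeric_hessian(
            lambda th: _nll(th, log_levels, k_corr, n_tot, lapse_prior), best.x
        )
        cov = np.linalg.inv(h)
        jac = _numeric_jacobian(_report_transform, best.x)
        cov_rep = jac @ cov @ jac.T
        sd = np.sqrt(np.clip(np.diag(cov_rep), 0, None))
        z = 1.959963984540054
        rep = _report_transform(best.x)
        ci["threshold"] = (np.exp(rep[0] - z * sd[0]), np.exp(rep[0] + z * sd[0]))
        ci["width"] = (np.exp(rep[1] - z * sd[1]), np.exp(rep[1] + z * sd[1]))
        ci["lapse"] = (max(0.0, lapse - z * sd[2]), min(_LAPSE_MAX, lapse + z * sd[2]))
    except np.linalg.LinAlgError:
        ci = {k: (np.nan, np.nan) for k in ("threshold", "width", "lapse")}
        at_boundary = True

    return FitResult(
        params=params, ci=ci, deviance=dev, log_likelihood=ll,
        threshold_75=params.threshold_75(), converged=bool(best.success),
        at_boundary=at_boundary, n_levels=int(np.count_nonzero(has_data)),
    )


def _report_transform(theta):
    """(log scale, log shape, lapse) -> (log threshold, log width, lapse)."""
    log_scale, log_shape, lapse = theta
    inv_k = np.exp(-log_shape)
    log_thr = log_scale + inv_k * np.log(_LN2)
    log_width = log_scale + np.log(_LN20**inv_k - _LN20_19**inv_k)
    return np.array([log_thr, log_width, lapse])


def _numeric_jacobian(f, x, eps=1e-6):
    f0 = np.asarray(f(x))
    jac = np.empty((f0.size, len(x)))
    for i in range(len(x)):
        xp = np.array(x, dtype=float)
        xp[i] += eps
        jac[:, i] = (np.asarray(f(xp)) - f0) / eps
    return jac


def _numeric_hessian(f, x, eps=1e-4):
    n = len(x)
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i] = eps
            xj[j] = eps
            h[i, j] = h[j, i] = (
                f(x + xi + xj) - f(x + xi) - f(x + xj) + f0
            ) / eps**2
    return h


def deviance_at(levels, counts, params: PsychometricParams) -> float:
    """Binomial deviance of counts at the given levels under ``params``."""
    levels = np.asarray(levels, dtype=float)
    counts = np.asarray(counts, dtype=float)
    k_corr, n_tot = counts[:, 0], counts[:, 1]
    mask = n_tot > 0
    p_hat = np.clip(psych_function(levels[mask], params), 1e-12, 1 - 1e-12)
    return float(2.0 * np.sum(_dev_terms(k_corr[mask], n_tot[mask], p_hat)))


def _dev_terms(k, n, p):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(k / (n * p)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log((n - k) / (n * (1 - p))), 0.0)
    return t1 + t2


@dataclass
class GoodnessOfFit:
    passed: bool
    observed_deviance: float
    percentile_95: float
    bootstrap_deviances: np.ndarray


def goodness_of_fit(fit: FitResult, counts, design: CSDesign,
                    n_boot: int = 10_000, seed=None,
                    lapse_prior=(1.0, 19.0)) -> GoodnessOfFit:
    """Parametric-bootstrap deviance test of a psychometric fit.

    Simulates ``n_boot`` datasets from the fitted curve, refits each, and
    compares the observed deviance with the 95th percentile of the bootstrap
    deviance distribution.  The fit passes iff observed <= percentile.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unstable 95th percentile", UserWarning)
    rng = np.random.default_rng(seed)
    levels = np.asarray(design.levels)
    counts = np.asarray(counts, dtype=float)
    n_tot = counts[:, 1].astype(int)
    p_fit = psych_function(levels, fit.params)

    obs_dev = deviance_at(levels, counts, fit.params)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        k_sim = rng.binomial(n_tot, p_fit)
        sim_counts = np.column_stack([k_sim, n_tot])
        refit = fit_psychometric(sim_counts, design, lapse_prior=lapse_prior,
                                 compute_ci=False)
        boot[b] = deviance_at(levels, sim_counts, refit.params)
    pct = float(np.percentile(boot, 95))
    return GoodnessOfFit(
        passed=bool(obs_dev <= pct), observed_deviance=obs_dev,
        percentile_95=pct, bootstrap_deviances=boot,
    )
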