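"""End-to-end orchestration: simulate, measure, cluster, compare, report.

Composes the other modules into the full analysis chain: a synthetic cohort
of thresholds and synchronization signals, adaptive staircase measurement per
participant and standard rate, optional constant-stimuli validation at 4 and
11.86 Hz, PLV clustering into high/low synchronizers, robust outlier
exclusion (median +/- 3 scaled MAD), the 149-model Bayesian comparison, and
cluster-demeaned rank correlations between measures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import model_comparison as mc
from . import psychometric as psy
from . import staircase as sc
from . import sync
from . import synthetic_data as synth

__all__ = [
    "PipelineConfig",
    "CohortReport",
    "mad_outlier_filter",
    "cycle_fraction",
    "demeaned_spearman",
    "run_full_pipeline",
]

MAD_SCALE = 1.4826  # normal-consistency constant


@dataclass
class MADFilterResult:
    keep: np.ndarray
    median: float
    mad_raw: float
    mad_scaled: float


def mad_outlier_filter(values, n_mad: float = 3.0) -> MADFilterResult:
    """Flag values outside median +/- n_mad * scaled MAD (strict inequality).

    The MAD is scaled by 1.4826 so that, for Gaussian data, it estimates the
    standard deviation.  Both the raw and scaled MAD are reported.  If all
    values are identical (MAD = 0 and nothing deviates) nothing is excluded
    and a warning is raised.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values for a MAD filter")
    med = float(np.median(v))
    mad_raw = float(np.median(np.abs(v - med)))
    mad_scaled = MAD_SCALE * mad_raw
    if np.ptp(v) == 0:
        warnings.warn("all values identical (MAD = 0); no exclusions", UserWarning)
        keep = np.ones(v.size, dtype=bool)
    else:
        keep = np.abs(v - med) <= n_mad * mad_scaled
    return MADFilterResult(keep=keep, median=med, mad_raw=mad_raw,
                           mad_scaled=mad_scaled)


def cycle_fraction(d: float, rate: float) -> tuple:
    """Express a relative rate difference as a fraction of the oscillatory cycle.

    For a comparison faster by a factor (1 + d), the period shortens from 1/r
    to 1/(r(1+d)); the difference is d/(1+d) of the standard period, i.e.
    (fraction, milliseconds) = (d/(1+d), fraction * 1000/r).
    """
    if d < 0 or rate <= 0:
        raise ValueError("d must be >= 0 and rate > 0")
    frac = d / (1.0 + d)
    return frac, frac * 1000.0 / rate


def _demean_by_group(x, groups):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for g in np.unique(groups):
        m = groups == g
        out[m] = x[m] - x[m].mean()
    return out


def demeaned_spearman(x, y, group_labels, covariate=None,
                      method: str = "auto", n_perm: int = 10_000,
                      seed=None) -> tuple:
    """Spearman correlation after demeaning both variables within clusters.

    Subtracting each cluster's mean removes the spurious association induced
    by bimodal group structure.  With ``covariate`` given, a partial rank
    correlation is computed: all three variables are demeaned and ranked, the
    covariate's contribution is regressed out of x and y, and the residuals
    are correlated.  p-values use the large-sample t approximation, or an
    exact-style permutation test (``method='permutation'``, automatic for
    n < 30 under ``method='auto'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(group_labels)
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    dx = _demean_by_group(x, groups)
    dy = _demean_by_group(y, groups)
    if np.ptp(dx) == 0 or np.ptp(dy) == 0:
        raise ValueError("a variable is constant after demeaning")

    if covariate is None:
        def statistic(yy):
            return stats.spearmanr(dx, yy).statistic
        rho = float(stats.spearmanr(dx, dy).statistic)
    else:
        dz = _demean_by_group(np.asarray(covariate, dtype=float), groups)
        rx, ry, rz = (stats.rankdata(v) for v in (dx, dy, dz))
        rz = (rz - rz.mean()) / rz.std()

        def _resid(r):
            return r - r.mean() - np.dot(r - r.mean(), rz) / rz.size * rz

        ex = _resid(rx)

        def statistic(yy):
            ry_l = stats.rankdata(yy)
            ey = _resid(ry_l)
            return float(np.corrcoef(ex, ey)[0, 1])
        rho = statistic(dy)

    n = x.size
    if method == "auto":
        method = "permutation" if n < 30 else "asymptotic"
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            stat = statistic(rng.permutation(dy))
            if abs(stat) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        dof = n - 2 - (1 if covariate is not None else 0)
        t = rho * np.sqrt(dof / max(1e-12, 1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort: synth.GenerativeSpec = field(default_factory=synth.GenerativeSpec)
    observer_width_factor: float = 1.0   # psychometric width = factor * true threshold
    observer_lapse: float = 0.02
    run_constant_stimuli: bool = True
    cs_rate_indices: tuple = (1, 6)      # 4 Hz and 11.86 Hz
    sync_duration_s: float = 70.0
    n_sync_runs: int = 2
    model_method: str = "quadrature"

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = synth.GenerativeSpec(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


@dataclass
class CohortReport:
    included: list
    excluded: dict                      # participant_id -> reason code
    cluster_labels: dict                # participant_id -> "high"/"low"
    cluster_centroids: tuple
    thresholds_wud: pd.DataFrame
    thresholds_cs: pd.DataFrame | None
    plv_table: pd.DataFrame
    family_probabilities: dict
    best_model: dict
    onset_earlier_in_low_prob: float
    correlations: dict
    group_tests: dict
    seeds: dict

    def to_json(self, path=None) -> str:
        payload = {
            "included": self.included,
            "excluded": self.excluded,
            "cluster_labels": self.cluster_labels,
            "cluster_centroids": list(self.cluster_centroids),
            "family_probabilities": self.family_probabilities,
            "best_model": self.best_model,
            "onset_earlier_in_low_prob": self.onset_earlier_in_low_prob,
            "correlations": self.correlations,
            "group_tests": self.group_tests,
            "seeds": self.seeds,
            "n_thresholds_wud": int(len(self.thresholds_wud)),
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _measure_wud(truth: pd.DataFrame, config: PipelineConfig, rng) -> pd.DataFrame:
    """Adaptive staircase estimate per participant x rate from simulated observers."""
    grid = mc.rate_grid().rates
    starts = sc.start_values(grid)
    rows = []
    for (pid, group, j), sub in truth.groupby(
            ["participant_id", "group", "group_j"], sort=False):
        for _, rec in sub.iterrows():
            r = int(rec["rate_index"])
            observer = synth.make_observer(
                rec["threshold"],
                config.observer_width_factor * rec["threshold"],
                config.observer_lapse,
            )
            cfg = sc.StaircaseConfig(start_value=float(starts[r - 1]))
            est, _ = sc.run_staircase(
                observer, cfg, seed=int(rng.integers(2**31 - 1)),
                rate_hz=float(rec["rate_hz"]),
            )
            rows.append((pid, group, int(j), r, float(rec["rate_hz"]),
                         est.threshold, est.n_trials, est.complete))
    return pd.DataFrame(rows, columns=[
        "participant_id", "group", "group_j", "rate_index", "rate_hz",
        "threshold", "n_trials", "complete",
    ])


def _measure_cs(truth: pd.DataFrame, wud: pd.DataFrame,
                config: PipelineConfig, rng) -> pd.DataFrame:
    rows = []
    for (pid, group), sub in truth.groupby(["participant_id", "group"], sort=False):
        for r in config.cs_rate_indices:
            rec = sub[sub["rate_index"] == r].iloc[0]
            wud_thr = float(wud[(wud["participant_id"] == pid)
                                & (wud["rate_index"] == r)]["threshold"].iloc[0])
            design = psy.CSDesign(standard_rate=float(rec["rate_hz"]),
                                  levels=tuple(psy.comparison_levels(wud_thr)))
            observer = synth.make_observer(
                rec["threshold"],
                config.observer_width_factor * rec["threshold"],
                config.observer_lapse,
            )
            counts = psy.simulate_cs_run(observer, design,
                                         seed=int(rng.integers(2**31 - 1)))
            fit = psy.fit_psychometric(counts, design)
            rows.append((pid, group, int(r), float(rec["rate_hz"]),
                         fit.threshold_75, fit.params.lapse, fit.deviance))
    return pd.DataFrame(rows, columns=[
        "participant_id", "group", "rate_index", "rate_hz",
        "threshold", "lapse", "deviance",
    ])


def _measure_sync(config: PipelineConfig, seed) -> pd.DataFrame:
    cohort = synth.draw_sync_cohort(
        n_high=config.cohort.n_high, n_low=config.cohort.n_low, seed=seed)
    rng = np.random.default_rng(seed + 1)
    sync_cfg = sync.SyncConfig()
    mean_plvs, run_plvs = [], []
    for _, rec in cohort.iterrows():
        runs = []
        for _ in range(config.n_sync_runs):
            pair = synth.synth_sync_pair(
                config.sync_duration_s, phase_jitter_sd=float(rec["jitter_sd"]),
                seed=int(rng.integers(2**31 - 1)))
            pa = sync.phase_series(pair.stimulus_envelope, pair.sample_rate, sync_cfg)
            pb = sync.phase_series(pair.produced_envelope, pair.sample_rate, sync_cfg)
            runs.append(sync.windowed_plv(pa, pb, sync_cfg).mean_plv)
        run_plvs.append(runs)
        mean_plvs.append(float(np.mean(runs)))
    cohort = cohort.copy()
    cohort["mean_plv"] = mean_plvs
    cohort["run_plvs"] = run_plvs
    return cohort


def run_full_pipeline(config: PipelineConfig) -> CohortReport:
    """Simulate a cohort and run the complete analysis chain on it.

    Every random stage draws its own seed from a seed sequence spawned off
    ``config.seed``, so reruns with the same configuration are identical.
    """
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(
                 ("cohort", "wud", "cs", "sync", "models"), root.spawn(5))}

    truth = synth.draw_threshold_dataset(
        synth.GenerativeSpec(**{**asdict(config.cohort), "seed": seeds["cohort"]}))

    wud = _measure_wud(truth, config, np.random.default_rng(seeds["wud"]))
    cs = (_measure_cs(truth, wud, config, np.random.default_rng(seeds["cs"]))
          if config.run_constant_stimuli else None)

    plv_table = _measure_sync(config, seeds["sync"])
    clusters = sync.cluster_synchronizers(plv_table["mean_plv"].to_numpy(),
                                          seed=seeds["sync"])
    plv_table["cluster"] = clusters.labels
    cluster_map = dict(zip(plv_table["participant_id"], clusters.labels))

    # exclusion: mean threshold per participant in each procedure
    excluded = {}
    wud_means = wud.groupby("participant_id", sort=False)["threshold"].mean()
    res = mad_outlier_filter(wud_means.to_numpy())
    for pid, keep in zip(wud_means.index, res.keep):
        if not keep:
            excluded[pid] = "wud_threshold_outlier"
    if cs is not None:
        cs_means = cs.groupby("participant_id", sort=False)["threshold"].mean()
        res_cs = mad_outlier_filter(cs_means.to_numpy())
        for pid, keep in zip(cs_means.index, res_cs.keep):
            if not keep:
                excluded.setdefault(pid, "cs_threshold_outlier")
    # run-consistency flag: the two sync runs straddle the centroid midpoint
    midpoint = float(np.mean(clusters.centroids))
    for pid, runs in zip(plv_table["participant_id"], plv_table["run_plvs"]):
        lo, hi = min(runs), max(runs)
        if lo < midpoint < hi:
            excluded.setdefault(pid, "inconsistent_sync_runs")

    included = [p for p in wud_means.index if p not in excluded]
    wud_in = wud[wud["participant_id"].isin(included)].copy()
    # model comparison uses the measured clusters, not the generative labels
    wud_in["group_j"] = wud_in["participant_id"].map(
        lambda p: 1 if cluster_map.get(p) == "high" else 2)

    posterior = mc.compare_models(
        wud_in[["participant_id", "group_j", "rate_index", "threshold"]],
        method=config.model_method, seed=seeds["models"])
    best_spec, best_p = posterior.best_model()
    onset_low_earlier = mc.marginal_event_probability(
        posterior,
        lambda s: (s.onset_low is not None and s.onset_low < s.onset_high),
    )

    correlations = {}
    if cs is not None:
        cs_in = cs[cs["participant_id"].isin(included)]
        cs_means_in = cs_in.groupby("participant_id", sort=False)["threshold"].mean()
        wud_at_cs = (wud_in[wud_in["rate_index"].isin(config.cs_rate_indices)]
                     .groupby("participant_id", sort=False)["threshold"].mean())
        common = [p for p in included
                  if p in cs_means_in.index and p in wud_at_cs.index]
        labels = np.array([cluster_map[p] for p in common])
        rho, p = demeaned_spearman(wud_at_cs.loc[common], cs_means_in.loc[common],
                                   labels, method="asymptotic")
        correlations["wud_vs_cs"] = {"rho": rho, "p": p}
    plv_in = plv_table[plv_table["participant_id"].isin(included)]
    wud_all_means = wud_in.groupby("participant_id", sort=False)["threshold"].mean()
    labels = np.array([cluster_map[p] for p in wud_all_means.index])
    rho, p = demeaned_spearman(
        wud_all_means.to_numpy(),
        plv_in.set_index("participant_id").loc[wud_all_means.index, "mean_plv"],
        labels, method="asymptotic")
    correlations["wud_vs_plv"] = {"rho": rho, "p": p}

    # group tests delegated to standard routines, reported for completeness
    hi_means = wud_all_means[labels == "high"]
    lo_means = wud_all_means[labels == "low"]
    group_tests = {}
    if len(hi_means) >= 3 and len(lo_means) >= 3:
        u = stats.mannwhitneyu(hi_means, lo_means, alternative="less")
        group_tests["wud_high_lower_than_low"] = {
            "statistic": float(u.statistic), "p": float(u.pvalue)}

    return CohortReport(
        included=included,
        excluded=excluded,
        cluster_labels=cluster_map,
        cluster_centroids=clusters.centroids,
        thresholds_wud=wud,
        thresholds_cs=cs,
        plv_table=plv_table.drop(columns=["run_plvs"]).assign(
            run_plv_min=[min(r) for r in plv_table["run_plvs"]],
            run_plv_max=[max(r) for r in plv_table["run_plvs"]],
        ),
        family_probabilities=posterior.family_probabilities(),
        best_model={
            "id": best_spec.id, "family": best_spec.family,
            "onset_high": best_spec.onset_high, "onset_low": best_spec.onset_low,
            "posterior_prob": best_p,
            "bayes_factor": mc.bayes_factor(best_p),
        },
        onset_earlier_in_low_prob=onset_low_earlier,
        correlations=correlations,
        group_tests=group_tests,
        seeds=seeds,
    )
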