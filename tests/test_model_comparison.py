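"""Model space, likelihood/prior arithmetic, marginal likelihoods, posteriors."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import logsumexp

from ratesync import model_comparison as mc
from ratesync import synthetic_data as synth


class TestRateGrid:
    def test_printed_values(self):
        g = mc.rate_grid()
        assert np.allclose(np.round(g.rates, 2),
                           [4.0, 5.57, 7.14, 8.71, 10.29, 11.86, 13.43, 15.0])
        assert g[1] == 4.0
        assert round(g[6], 2) == 11.86

    def test_constant_spacing(self):
        assert np.allclose(np.diff(mc.rate_grid().rates), 11 / 7)


class TestIndicatorVector:
    @pytest.mark.parametrize("onset, expected", [
        (2, [0, 1, 2, 3, 4, 5, 6, 7]),
        (5, [0, 0, 0, 0, 1, 2, 3, 4]),
        (8, [0, 0, 0, 0, 0, 0, 0, 1]),
    ])
    def test_values(self, onset, expected):
        assert mc.indicator_vector(onset).tolist() == expected

    def test_first_entry_always_zero(self):
        for onset in range(2, 9):
            assert mc.indicator_vector(onset)[0] == 0

    def test_out_of_range_rejected(self):
        for bad in (1, 9):
            with pytest.raises(ValueError):
                mc.indicator_vector(bad)


class TestEnumeration:
    def test_149_models_with_block_structure(self):
        models = mc.enumerate_models()
        assert len(models) == 149
        assert models[0].family == "NULL"
        assert models[1].family == "GROUP_BASELINE"
        fams = [m.family for m in models]
        assert fams.count("INCREASE") == 49
        assert fams.count("INCREASE_GROUP_BASELINE") == 49
        assert fams.count("INCREASE_GROUP_SLOPE") == 49
        assert [m.id for m in models] == list(range(1, 150))

    def test_m33_onset_pair(self):
        # baselines to 10.29 Hz (high) and 7.14 Hz (low): increase starts at
        # the next grid point, 11.86 Hz and 8.71 Hz
        m33 = mc.enumerate_models()[32]
        assert (m33.id, m33.family) == (33, "INCREASE")
        assert round(mc.rate_grid()[m33.onset_high], 2) == 11.86
        assert round(mc.rate_grid()[m33.onset_low], 2) == 8.71

    def test_parameter_counts(self):
        models = mc.enumerate_models()
        counts = {m.family: m.n_params for m in models}
        assert counts["NULL"] == 2
        assert counts["GROUP_BASELINE"] == 3
        assert counts["INCREASE"] == 3
        assert counts["INCREASE_GROUP_BASELINE"] == 4
        assert counts["INCREASE_GROUP_SLOPE"] == 4


class TestLikelihood:
    def test_single_record_closed_form(self):
        tab = pd.DataFrame({"participant_id": ["p"], "group_j": [1],
                            "rate_index": [1], "threshold": [1.0]})
        m = mc.ModelSpec(1, "NULL")
        ll = mc.log_likelihood(tab, m, {"mu": 1.0, "sigma2": 1.0})
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_scipy_lognorm_sum(self, small_cohort):
        m = mc.ModelSpec(3, "INCREASE", onset_high=2, onset_low=2)
        params = {"mu": 0.05, "beta": 0.01, "sigma2": 0.2}
        ll = mc.log_likelihood(small_cohort, m, params)
        x = mc.indicator_vector(2)
        oracle = sum(
            stats.lognorm.logpdf(r.threshold, s=np.sqrt(0.2),
                                 scale=0.05 + x[int(r.rate_index) - 1] * 0.01)
            for r in small_cohort.itertuples())
        assert ll == pytest.approx(oracle)

    def test_doubling_data_doubles_loglik(self, small_cohort):
        m = mc.ModelSpec(1, "NULL")
        params = {"mu": 0.06, "sigma2": 0.3}
        ll1 = mc.log_likelihood(small_cohort, m, params)
        ll2 = mc.log_likelihood(
            pd.concat([small_cohort, small_cohort], ignore_index=True),
            m, params)
        assert ll2 == pytest.approx(2 * ll1)

    def test_nesting_increase_with_zero_slope_equals_null(self, small_cohort):
        m_null = mc.ModelSpec(1, "NULL")
        m_inc = mc.ModelSpec(3, "INCREASE", onset_high=4, onset_low=6)
        for mu, s2 in ((0.04, 0.1), (0.08, 0.5)):
            assert mc.log_likelihood(small_cohort, m_inc,
                                     {"mu": mu, "beta": 0.0, "sigma2": s2}) == \
                pytest.approx(mc.log_likelihood(small_cohort, m_null,
                                                {"mu": mu, "sigma2": s2}))

    def test_location_reconciliation(self):
        m = mc.ModelSpec(3, "INCREASE", onset_high=4, onset_low=4)
        params = {"mu": 0.0448, "beta": 0.0144, "sigma2": 0.1}
        loc = mc.model_location(m, params, rate_idx=8, group_j=2)
        assert loc == pytest.approx(np.log(0.0448 + 5 * 0.0144))
        m1 = mc.ModelSpec(1, "NULL")
        assert mc.model_location(m1, {"mu": 0.05, "sigma2": 0.1}, 5, 1) == \
            pytest.approx(np.log(0.05))


class TestPriors:
    def test_printed_constants(self):
        pr = mc.PriorSpec()
        assert pr.var_mu0 == pytest.approx(2 * (0.5 - 0.001) ** 2 / 4)
        assert round(pr.var_mu0, 3) == 0.125
        assert round(pr.sigma2_upper, 2) == 9.66

    def test_uniform_sigma2_density(self):
        pr = mc.PriorSpec()
        m = mc.ModelSpec(1, "NULL")
        lp5 = mc.log_prior(m, {"mu": 0.05, "sigma2": 5.0}, pr)
        lp1 = mc.log_prior(m, {"mu": 0.05, "sigma2": 1.0}, pr)
        assert lp5 == pytest.approx(lp1)          # flat in sigma2
        assert mc.log_prior(m, {"mu": 0.05, "sigma2": 10.0}, pr) == -np.inf

    def test_negative_mu_excluded(self):
        m = mc.ModelSpec(1, "NULL")
        assert mc.log_prior(m, {"mu": -0.01, "sigma2": 1.0}) == -np.inf

    def test_truncated_normal_integrates_to_one(self):
        pr = mc.PriorSpec()
        mean, sd = pr.mean_prior("mu")
        val, _ = integrate.quad(
            lambda v: np.exp(mc._trunc_normal_logpdf(v, mean, sd)), 0, 20)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_group_baseline_prior_means(self):
        pr = mc.PriorSpec()
        assert pr.mean_prior("mu_high")[0] == 0.05
        assert pr.mean_prior("mu_low")[0] == 0.09
        assert pr.mean_prior("beta")[0] == 0.02


def _dense_grid_logml_null(tab, priors, n_mu=1200, n_sig=1200):
    """Brute-force trapezoid integration for the 2-parameter constant model."""
    d = tab["threshold"].to_numpy()
    logd = np.log(d)
    mus = np.linspace(1e-7, priors.mean_upper, n_mu)
    sigs = np.linspace(1e-7, priors.sigma2_upper, n_sig)
    m0, s0 = priors.mean_prior("mu")
    lp_mu = mc._trunc_normal_logpdf(mus, m0, s0)
    ss = ((logd[:, None] - np.log(mus)[None, :]) ** 2).sum(axis=0)
    ll = (-0.5 * d.size * np.log(2 * np.pi * sigs)[None, :]
          - logd.sum() - ss[:, None] / (2 * sigs[None, :]))
    w_mu = np.full(n_mu, mus[1] - mus[0]); w_mu[[0, -1]] *= 0.5
    w_s = np.full(n_sig, sigs[1] - sigs[0]); w_s[[0, -1]] *= 0.5
    mat = (ll + lp_mu[:, None] - np.log(priors.sigma2_upper)
           + np.log(w_mu)[:, None] + np.log(w_s)[None, :])
    return float(logsumexp(mat))


class TestMarginalLikelihood:
    def test_quadrature_matches_dense_grid_oracle(self, small_cohort):
        pr = mc.PriorSpec()
        got = mc.marginal_likelihood(small_cohort, mc.ModelSpec(1, "NULL")).log_ml
        oracle = _dense_grid_logml_null(small_cohort, pr)
        assert got == pytest.approx(oracle, abs=0.05)

    def test_bridge_agrees_with_quadrature(self, small_cohort):
        m = mc.ModelSpec(3, "INCREASE", onset_high=2, onset_low=2)
        q = mc.marginal_likelihood(small_cohort, m).log_ml
        b = mc.marginal_likelihood(small_cohort, m, method="bridge", seed=11)
        assert b.log_ml == pytest.approx(q, abs=0.1)
        assert np.all(b.diagnostics["rhat"] < 1.1)

    def test_occam_penalty_for_irrelevant_slope(self):
        # data generated with beta=0: the extra slope parameter should lower
        # the marginal likelihood on average
        diffs = []
        for seed in range(6):
            spec = synth.GenerativeSpec(
                family="NULL", mu_high=0.05, mu_low=0.05,
                beta_high=0.0, beta_low=0.0, onset_high=None, onset_low=None,
                sigma2=0.15, n_high=20, n_low=15, seed=seed)
            tab = synth.draw_threshold_dataset(spec)
            null_ml = mc.marginal_likelihood(tab, mc.ModelSpec(1, "NULL")).log_ml
            inc_ml = mc.marginal_likelihood(
                tab, mc.ModelSpec(3, "INCREASE", onset_high=2, onset_low=2)).log_ml
            diffs.append(null_ml - inc_ml)
        assert np.mean(diffs) > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mc.marginal_likelihood(pd.DataFrame(columns=["threshold"]),
                                   mc.ModelSpec(1, "NULL"))


class TestPosterior:
    def test_equal_logml_gives_uniform(self):
        post = mc.posterior_model_probabilities(np.zeros(149))
        assert np.allclose(post.posterior_probs, 1 / 149)
        assert post.posterior_probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dominating_model(self):
        lm = np.zeros(149)
        lm[32] = 50.0
        post = mc.posterior_model_probabilities(lm)
        assert post.posterior_probs[32] == pytest.approx(1.0, abs=1e-12)
        assert post.best_model()[0].id == 33

    def test_shift_invariance(self, rng):
        lm = rng.normal(size=149)
        p1 = mc.posterior_model_probabilities(lm).posterior_probs
        p2 = mc.posterior_model_probabilities(lm + 123.4).posterior_probs
        assert np.allclose(p1, p2)

    def test_all_neginf_rejected(self):
        with pytest.raises(ValueError):
            mc.posterior_model_probabilities(np.full(149, -np.inf))


class TestBayesFactor:
    @pytest.mark.parametrize("p, expected, nd", [
        (0.7453, 2.93, 2), (0.8797, 7.31, 2), (0.2861, 0.4, 1), (0.5, 1.0, 2),
    ])
    def test_posterior_odds_transform(self, p, expected, nd):
        assert round(mc.bayes_factor(p), nd) == expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            mc.bayes_factor(1.0)


class TestEventProbability:
    def test_counting_under_uniform_posterior(self):
        post = mc.posterior_model_probabilities(np.zeros(149))
        p_inc = mc.marginal_event_probability(
            post, lambda s: s.family == "INCREASE")
        assert p_inc == pytest.approx(49 / 149)
        assert mc.marginal_event_probability(post, lambda s: True) == \
            pytest.approx(1.0)

    def test_onset_order_events_partition(self):
        post = mc.posterior_model_probabilities(np.zeros(149))
        lt = mc.marginal_event_probability(
            post, lambda s: s.onset_low is not None and s.onset_low < s.onset_high)
        ge = mc.marginal_event_probability(
            post, lambda s: s.onset_low is not None and s.onset_low >= s.onset_high)
        none = mc.marginal_event_probability(post, lambda s: s.onset_low is None)
        assert lt + ge + none == pytest.approx(1.0)

    def test_empty_event_warns(self):
        post = mc.posterior_model_probabilities(np.zeros(149))
        with pytest.warns(UserWarning):
            assert mc.marginal_event_probability(post, lambda s: False) == 0.0

    def test_onset_heatmap_sums_to_increase_mass(self):
        post = mc.posterior_model_probabilities(np.zeros(149))
        heat = post.onset_heatmap()
        assert heat.shape == (7, 7)
        assert heat.sum() == pytest.approx(147 / 149)


class TestFitParameters:
    def test_quadrature_and_mcmc_agree(self, small_cohort):
        m = mc.ModelSpec(3, "INCREASE", onset_high=6, onset_low=4)
        q = mc.fit_parameters(small_cohort, m)
        s = mc.fit_parameters(small_cohort, m, method="mcmc", seed=3)
        for name in ("mu", "beta", "sigma2"):
            sd = (q.summaries[name]["ci_high"] - q.summaries[name]["ci_low"]) / 4
            assert abs(q.summaries[name]["mean"] - s.summaries[name]["mean"]) \
                < max(0.5 * sd, 0.01)

    def test_interval_brackets_mean(self, small_cohort):
        m = mc.ModelSpec(1, "NULL")
        res = mc.fit_parameters(small_cohort, m)
        for v in res.summaries.values():
            assert v["ci_low"] <= v["mean"] <= v["ci_high"]

    def test_concentrates_on_truth_at_small_variance(self):
        spec = synth.GenerativeSpec(
            family="NULL", mu_high=0.05, mu_low=0.05, beta_high=0.0,
            beta_low=0.0, onset_high=None, onset_low=None,
            sigma2=0.001, n_high=30, n_low=20, seed=4)
        tab = synth.draw_threshold_dataset(spec)
        res = mc.fit_parameters(tab, mc.ModelSpec(1, "NULL"))
        assert res.summaries["mu"]["mean"] == pytest.approx(0.05, rel=0.02)
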