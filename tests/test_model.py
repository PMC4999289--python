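import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import nmareg
from nmareg.data import ArmTable, build_network
from nmareg.model import (
    ConvergenceWarning,
    MCMCConfig,
    ModelSpec,
    ParameterState,
    _Design,
    fit_nma,
    log_joint,
    relative_effects,
)
from nmareg.simulate import SimConfig, simulate_network

from conftest import quick_mcmc


def _toy_state(net, rng=None):
    rng = rng or np.random.default_rng(0)
    des = _Design(net)
    return ParameterState(
        mu=rng.normal(-2, 0.3, des.S),
        delta=rng.normal(0, 0.3, des.nD),
        d=np.concatenate([[0.0], rng.normal(0, 0.3, des.K - 1)]),
        sigma=0.3,
        beta=0.0,
    )


def _oracle_log_joint(state, net, spec):
    """Independent evaluation: scipy binom pmfs + explicit prior densities."""
    des = _Design(net)
    total = 0.0
    # likelihood, arm by arm, from first principles
    dfull = np.zeros(des.A)
    dfull[des.nb_pos] = state.delta
    if spec.effect == "FE":
        dfull = state.d[des.t_idx] - state.d[des.b_idx]
    for a in range(des.A):
        logit = state.mu[des.s_idx[a]] + dfull[a]
        total += stats.binom.logpmf(des.r[a], des.n[a], expit(logit))
    total += stats.norm.logpdf(state.mu, spec.prior_effect_mean, spec.prior_effect_sd).sum()
    total += stats.norm.logpdf(state.d[1:], spec.prior_effect_mean, spec.prior_effect_sd).sum()
    if spec.effect == "RE":
        total += np.log(1.0 / spec.sd_prior_upper)
        for s in range(des.S):
            idx = des.nb_s == s
            mvec = state.d[des.nb_t[idx]] - state.d[des.nb_b[idx]]
            m = int(idx.sum())
            cov = state.sigma**2 * (0.5 * np.eye(m) + 0.5 * np.ones((m, m)))
            total += stats.multivariate_normal.logpdf(state.delta[idx], mvec, cov)
    return float(total)


class TestLogJoint:
    def test_matches_brute_force_oracle_re(self, toy_network):
        spec = ModelSpec(effect="RE")
        state = _toy_state(toy_network)
        got = log_joint(state, toy_network, spec)
        want = _oracle_log_joint(state, toy_network, spec)
        assert got == pytest.approx(want, abs=1e-10)

    def test_matches_brute_force_oracle_fe(self, toy_network):
        spec = ModelSpec(effect="FE")
        state = _toy_state(toy_network)
        got = log_joint(state, toy_network, spec)
        want = _oracle_log_joint(state, toy_network, spec)
        assert got == pytest.approx(want, abs=1e-10)

    def test_symmetric_arm_maximized_at_logit_zero(self):
        # one arm with r = n/2: its likelihood peaks where logit(p) = 0
        arms = ArmTable(
            pd.DataFrame(
                {
                    "study": ["A", "A"],
                    "treatment": ["p", "t"],
                    "r": [50, 50],
                    "n": [100, 100],
                }
            )
        )
        des = _Design(build_network(arms))
        grid = np.linspace(-2, 2, 401)
        vals = [des.arm_loglik(np.array([g, g]))[0] for g in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.0, abs=1e-9)

    def test_zero_event_arm_closed_form(self, toy_network):
        # the r = 0 arm contributes n*log(1-p), finite for p < 1
        des = _Design(toy_network)
        zero = np.flatnonzero(des.r == 0)[0]
        logits = np.full(des.A, -1.2)
        ll = des.arm_loglik(logits)
        expected = des.n[zero] * np.log(1.0 - expit(-1.2))
        assert ll[zero] == pytest.approx(expected, abs=1e-10)
        assert np.isfinite(ll).all()

    def test_zero_cells_never_nonfinite(self, toy_network):
        spec = ModelSpec(effect="RE")
        rng = np.random.default_rng(4)
        for _ in range(20):
            state = _toy_state(toy_network, rng)
            assert np.isfinite(log_joint(state, toy_network, spec))

    def test_nonfinite_state_rejected(self, toy_network):
        state = _toy_state(toy_network)
        state.mu[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            log_joint(state, toy_network, ModelSpec())

    def test_delta_prior_matches_scipy_mvn(self, toy_network):
        # closed-form correlated prior vs scipy on the 3-arm study
        des = _Design(toy_network)
        rng = np.random.default_rng(1)
        delta = rng.normal(0, 0.5, des.nD)
        d = np.array([0.0, -0.4, -0.2])
        got = des.delta_prior(delta, d, 0.37)
        for s in range(des.S):
            idx = des.nb_s == s
            m = int(idx.sum())
            mvec = d[des.nb_t[idx]] - d[des.nb_b[idx]]
            cov = 0.37**2 * (0.5 * np.eye(m) + 0.5 * np.ones((m, m)))
            want = stats.multivariate_normal.logpdf(delta[idx], mvec, cov)
            assert got[s] == pytest.approx(want, abs=1e-10)


class TestParameterState:
    def test_reference_effect_must_be_zero(self):
        with pytest.raises(ValueError):
            ParameterState(mu=[0.0], delta=[0.0], d=[0.1, 0.0])

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            ParameterState(mu=[0.0], delta=[0.0], d=[0.0, 1.0], sigma=-0.1)


class TestFitNMA:
    def test_large_trial_recovers_empirical_log_or(self):
        # large-sample oracle: posterior median of d2 ~= observed log-OR
        arms = ArmTable(
            pd.DataFrame(
                {
                    "study": ["A", "A"],
                    "treatment": ["plb", "act"],
                    "r": [5000, 3000],
                    "n": [100_000, 100_000],
                }
            )
        )
        net = build_network(arms)
        fit = fit_nma(net, ModelSpec(effect="FE"), quick_mcmc(burn_in=1500, samples=1500))
        emp = np.log(3000 / 97_000) - np.log(5000 / 95_000)
        assert fit.median("d[act]") == pytest.approx(emp, abs=0.02)

    def test_sigma_discriminates_simulated_heterogeneity(self):
        medians = {}
        for sig in (0.0, 0.5):
            cfg = SimConfig(seed=13, true_sigma=sig, n_studies=14, arm_n=(400, 900))
            arms, _, _ = simulate_network(cfg)
            net = build_network(arms, cfg.coding)
            fit = fit_nma(net, ModelSpec(effect="RE"), quick_mcmc(seed=3))
            medians[sig] = fit.median("sigma")
        assert medians[0.0] < medians[0.5]
        assert medians[0.5] > 0.2

    def test_unconverged_fit_warns_not_silent(self, small_sim):
        cfg, arms, _, _ = small_sim
        net = build_network(arms, cfg.coding)
        mcmc = MCMCConfig(chains=3, burn_in=0, samples=40, seed=0)
        with pytest.warns(ConvergenceWarning):
            fit = fit_nma(net, ModelSpec(effect="RE"), mcmc)
        assert not fit.converged

    def test_covariate_mode_rejected(self, toy_network):
        with pytest.raises(ValueError):
            fit_nma(toy_network, ModelSpec(covariate_mode="covariate"), quick_mcmc())

    def test_exchangeability_of_nonreference_labels(self, small_sim):
        # relabeling non-reference treatments permutes d identically
        cfg, arms, _, _ = small_sim
        names = list(cfg.treatment_names)
        swapped = [names[0], names[1], names[3], names[2]]  # swap T3 <-> T4
        fit_a = fit_nma(
            build_network(arms, cfg.coding), ModelSpec(), quick_mcmc(seed=21)
        )
        fit_b = fit_nma(
            build_network(arms, nmareg.TreatmentCoding(tuple(swapped))),
            ModelSpec(),
            quick_mcmc(seed=22),
        )
        for name in names[1:]:
            assert fit_a.median(f"d[{name}]") == pytest.approx(
                fit_b.median(f"d[{name}]"), abs=0.06
            )

    def test_prior_mean_zero_vs_one_insensitive(self, small_sim):
        cfg, arms, _, _ = small_sim
        net = build_network(arms, cfg.coding)
        fit0 = fit_nma(net, ModelSpec(prior_effect_mean=0.0), quick_mcmc(seed=31))
        fit1 = fit_nma(net, ModelSpec(prior_effect_mean=1.0), quick_mcmc(seed=32))
        for name in cfg.treatment_names[1:]:
            assert fit0.median(f"d[{name}]") == pytest.approx(
                fit1.median(f"d[{name}]"), abs=0.06
            )
        assert fit0.median("sigma") == pytest.approx(fit1.median("sigma"), abs=0.06)


class TestRelativeEffects:
    def test_antisymmetry_draw_by_draw(self, small_sim_fit):
        d = small_sim_fit.pooled("d")
        fwd = d[:, 2] - d[:, 1]
        np.testing.assert_array_equal(fwd, -(d[:, 1] - d[:, 2]))
        league = relative_effects(small_sim_fit)
        row = league[(league.treat_a == "anchor") & (league.treat_b == "T3")].iloc[0]
        assert row.log_or_median == pytest.approx(np.median(fwd), abs=1e-12)

    def test_consistency_draw_by_draw(self, small_sim_fit):
        d = small_sim_fit.pooled("d")
        ab = d[:, 1] - d[:, 0]
        bc = d[:, 2] - d[:, 1]
        ac = d[:, 2] - d[:, 0]
        np.testing.assert_allclose(ab + bc, ac, atol=1e-12)

    def test_row_count_and_or_columns(self, small_sim_fit):
        league = relative_effects(small_sim_fit)
        k = small_sim_fit.network.coding.n_treatments
        assert len(league) == k * (k - 1) // 2
        np.testing.assert_allclose(
            league["or_median"], np.exp(league["log_or_median"]), rtol=1e-12
        )


class TestMCMCConfig:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(chains=1)

    def test_from_yaml(self, tmp_path):
        p = tmp_path / "mcmc.yaml"
        p.write_text("chains: 2\nburn_in: 10\nsamples: 20\nseed: 4\n")
        cfg = MCMCConfig.from_file(p)
        assert cfg.chains == 2 and cfg.samples == 20

    def test_defaults_match_reported_run_length(self):
        cfg = MCMCConfig()
        assert (cfg.chains, cfg.burn_in, cfg.samples) == (3, 50_000, 50_000)
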