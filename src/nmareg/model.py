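"""Binomial-logit network meta-analysis: joint density, sampler, effects.

Model
-----
For arm k of study i, ``r_ik ~ Binomial(n_ik, p_ik)`` with

    logit(p_ik) = mu_i                      (baseline arm)
    logit(p_ik) = mu_i + delta_ik + beta * x_i * w_ik   (other arms)

where ``w_ik = I(t_ik != 1) - I(t_i,base != 1)`` so the interaction is common
to every treatment versus the reference and cancels in contrasts between two
non-reference arms.  Fixed effect: ``delta_ik = d[t_ik] - d[t_i,base]``.
Random effects: the vector of within-study contrasts is multivariate normal
around those differences with variance ``sigma^2`` and pairwise correlation
1/2 (the standard multi-arm construction).

Priors: ``mu_i, d_k ~ Normal(m0, sd0^2)`` (vague, defaults ``m0=0, sd0=100``),
``sigma ~ Uniform(0, upper)``, ``beta ~ Normal(0, 100^2)``.

Sampling is adaptive random-walk Metropolis-within-Gibbs: study-level block
updates for ``mu`` and ``delta`` (vectorized across studies, which are
conditionally independent), scalar updates for each ``d_k``, ``sigma`` and
``beta``; proposal scales adapt toward 0.44 acceptance during burn-in only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, gammaln

from .data import TreatmentNetwork

__all__ = [
    "ModelSpec",
    "MCMCConfig",
    "ParameterState",
    "PosteriorFit",
    "ConvergenceWarning",
    "log_joint",
    "fit_nma",
    "relative_effects",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Effect structure, covariate mode and prior settings."""

    effect: Literal["FE", "RE"] = "RE"
    covariate_mode: Literal["none", "covariate", "baseline_risk"] = "none"
    prior_effect_mean: float = 0.0
    prior_effect_sd: float = 100.0
    sd_prior_upper: float = 2.0

    def __post_init__(self) -> None:
        if self.prior_effect_sd <= 0 or self.sd_prior_upper <= 0:
            raise ValueError("prior scale parameters must be positive")
        if self.effect not in ("FE", "RE"):
            raise ValueError(f"unknown effect structure {self.effect!r}")
        if self.covariate_mode not in ("none", "covariate", "baseline_risk"):
            raise ValueError(f"unknown covariate mode {self.covariate_mode!r}")


@dataclass(frozen=True)
class MCMCConfig:
    chains: int = 3
    burn_in: int = 50_000
    samples: int = 50_000
    thin: int = 1
    seed: int = 0
    convergence_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for convergence checking")
        if self.samples < 1 or self.burn_in < 0 or self.thin < 1:
            raise ValueError("invalid MCMC sizes")

    @classmethod
    def from_file(cls, path: str | Path) -> "MCMCConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "chains": self.chains,
            "burn_in": self.burn_in,
            "samples": self.samples,
            "thin": self.thin,
            "seed": self.seed,
            "convergence_threshold": self.convergence_threshold,
        }


@dataclass
class ParameterState:
    """One point in parameter space (see module docstring for roles)."""

    mu: np.ndarray
    delta: np.ndarray
    d: np.ndarray
    sigma: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.d[0] != 0.0:
            raise ValueError("d[0] (reference treatment) must be exactly 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


class _Design:
    """Flat arrays extracted from a network, in study-major arm order."""

    def __init__(self, net: TreatmentNetwork):
        rows = []
        for s_i, study in enumerate(net.studies):
            grp = net.arms_of(study).sort_values("code")
            base = net.study_baseline[study]
            for row in grp.itertuples(index=False):
                rows.append((s_i, row.code - 1, base - 1, row.r, row.n))
        arr = np.array(rows, dtype=int)
        self.s_idx = arr[:, 0]
        self.t_idx = arr[:, 1]
        self.b_idx = arr[:, 2]
        self.r = arr[:, 3].astype(float)
        self.n = arr[:, 4].astype(float)
        self.A = len(rows)
        self.S = net.n_studies
        self.K = net.coding.n_treatments
        self.lgam = gammaln(self.n + 1) - gammaln(self.r + 1) - gammaln(self.n - self.r + 1)
        self.nb = self.t_idx != self.b_idx  # non-baseline arms
        self.nb_pos = np.flatnonzero(self.nb)
        self.nD = int(self.nb.sum())
        self.nb_s = self.s_idx[self.nb]  # study of each delta element
        self.nb_t = self.t_idx[self.nb]
        self.nb_b = self.b_idx[self.nb]
        self.m = np.bincount(self.nb_s, minlength=self.S).astype(float)  # contrasts/study
        # interaction indicator: 1 only when the arm is active and the study
        # baseline is the reference treatment
        self.w = ((self.t_idx != 0).astype(float) - (self.b_idx != 0).astype(float))
        self.net = net

    def arm_loglik(self, logits: np.ndarray) -> np.ndarray:
        return self.r * logits - self.n * np.logaddexp(0.0, logits) + self.lgam

    def delta_full(self, delta: np.ndarray) -> np.ndarray:
        out = np.zeros(self.A)
        out[self.nb_pos] = delta
        return out

    def fe_delta(self, d: np.ndarray) -> np.ndarray:
        return d[self.t_idx] - d[self.b_idx]

    def logits(self, mu, delta_full, beta, x, mode, center) -> np.ndarray:
        lp = mu[self.s_idx] + delta_full
        if mode == "covariate":
            lp = lp + beta * x[self.s_idx] * self.w
        elif mode == "baseline_risk":
            lp = lp + beta * (mu[self.s_idx] - center) * self.w
        return lp

    def delta_prior(self, delta, d, sigma) -> np.ndarray:
        """Per-study log density of the correlated multi-arm normal.

        Sigma = sigma^2/2 * (I + 11'); det = (sigma^2/2)^m (m+1);
        inverse = 2/sigma^2 (I - 11'/(m+1)).
        """
        e = delta - (d[self.nb_t] - d[self.nb_b])
        se = np.bincount(self.nb_s, weights=e, minlength=self.S)
        se2 = np.bincount(self.nb_s, weights=e * e, minlength=self.S)
        s2 = sigma * sigma
        quad = (se2 - se * se / (self.m + 1.0)) / s2
        logdet = self.m * np.log(s2 / 2.0) + np.log(self.m + 1.0)
        return -0.5 * (self.m * _LOG_2PI + logdet) - quad


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x, dtype=float) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def log_joint(
    state: ParameterState,
    net: TreatmentNetwork,
    spec: ModelSpec,
    x: np.ndarray | None = None,
    center: float = 0.0,
    beta_prior: tuple[float, float] = (0.0, 100.0),
) -> float:
    """Log prior + log likelihood (fully normalized) at ``state``.

    ``x`` is the centered per-study covariate (covariate mode only); the
    baseline-risk mode uses ``state.mu - center`` instead.  Zero-event arms
    contribute ``n * log(1 - p)`` with no continuity correction.

    Note: in baseline-risk mode the sampler additionally places an
    exchangeable hierarchy on ``mu`` (hyperparameters not part of
    :class:`ParameterState`); this function evaluates the density with the
    vague independent ``mu`` priors of the other modes.
    """
    des = _Design(net)
    for arr in (state.mu, state.delta, state.d, [state.sigma, state.beta]):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite parameter value in state")
    if spec.covariate_mode == "covariate":
        if x is None or len(x) != des.S:
            raise ValueError("covariate vector missing or wrong length")
        x = np.asarray(x, dtype=float)

    if spec.effect == "FE":
        dfull = des.fe_delta(state.d)
    else:
        if len(state.delta) != des.nD:
            raise ValueError(f"delta has length {len(state.delta)}, expected {des.nD}")
        dfull = des.delta_full(state.delta)
    lp = des.logits(state.mu, dfull, state.beta, x, spec.covariate_mode, center)
    total = float(des.arm_loglik(lp).sum())

    m0, sd0 = spec.prior_effect_mean, spec.prior_effect_sd
    total += float(_norm_logpdf(state.mu, m0, sd0).sum())
    total += float(_norm_logpdf(state.d[1:], m0, sd0).sum())
    if spec.effect == "RE":
        if not 0.0 < state.sigma < spec.sd_prior_upper:
            return -np.inf
        total += -np.log(spec.sd_prior_upper)  # U(0, upper) density
        total += float(des.delta_prior(state.delta, state.d, state.sigma).sum())
    if spec.covariate_mode != "none":
        total += float(_norm_logpdf(state.beta, beta_prior[0], beta_prior[1]))
    return total


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    x = (x - lo) % (2.0 * span)
    return lo + (span - abs(x - span))


def _run_chain(des: _Design, spec, x, center, beta_prior, cfg: MCMCConfig, rng):
    S, K, nD = des.S, des.K, des.nD
    m0, sd0 = spec.prior_effect_mean, spec.prior_effect_sd
    mode = spec.covariate_mode
    re = spec.effect == "RE"
    has_beta = mode != "none"
    # Baseline-risk regression needs exchangeable baselines mu_i ~ N(b, tau^2):
    # with independent vague mu priors the latent covariate is a functional
    # measurement-error model and regression dilution is NOT removed.
    hier = mode == "baseline_risk"

    # overdispersed start: priors truncated to |value| <= 5 on the log-odds scale
    mu = np.clip(rng.normal(m0, sd0, S), -5.0, 5.0) * rng.uniform(0.2, 1.0, S)
    mu = np.clip(mu, -5.0, 5.0)
    d = np.zeros(K)
    d[1:] = np.clip(rng.normal(m0, sd0, K - 1), -5.0, 5.0) * rng.uniform(0.2, 1.0, K - 1)
    sigma = rng.uniform(0.05, min(1.0, spec.sd_prior_upper)) if re else 0.0
    beta = rng.uniform(-0.5, 0.5) if has_beta else 0.0
    delta = (d[des.nb_t] - d[des.nb_b]) + rng.normal(0.0, 0.2, nD) if re else np.zeros(nD)
    b_mu = float(mu.mean()) if hier else 0.0
    tau = rng.uniform(0.2, 1.0) if hier else 0.0

    def cur_logits(mu_, dfull_, beta_):
        return des.logits(mu_, dfull_, beta_, x, mode, center)

    dfull = des.delta_full(delta) if re else des.fe_delta(d)
    logits = cur_logits(mu, dfull, beta)
    ll = des.arm_loglik(logits)
    pri_delta = des.delta_prior(delta, d, sigma) if re else np.zeros(S)

    step_mu = np.full(S, 0.4)
    step_de = np.full(S, 0.4)
    step_d = np.full(K - 1, 0.4)
    step_sig, step_beta, step_scale = 0.2, 0.3, 0.5
    step_tau, step_tscale = 0.2, 0.4
    step_dt = np.full(K - 1, 0.4)
    dshift = {
        k: (des.nb_t == k).astype(float) - (des.nb_b == k).astype(float)
        for k in range(1, K)
    }

    n_keep = cfg.samples // cfg.thin
    out = {
        "mu": np.empty((n_keep, S)),
        "delta": np.empty((n_keep, nD)),
        "d": np.empty((n_keep, K)),
        "sigma": np.empty(n_keep),
        "beta": np.empty(n_keep),
        "baseline_mean": np.empty(n_keep),
        "baseline_sd": np.empty(n_keep),
        "p": np.empty((n_keep, des.A)),
    }
    kept = 0
    total_iter = cfg.burn_in + cfg.samples
    for it in range(total_iter):
        adapting = it < cfg.burn_in
        gam = 2.0 / (1.0 + it) ** 0.55 if adapting else 0.0

        # -- mu block (studies conditionally independent) -------------------
        prop = mu + step_mu * rng.standard_normal(S)
        lp_p = cur_logits(prop, dfull, beta)
        ll_p = des.arm_loglik(lp_p)
        dll = np.bincount(des.s_idx, weights=ll_p - ll, minlength=S)
        if hier:
            dpri = _norm_logpdf(prop, b_mu, tau) - _norm_logpdf(mu, b_mu, tau)
        else:
            dpri = _norm_logpdf(prop, m0, sd0) - _norm_logpdf(mu, m0, sd0)
        acc = np.log(rng.uniform(size=S)) < dll + dpri
        if acc.any():
            mu = np.where(acc, prop, mu)
            arm_acc = acc[des.s_idx]
            logits = np.where(arm_acc, lp_p, logits)
            ll = np.where(arm_acc, ll_p, ll)
        if adapting:
            step_mu *= np.exp(gam * (acc.astype(float) - 0.44))

        # -- baseline hyperparameters (baseline-risk mode) ------------------
        if hier:
            # Gibbs for b: normal likelihood of mu around b, N(m0, sd0) prior
            prec = S / (tau * tau) + 1.0 / (sd0 * sd0)
            mean = (mu.sum() / (tau * tau) + m0 / (sd0 * sd0)) / prec
            b_mu = mean + rng.standard_normal() / np.sqrt(prec)

            tp = _reflect(tau + step_tau * rng.standard_normal(), 0.0, spec.sd_prior_upper)
            log_acc = float(
                (_norm_logpdf(mu, b_mu, tp) - _norm_logpdf(mu, b_mu, tau)).sum()
            )
            accepted = 0.0
            if np.log(rng.uniform()) < log_acc:
                tau, accepted = tp, 1.0
            if adapting:
                step_tau *= np.exp(gam * (accepted - 0.44))

            # joint rescale of (tau, mu residuals) through the funnel; the
            # mu-prior change cancels against the Jacobian e^{z(1+S)}
            z = step_tscale * rng.standard_normal()
            tp = tau * np.exp(z)
            accepted = 0.0
            if 0.0 < tp < spec.sd_prior_upper:
                prop = b_mu + np.exp(z) * (mu - b_mu)
                lp_p = cur_logits(prop, dfull, beta)
                ll_p = des.arm_loglik(lp_p)
                log_acc = (
                    float((ll_p - ll).sum())
                    + float(
                        (_norm_logpdf(prop, b_mu, tp) - _norm_logpdf(mu, b_mu, tau)).sum()
                    )
                    + z * (1.0 + S)
                )
                if np.log(rng.uniform()) < log_acc:
                    tau, mu, logits, ll, accepted = tp, prop, lp_p, ll_p, 1.0
            if adapting:
                step_tscale *= np.exp(gam * (accepted - 0.44))

        # -- delta block (RE) ----------------------------------------------
        if re:
            prop_d = delta + step_de[des.nb_s] * rng.standard_normal(nD)
            dfull_p = des.delta_full(prop_d)
            lp_p = cur_logits(mu, dfull_p, beta)
            ll_p = des.arm_loglik(lp_p)
            dll = np.bincount(des.s_idx, weights=ll_p - ll, minlength=S)
            pri_p = des.delta_prior(prop_d, d, sigma)
            acc = np.log(rng.uniform(size=S)) < dll + pri_p - pri_delta
            if acc.any():
                delta = np.where(acc[des.nb_s], prop_d, delta)
                dfull = des.delta_full(delta)
                arm_acc = acc[des.s_idx]
                logits = np.where(arm_acc, lp_p, logits)
                ll = np.where(arm_acc, ll_p, ll)
                pri_delta = np.where(acc, pri_p, pri_delta)
            if adapting:
                step_de *= np.exp(gam * (acc.astype(float) - 0.44))

        # -- basic effects d_k ---------------------------------------------
        for k in range(1, K):
            dp = d.copy()
            dp[k] = d[k] + step_d[k - 1] * rng.standard_normal()
            dpri_k = float(_norm_logpdf(dp[k], m0, sd0) - _norm_logpdf(d[k], m0, sd0))
            if re:
                pri_p = des.delta_prior(delta, dp, sigma)
                log_acc = float((pri_p - pri_delta).sum()) + dpri_k
                if np.log(rng.uniform()) < log_acc:
                    d = dp
                    pri_delta = pri_p
                    accepted = 1.0
                else:
                    accepted = 0.0
                if adapting:
                    step_d[k - 1] *= np.exp(gam * (accepted - 0.44))

                # translation move: drag the trial effects along with d_k so
                # the residuals (and hence the RE prior) are untouched;
                # essential when sigma is small and delta hugs the contrasts
                z = step_dt[k - 1] * rng.standard_normal()
                dp = d.copy()
                dp[k] = d[k] + z
                prop_d = delta + z * dshift[k]
                dfull_p = des.delta_full(prop_d)
                lp_p = cur_logits(mu, dfull_p, beta)
                ll_p = des.arm_loglik(lp_p)
                log_acc = float((ll_p - ll).sum()) + float(
                    _norm_logpdf(dp[k], m0, sd0) - _norm_logpdf(d[k], m0, sd0)
                )
                accepted = 0.0
                if np.log(rng.uniform()) < log_acc:
                    d, delta, dfull, logits, ll = dp, prop_d, dfull_p, lp_p, ll_p
                    accepted = 1.0
                if adapting:
                    step_dt[k - 1] *= np.exp(gam * (accepted - 0.44))
                continue
            else:
                dfull_p = des.fe_delta(dp)
                lp_p = cur_logits(mu, dfull_p, beta)
                ll_p = des.arm_loglik(lp_p)
                log_acc = float((ll_p - ll).sum()) + dpri_k
                if np.log(rng.uniform()) < log_acc:
                    d, dfull, logits, ll = dp, dfull_p, lp_p, ll_p
                    accepted = 1.0
                else:
                    accepted = 0.0
            if adapting:
                step_d[k - 1] *= np.exp(gam * (accepted - 0.44))

        # -- between-study SD ----------------------------------------------
        if re:
            sp = _reflect(sigma + step_sig * rng.standard_normal(), 0.0, spec.sd_prior_upper)
            pri_p = des.delta_prior(delta, d, sp)
            accepted = 0.0
            if np.log(rng.uniform()) < float((pri_p - pri_delta).sum()):
                sigma, pri_delta, accepted = sp, pri_p, 1.0
            if adapting:
                step_sig *= np.exp(gam * (accepted - 0.44))

            # joint rescale of (sigma, delta residuals): log-scale walk that
            # traverses the funnel at small sigma; Jacobian e^{z(1+nD)}
            z = step_scale * rng.standard_normal()
            sp = sigma * np.exp(z)
            accepted = 0.0
            if 0.0 < sp < spec.sd_prior_upper:
                mean_d = d[des.nb_t] - d[des.nb_b]
                prop_d = mean_d + np.exp(z) * (delta - mean_d)
                dfull_p = des.delta_full(prop_d)
                lp_p = cur_logits(mu, dfull_p, beta)
                ll_p = des.arm_loglik(lp_p)
                pri_p = des.delta_prior(prop_d, d, sp)
                log_acc = (
                    float((ll_p - ll).sum())
                    + float((pri_p - pri_delta).sum())
                    + z * (1.0 + nD)
                )
                if np.log(rng.uniform()) < log_acc:
                    sigma, delta, pri_delta = sp, prop_d, pri_p
                    dfull, logits, ll = dfull_p, lp_p, ll_p
                    accepted = 1.0
            if adapting:
                step_scale *= np.exp(gam * (accepted - 0.44))

        # -- interaction coefficient ---------------------------------------
        if has_beta:
            bp = beta + step_beta * rng.standard_normal()
            lp_p = cur_logits(mu, dfull, bp)
            ll_p = des.arm_loglik(lp_p)
            log_acc = float((ll_p - ll).sum()) + float(
                _norm_logpdf(bp, beta_prior[0], beta_prior[1])
                - _norm_logpdf(beta, beta_prior[0], beta_prior[1])
            )
            accepted = 0.0
            if np.log(rng.uniform()) < log_acc:
                beta, logits, ll, accepted = bp, lp_p, ll_p, 1.0
            if adapting:
                step_beta *= np.exp(gam * (accepted - 0.44))

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < n_keep:
            out["mu"][kept] = mu
            out["delta"][kept] = delta
            out["d"][kept] = d
            out["sigma"][kept] = sigma
            out["beta"][kept] = beta
            out["baseline_mean"][kept] = b_mu
            out["baseline_sd"][kept] = tau
            out["p"][kept] = expit(logits)
            kept += 1
    for key in out:
        out[key] = out[key][:kept]
    return out


@dataclass
class PosteriorFit:
    """Post-burn-in draws from all chains plus fitted event probabilities."""

    draws: dict[str, np.ndarray]  # name -> (chains, draws[, dim])
    fitted_p: np.ndarray  # (chains, draws, arms)
    spec: ModelSpec
    network: TreatmentNetwork
    mcmc: MCMCConfig
    x: np.ndarray | None = None
    center: float = 0.0
    covariate_name: str | None = None
    rhat: pd.Series | None = None
    converged: bool = True
    companion: "PosteriorFit | None" = None

    def __post_init__(self) -> None:
        if self.fitted_p.shape[0] < 2:
            raise ValueError("at least 2 chains are required")
        if not ((self.fitted_p > 0) & (self.fitted_p < 1)).all():
            raise ValueError("fitted probabilities outside (0, 1)")

    def pooled(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    @property
    def design(self) -> _Design:
        return _Design(self.network)

    def parameter_names(self) -> list[str]:
        labels = self.network.coding.names
        names = [f"d[{labels[k]}]" for k in range(1, len(labels))]
        if self.spec.effect == "RE":
            names.append("sigma")
        if self.spec.covariate_mode != "none":
            names.append("beta")
        if self.spec.covariate_mode == "baseline_risk":
            names += ["baseline_mean", "baseline_sd"]
        names += [f"mu[{s}]" for s in self.network.studies]
        return names

    def parameter_draws(self, name: str) -> np.ndarray:
        """(chains, draws) array for one named scalar parameter."""
        if name in ("sigma", "beta", "baseline_mean", "baseline_sd"):
            return self.draws[name]
        kind, label = name[:-1].split("[", 1)
        if kind == "d":
            return self.draws["d"][:, :, self.network.coding.code(label) - 1]
        if kind == "mu":
            return self.draws["mu"][:, :, self.network.studies.index(label)]
        raise KeyError(name)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.parameter_names():
            flat = self.parameter_draws(name).ravel()
            lo, mid, hi = np.percentile(flat, [2.5, 50.0, 97.5])
            rows.append({"parameter": name, "median": mid, "l95": lo, "u95": hi})
        return pd.DataFrame(rows)

    def median(self, name: str) -> float:
        return float(np.median(self.parameter_draws(name)))

    def cri(self, name: str) -> tuple[float, float]:
        lo, hi = np.percentile(self.parameter_draws(name).ravel(), [2.5, 97.5])
        return float(lo), float(hi)


def _fit(
    net: TreatmentNetwork,
    spec: ModelSpec,
    mcmc: MCMCConfig,
    x: np.ndarray | None = None,
    center: float = 0.0,
    beta_prior: tuple[float, float] = (0.0, 100.0),
    covariate_name: str | None = None,
) -> PosteriorFit:
    des = _Design(net)
    if spec.covariate_mode == "covariate":
        if x is None or len(x) != des.S:
            raise ValueError("covariate vector missing or wrong length")
        x = np.asarray(x, dtype=float)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [
        _run_chain(des, spec, x, center, beta_prior, mcmc, np.random.default_rng(s))
        for s in seeds
    ]
    keys = ("mu", "delta", "d", "sigma", "beta", "baseline_mean", "baseline_sd")
    draws = {k: np.stack([c[k] for c in chains]) for k in keys}
    fitted_p = np.stack([c["p"] for c in chains])
    fit = PosteriorFit(
        draws=draws,
        fitted_p=fitted_p,
        spec=spec,
        network=net,
        mcmc=mcmc,
        x=x,
        center=center,
        covariate_name=covariate_name,
    )
    from .diagnostics import convergence_report  # deferred: avoids module cycle

    report = convergence_report(fit, threshold=mcmc.convergence_threshold)
    fit.rhat = report.set_index("parameter")["bgr"]
    fit.converged = bool((fit.rhat <= mcmc.convergence_threshold).all())
    if not fit.converged:
        worst = fit.rhat.idxmax()
        warnings.warn(
            f"fit did not converge: BGR {fit.rhat.max():.3f} for {worst} "
            f"exceeds {mcmc.convergence_threshold}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fit


def fit_nma(net: TreatmentNetwork, spec: ModelSpec, mcmc: MCMCConfig) -> PosteriorFit:
    """Fit the unadjusted FE/RE NMA model.

    Unconverged fits are returned with ``converged=False`` and a
    :class:`ConvergenceWarning`, never silently.
    """
    if spec.covariate_mode != "none":
        raise ValueError("fit_nma handles the unadjusted model only; see covariates module")
    return _fit(net, spec, mcmc)


def relative_effects(fit: PosteriorFit) -> pd.DataFrame:
    """League table of all K(K-1)/2 unordered pairwise contrasts.

    ``log_or`` for row (a, b) summarizes ``d_b - d_a`` (positive = higher
    event odds under b).
    """
    d = fit.pooled("d")
    labels = fit.network.coding.names
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            contrast = d[:, b] - d[:, a]
            lo, mid, hi = np.percentile(contrast, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "treat_a": labels[a],
                    "treat_b": labels[b],
                    "log_or_median": mid,
                    "log_or_l95": lo,
                    "log_or_u95": hi,
                    "or_median": np.exp(mid),
                    "or_l95": np.exp(lo),
                    "or_u95": np.exp(hi),
                }
            )
    return pd.DataFrame(rows)
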