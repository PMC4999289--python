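"""Meta-regression extensions: study-level covariates and baseline risk.

A single coefficient ``beta`` modifies every treatment's effect versus the
reference identically, so contrasts between two non-reference treatments are
covariate-free.  The baseline-risk variant uses each trial's *latent*
baseline log-odds ``mu_i`` (a model quantity, centered at a fixed constant)
as the covariate, so its estimation uncertainty propagates into ``beta``;
the variant that plugs in observed baseline proportions is provided only to
demonstrate the regression-dilution bias it incurs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import TreatmentNetwork
from .model import (
    MCMCConfig,
    ModelSpec,
    ParameterState,
    PosteriorFit,
    _Design,
    _fit,
)

__all__ = [
    "InteractionSpec",
    "regression_linear_predictor",
    "fit_covariate_model",
    "fit_baseline_risk_model",
    "empirical_baseline_logits",
]


@dataclass(frozen=True)
class InteractionSpec:
    """Which interaction is active and the prior placed on its coefficient."""

    mode: Literal["covariate", "baseline_risk"]
    name: str | None = None
    scale: float | None = None
    center: float = 0.0
    beta_prior_mean: float = 0.0
    beta_prior_sd: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("covariate", "baseline_risk"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.mode == "covariate" and self.name is None:
            raise ValueError("covariate mode requires a covariate name")
        if self.beta_prior_sd <= 0:
            raise ValueError("beta prior sd must be positive")


def regression_linear_predictor(
    state: ParameterState,
    net: TreatmentNetwork,
    x: np.ndarray,
) -> np.ndarray:
    """Per-arm logits ``mu_i + delta_ik + beta * x_i * w_ik``.

    ``w_ik = I(t_ik != 1) - I(t_i,base != 1)``: the interaction enters only
    for effects expressed against the reference treatment, so within any
    study whose arms are all non-reference the ``beta`` terms cancel in
    every contrast.  Arms are ordered study-major, baseline first.
    """
    des = _Design(net)
    x = np.asarray(x, dtype=float)
    if len(x) != des.S:
        raise ValueError(f"covariate has length {len(x)}, expected {des.S} studies")
    if len(state.delta) != des.nD:
        raise ValueError(f"delta has length {len(state.delta)}, expected {des.nD}")
    return des.logits(state.mu, des.delta_full(state.delta), state.beta, x, "covariate", 0.0)


def fit_covariate_model(
    net: TreatmentNetwork,
    x: np.ndarray,
    spec: ModelSpec,
    mcmc: MCMCConfig,
    interaction: InteractionSpec | None = None,
    with_unadjusted: bool = True,
) -> PosteriorFit:
    """Fit the common-interaction meta-regression on a centered covariate.

    ``net``/``x`` come from ``attach_covariate`` (missing-covariate studies
    already dropped, covariate centered).  The returned fit carries the
    matched unadjusted fit on the same reduced data in ``.companion`` for
    like-for-like DIC comparison.
    """
    x = np.asarray(x, dtype=float)
    if interaction is None:
        interaction = InteractionSpec(mode="covariate", name="covariate")
    cspec = ModelSpec(
        effect=spec.effect,
        covariate_mode="covariate",
        prior_effect_mean=spec.prior_effect_mean,
        prior_effect_sd=spec.prior_effect_sd,
        sd_prior_upper=spec.sd_prior_upper,
    )
    fit = _fit(
        net,
        cspec,
        mcmc,
        x=x,
        beta_prior=(interaction.beta_prior_mean, interaction.beta_prior_sd),
        covariate_name=interaction.name,
    )
    if with_unadjusted:
        uspec = ModelSpec(
            effect=spec.effect,
            covariate_mode="none",
            prior_effect_mean=spec.prior_effect_mean,
            prior_effect_sd=spec.prior_effect_sd,
            sd_prior_upper=spec.sd_prior_upper,
        )
        fit.companion = _fit(net, uspec, mcmc)
    return fit


def empirical_baseline_logits(net: TreatmentNetwork) -> np.ndarray:
    """Observed baseline-arm logits with a +0.5 continuity correction.

    Used only for the fixed centering constant of the latent baseline-risk
    model and as the plug-in covariate of the naive (dilution-prone)
    variant; never in the likelihood.
    """
    des = _Design(net)
    base = ~des.nb
    r, n = des.r[base], des.n[base]
    return np.log((r + 0.5) / (n - r + 0.5))


def fit_baseline_risk_model(
    net: TreatmentNetwork,
    spec: ModelSpec,
    mcmc: MCMCConfig,
    interaction: InteractionSpec | None = None,
    naive: bool = False,
    with_unadjusted: bool = False,
) -> PosteriorFit:
    """Meta-regression on trial baseline risk.

    Default (``naive=False``): the covariate for study i is its latent
    baseline ``mu_i`` centered at the fixed mean of observed baseline-arm
    empirical logits, so baseline uncertainty feeds through to ``beta``.
    ``naive=True`` instead fixes the observed empirical logit as covariate,
    ignoring its sampling error (for dilution-bias comparisons only).
    """
    if interaction is None:
        interaction = InteractionSpec(mode="baseline_risk")
    obs = empirical_baseline_logits(net)
    center = float(obs.mean())
    beta_prior = (interaction.beta_prior_mean, interaction.beta_prior_sd)
    if naive:
        cspec = ModelSpec(
            effect=spec.effect,
            covariate_mode="covariate",
            prior_effect_mean=spec.prior_effect_mean,
            prior_effect_sd=spec.prior_effect_sd,
            sd_prior_upper=spec.sd_prior_upper,
        )
        fit = _fit(net, cspec, mcmc, x=obs - center, beta_prior=beta_prior,
                   covariate_name="baseline_risk_naive")
    else:
        cspec = ModelSpec(
            effect=spec.effect,
            covariate_mode="baseline_risk",
            prior_effect_mean=spec.prior_effect_mean,
            prior_effect_sd=spec.prior_effect_sd,
            sd_prior_upper=spec.sd_prior_upper,
        )
        fit = _fit(net, cspec, mcmc, center=center, beta_prior=beta_prior,
                   covariate_name="baseline_risk")
    if with_unadjusted:
        uspec = ModelSpec(
            effect=spec.effect,
            covariate_mode="none",
            prior_effect_mean=spec.prior_effect_mean,
            prior_effect_sd=spec.prior_effect_sd,
            sd_prior_upper=spec.sd_prior_upper,
        )
        fit.companion = _fit(net, uspec, mcmc)
    return fit
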