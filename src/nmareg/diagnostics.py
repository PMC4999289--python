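"""Model criticism and convergence diagnostics.

Residual deviance per binomial data point, effective parameters (pD), DIC,
leverage coordinates with the ``c = x^2 + y`` threshold family, and the
Brooks-Gelman-Rubin potential scale reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PosteriorFit

__all__ = [
    "FitDiagnostics",
    "residual_deviance",
    "dic",
    "compare_dic",
    "leverage_coordinates",
    "potential_scale_reduction",
    "autocorrelation",
    "convergence_report",
]

LEVERAGE_THRESHOLD = 3.0


@dataclass
class FitDiagnostics:
    """Per-point and aggregate fit statistics for one PosteriorFit."""

    dev_i: np.ndarray  # posterior-mean residual deviance per data point
    Dbar: float  # sum of dev_i
    Dhat: float  # deviance at plug-in fitted probabilities
    pD: float  # Dbar - Dhat
    pD_i: np.ndarray  # per-point leverage contribution
    DIC: float  # Dbar + pD
    w_i: np.ndarray  # signed root deviance sign(r - rhat) * sqrt(dev_i)
    point_ids: pd.DataFrame = field(default_factory=pd.DataFrame)
    data_key: frozenset = frozenset()

    def table(self) -> pd.DataFrame:
        out = self.point_ids.copy()
        out["dev_i"] = self.dev_i
        out["pD_i"] = self.pD_i
        out["w_i"] = self.w_i
        out["flagged"] = self.w_i**2 + self.pD_i > LEVERAGE_THRESHOLD
        return out


def _binom_dev(r: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Saturated-model deviance 2[r log(r/rhat) + (n-r) log((n-r)/(n-rhat))].

    ``0 * log 0 == 0``; a plug-in of 0 or 1 discordant with the data yields
    +inf, which is propagated, not masked.
    """
    rhat = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(r > 0, r * np.log(r / rhat), 0.0)
        b = np.where(n - r > 0, (n - r) * np.log((n - r) / (n - rhat)), 0.0)
    return 2.0 * (a + b)


def residual_deviance(fit: PosteriorFit) -> tuple[np.ndarray, float]:
    """Posterior-mean residual deviance per data point and its total.

    A well-fitting model gives a total close to the number of data points.
    """
    des = fit.design
    p = fit.fitted_p.reshape(-1, des.A)  # (all draws, arms)
    dev = _binom_dev(des.r[None, :], des.n[None, :], p)
    dev_i = dev.mean(axis=0)
    return dev_i, float(dev_i.sum())


def dic(fit: PosteriorFit, plugin: str = "p") -> FitDiagnostics:
    """Dbar, Dhat at the plug-in fit, pD = Dbar - Dhat and DIC = Dbar + pD.

    ``plugin``: "p" evaluates Dhat at the posterior mean of the fitted
    probabilities (default); "linpred" at the mean of the linear predictor.
    """
    des = fit.design
    p = fit.fitted_p.reshape(-1, des.A)
    if plugin == "p":
        p_hat = p.mean(axis=0)
    elif plugin == "linpred":
        from scipy.special import expit, logit

        p_hat = expit(logit(p).mean(axis=0))
    else:
        raise ValueError(f"unknown plug-in scale {plugin!r}")
    dev_i, Dbar = residual_deviance(fit)
    dev_hat = _binom_dev(des.r, des.n, p_hat)
    Dhat = float(dev_hat.sum())
    pD_i = dev_i - dev_hat
    w_i = np.sign(des.r - des.n * p_hat) * np.sqrt(dev_i)
    net = fit.network
    ids = pd.DataFrame(
        {
            "point_id": np.arange(des.A),
            "study": [net.studies[s] for s in des.s_idx],
            "treatment": [net.coding.label(t + 1) for t in des.t_idx],
        }
    )
    key = frozenset(zip(ids["study"], ids["treatment"], des.r, des.n))
    return FitDiagnostics(
        dev_i=dev_i,
        Dbar=Dbar,
        Dhat=Dhat,
        pD=Dbar - Dhat,
        pD_i=pD_i,
        DIC=Dbar + (Dbar - Dhat),
        w_i=w_i,
        point_ids=ids,
        data_key=key,
    )


def compare_dic(adjusted: FitDiagnostics, unadjusted: FitDiagnostics) -> float:
    """DIC(adjusted) - DIC(unadjusted); both must be fits of the same data."""
    if adjusted.data_key != unadjusted.data_key:
        raise ValueError("DIC comparison requires identical data points in both fits")
    return adjusted.DIC - unadjusted.DIC


def leverage_coordinates(diag: FitDiagnostics) -> pd.DataFrame:
    """Plot-ready (w_i, pD_i) pairs; flagged when w^2 + pD_i exceeds c = 3."""
    out = diag.table()
    out["contribution"] = out["w_i"] ** 2 + out["pD_i"]
    return out


def potential_scale_reduction(
    chains: np.ndarray, split: bool = True, floor: bool = False
) -> float:
    """Brooks-Gelman-Rubin potential scale reduction factor for one scalar.

    ``chains`` is (n_chains, n_draws).  ``split=True`` halves each chain
    first (detects within-chain drift).  ``floor=True`` clips the estimate
    at 1: values below 1 are sampling noise with no diagnostic content, and
    with it two identical chains give exactly 1 under ``split=False``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with at least 2 chains")
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    rhat = float(np.sqrt(var_plus / W))
    return max(1.0, rhat) if floor else rhat


def autocorrelation(chain: np.ndarray, lags: tuple[int, ...] = (1, 5, 10, 50)) -> dict[int, float]:
    """Lag-k autocorrelations of a single chain."""
    x = np.asarray(chain, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    out = {}
    for lag in lags:
        if lag >= len(x) or denom == 0:
            out[lag] = np.nan
        else:
            out[lag] = float(x[:-lag] @ x[lag:]) / denom
    return out


def convergence_report(
    fit: PosteriorFit,
    threshold: float = 1.05,
    lags: tuple[int, ...] = (1, 10, 50),
) -> pd.DataFrame:
    """Split-BGR and autocorrelations for every monitored parameter.

    A parameter exceeding ``threshold`` marks the fit unconverged (the
    caller surfaces this as a warning flag, never silently).
    """
    rows = []
    for name in fit.parameter_names():
        arr = fit.parameter_draws(name)
        row = {"parameter": name, "bgr": potential_scale_reduction(arr, split=True)}
        acf = autocorrelation(arr[0], lags=lags)
        for lag, val in acf.items():
            row[f"acf_lag{lag}"] = val
        rows.append(row)
    report = pd.DataFrame(rows)
    report["exceeds_threshold"] = report["bgr"] > threshold
    return report
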