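import warnings

import numpy as np
import pandas as pd
import pytest

from nmareg.data import ArmTable, build_network
from nmareg.model import MCMCConfig, ModelSpec, ConvergenceWarning, fit_nma
from nmareg.simulate import SimConfig, simulate_network


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # tiny test-scale chains legitimately trip the convergence flag
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture
def toy_arms() -> ArmTable:
    """Three studies, three treatments, one zero-event arm, one 3-arm study."""
    return ArmTable(
        pd.DataFrame(
            {
                "study": ["A", "A", "B", "B", "B", "C", "C"],
                "treatment": ["plb", "act1", "plb", "act1", "act2", "act1", "act2"],
                "r": [12, 7, 30, 21, 0, 9, 14],
                "n": [100, 110, 250, 240, 60, 120, 115],
            }
        )
    )


@pytest.fixture
def toy_network(toy_arms):
    return build_network(toy_arms)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(seed=42, n_studies=10, true_sigma=0.2, arm_n=(300, 900))
    arms, cov, truth = simulate_network(cfg)
    return cfg, arms, cov, truth


@pytest.fixture(scope="session")
def small_sim_fit(small_sim):
    """One shared RE fit on synthetic data, reused by several test modules."""
    cfg, arms, cov, truth = small_sim
    net = build_network(arms, cfg.coding)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = fit_nma(
            net,
            ModelSpec(effect="RE"),
            MCMCConfig(chains=3, burn_in=1500, samples=1500, seed=7),
        )
    return fit


def quick_mcmc(**kw) -> MCMCConfig:
    base = dict(chains=2, burn_in=800, samples=800, seed=5)
    base.update(kw)
    return MCMCConfig(**base)
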