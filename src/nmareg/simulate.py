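"""Synthetic evidence networks with known truth.

Generates arm-level binomial data from the same logit-linear model the
fitting code assumes: star-like connected networks in which every study
carries an anchor treatment, loops arise only from multi-arm (3-arm)
studies, trial-level effects are drawn with between-study SD ``sigma`` and
multi-arm correlation 1/2, and an optional common treatment-by-covariate
interaction acts versus the reference.  Zero-event arms arise naturally
from low event probabilities and small arms, never by post-hoc zeroing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import (
    ArmTable,
    CovariateTable,
    DEFAULT_COVARIATE_SCALE,
    COVARIATE_COLUMNS,
    TreatmentCoding,
)

__all__ = ["SimConfig", "TruthRecord", "simulate_network", "paper_like_preset"]

#: comparator labels mirroring the anticoagulant/antiplatelet classes of the
#: 15-treatment ischaemic-stroke network (reference first, anchor second)
PRESET_TREATMENTS = (
    "placebo",
    "adjusted_dose_VKA",
    "apixaban",
    "rivaroxaban",
    "dabigatran_110",
    "dabigatran_150",
    "edoxaban_30",
    "edoxaban_60",
    "aspirin",
    "aspirin_clopidogrel",
    "fixed_low_dose_warfarin",
    "fld_warfarin_aspirin",
    "indobufen",
    "idraparinux",
    "ximelagatran",
)


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to draw one dataset; all randomness flows from seed."""

    n_studies: int = 12
    treatment_names: tuple[str, ...] = ("placebo", "anchor", "T3", "T4")
    anchor_treatment: str = "anchor"
    three_arm_prob: float = 0.25
    baseline_mu: tuple[float, float] = (-2.3, 0.4)  # mean, sd of log-odds
    true_d: tuple[float, ...] = (0.0, -0.6, -0.4, -0.3)
    true_sigma: float = 0.15
    true_beta: float = 0.0
    interaction_covariate: str | None = None  # covariate name or "baseline_risk"
    covariate_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "previous_stroke_tia": (0.0, 55.0),
            "proportion_male": (46.0, 100.0),
            "mean_age": (66.0, 75.0),
            "follow_up": (11.0, 42.0),
        }
    )
    arm_n: tuple[int, int] = (200, 800)
    zero_cell_rate: float = 0.0  # fraction of studies given small arms
    small_arm_n: tuple[int, int] = (15, 60)
    min_reference_studies: int = 0  # force the reference into >= this many studies
    seed: int = 0

    @property
    def n_treatments(self) -> int:
        return len(self.treatment_names)

    @property
    def coding(self) -> TreatmentCoding:
        return TreatmentCoding(tuple(self.treatment_names))

    def validate(self) -> None:
        if self.anchor_treatment not in self.treatment_names:
            raise ValueError("anchor treatment not in treatment names")
        if len(self.true_d) != self.n_treatments:
            raise ValueError("true_d length must match number of treatments")
        if self.true_d[0] != 0.0:
            raise ValueError("true_d[0] (reference) must be 0")
        if self.true_sigma < 0:
            raise ValueError("true_sigma must be >= 0")
        if self.true_beta != 0.0 and self.interaction_covariate is None:
            raise ValueError("true_beta != 0 requires an interaction covariate")
        # every non-anchor treatment needs a slot co-occurring with the anchor
        min_slots = self.n_studies  # >= 1 extra arm per study
        if self.n_treatments - 1 > min_slots:
            raise ValueError(
                f"unconnectable design: {self.n_treatments - 1} non-anchor treatments "
                f"but only {min_slots} guaranteed arm slots across {self.n_studies} studies"
            )


@dataclass
class TruthRecord:
    """Every latent drawn during simulation, for recovery checks."""

    seed: int
    treatment_names: list[str]
    studies: list[str]
    mu: list[float]
    d: list[float]
    sigma: float
    beta: float
    interaction_covariate: str | None
    x_centered: list[float]
    delta: dict[str, dict[str, float]]
    p: dict[str, dict[str, float]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def simulate_network(cfg: SimConfig) -> tuple[ArmTable, CovariateTable, TruthRecord]:
    """Draw one arm-level dataset plus its covariates and latent truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    coding = cfg.coding
    anchor = coding.code(cfg.anchor_treatment)
    codes = list(range(1, cfg.n_treatments + 1))
    non_anchor = [c for c in codes if c != anchor]

    studies = [f"S{i + 1:02d}" for i in range(cfg.n_studies)]
    n_arms = 2 + (rng.uniform(size=cfg.n_studies) < cfg.three_arm_prob).astype(int)

    # round-robin the non-anchor treatments over the guaranteed extra slot so
    # every treatment co-occurs with the anchor; fill 3-arm extras at random
    order = list(rng.permutation(non_anchor))
    composition: list[list[int]] = []
    for i in range(cfg.n_studies):
        first = order[i % len(order)]
        arms = {anchor, first}
        while len(arms) < n_arms[i]:
            extra = int(rng.choice(non_anchor))
            arms.add(extra)
        composition.append(sorted(arms))

    # the common interaction acts versus the reference, so enough studies
    # must be reference-based for it to be identified; widen two-arm studies
    # with a reference arm until the floor is met
    if cfg.min_reference_studies > 0:
        have = sum(1 in arms for arms in composition)
        candidates = [i for i, arms in enumerate(composition) if 1 not in arms]
        rng.shuffle(candidates)
        for i in candidates[: max(0, cfg.min_reference_studies - have)]:
            composition[i] = sorted(set(composition[i]) | {1})

    # study-level covariates (stored units)
    cov_rows = {"study": studies}
    raw_cov = {}
    for name, (lo, hi) in cfg.covariate_dist.items():
        vals = rng.uniform(lo, hi, cfg.n_studies)
        raw_cov[name] = vals
        cov_rows[COVARIATE_COLUMNS[name]] = vals

    m, s = cfg.baseline_mu
    mu = rng.normal(m, s, cfg.n_studies)

    # interaction covariate on the regression scale, centered at the realized
    # mean (matching how attach_covariate centers at fit time)
    if cfg.interaction_covariate == "baseline_risk":
        x_centered = mu - mu.mean()
    elif cfg.interaction_covariate is not None:
        scaled = raw_cov[cfg.interaction_covariate] * DEFAULT_COVARIATE_SCALE[
            cfg.interaction_covariate
        ]
        x_centered = scaled - scaled.mean()
    else:
        x_centered = np.zeros(cfg.n_studies)

    d = np.asarray(cfg.true_d, dtype=float)
    small = rng.uniform(size=cfg.n_studies) < cfg.zero_cell_rate

    rows = []
    delta_rec: dict[str, dict[str, float]] = {}
    p_rec: dict[str, dict[str, float]] = {}
    for i, study in enumerate(studies):
        arms = composition[i]
        base = arms[0]
        shared = rng.standard_normal()  # gives the pairwise-1/2 correlation
        delta_rec[study] = {}
        p_rec[study] = {}
        for code in arms:
            if code == base:
                delta = 0.0
            else:
                eps = rng.standard_normal()
                delta = (
                    d[code - 1]
                    - d[base - 1]
                    + cfg.true_sigma * np.sqrt(0.5) * (eps + shared)
                )
            w = float(code != 1) - float(base != 1)
            logit = mu[i] + delta + cfg.true_beta * x_centered[i] * w
            p = float(expit(logit))
            lo, hi = cfg.small_arm_n if small[i] else cfg.arm_n
            n = int(rng.integers(lo, hi + 1))
            r = int(rng.binomial(n, p))
            label = coding.label(code)
            rows.append({"study": study, "treatment": label, "r": r, "n": n})
            delta_rec[study][label] = float(delta)
            p_rec[study][label] = p

    arm_table = ArmTable(pd.DataFrame(rows))
    cov_table = CovariateTable(pd.DataFrame(cov_rows))
    truth = TruthRecord(
        seed=cfg.seed,
        treatment_names=list(cfg.treatment_names),
        studies=studies,
        mu=[float(v) for v in mu],
        d=[float(v) for v in d],
        sigma=float(cfg.true_sigma),
        beta=float(cfg.true_beta),
        interaction_covariate=cfg.interaction_covariate,
        x_centered=[float(v) for v in x_centered],
        delta=delta_rec,
        p=p_rec,
    )
    return arm_table, cov_table, truth


def paper_like_preset(seed: int = 0) -> SimConfig:
    """19 studies, 15 comparators, anchor in every study, covariates spanning
    the observed ranges (follow-up 11-42 months, males 46-100%, previous
    stroke/TIA 0-55%, age 66-75), baseline log-odds placed so anchor/placebo
    arm odds fall around 0.05-0.22."""
    return SimConfig(
        n_studies=19,
        treatment_names=PRESET_TREATMENTS,
        anchor_treatment="adjusted_dose_VKA",
        three_arm_prob=0.25,
        baseline_mu=(-2.3, 0.35),
        true_d=(
            0.0, -0.7, -0.9, -0.75, -0.6, -0.85, -0.5, -0.8,
            -0.25, -0.35, -0.3, -0.4, -0.2, -0.55, -0.65,
        ),
        true_sigma=0.15,
        true_beta=0.0,
        arm_n=(120, 1500),
        zero_cell_rate=0.35,
        small_arm_n=(12, 45),
        min_reference_studies=5,
        seed=seed,
    )
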