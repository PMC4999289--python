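"""Arm-level data model, CSV ingest, treatment coding and network construction.

The unit of evidence is one binomial arm: ``(study, treatment, r, n)`` with
``r`` events out of ``n`` patients.  Treatments are coded as contiguous
integers ``1..K`` with the reference treatment (placebo) always coded 1; the
baseline arm of each study is the arm with the lowest treatment code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ArmRecord",
    "ArmTable",
    "TreatmentCoding",
    "TreatmentNetwork",
    "CovariateTable",
    "COVARIATE_COLUMNS",
    "read_arm_data",
    "write_arm_data",
    "read_covariates",
    "write_covariates",
    "build_network",
    "attach_covariate",
    "pairwise_comparison_count",
]

ARM_COLUMNS = ("study", "treatment", "r", "n")

#: maps covariate names to the CSV columns that store them
COVARIATE_COLUMNS = {
    "previous_stroke_tia": "prev_stroke_tia_pct",
    "proportion_male": "male_pct",
    "mean_age": "mean_age_yr",
    "follow_up": "follow_up_months",
}

#: default multiplier applied to the stored unit before centering;
#: follow-up is stored in months but regressed per year
DEFAULT_COVARIATE_SCALE = {
    "previous_stroke_tia": 1.0,
    "proportion_male": 1.0,
    "mean_age": 1.0,
    "follow_up": 1.0 / 12.0,
}


class DataError(ValueError):
    """Raised for invalid arm/covariate tables or broken networks."""


@dataclass(frozen=True)
class ArmRecord:
    """One binomial observation: ``r`` events out of ``n`` in one arm."""

    study_id: str
    treatment_id: int
    r: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DataError(f"arm ({self.study_id}, {self.treatment_id}): n={self.n} < 1")
        if not 0 <= self.r <= self.n:
            raise DataError(
                f"arm ({self.study_id}, {self.treatment_id}): r={self.r} outside [0, n={self.n}]"
            )
        if self.treatment_id < 1:
            raise DataError(
                f"arm ({self.study_id}, {self.treatment_id}): treatment code must be >= 1"
            )


@dataclass
class ArmTable:
    """Validated table of arms; treatment column holds raw labels."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _validate_arm_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def studies(self) -> list[str]:
        return list(dict.fromkeys(self.df["study"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.df["treatment"]))


def _validate_arm_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ARM_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"arm table missing column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in ARM_COLUMNS]
    if unknown:
        raise DataError(f"arm table has unknown column(s): {', '.join(unknown)}")
    if len(df) == 0:
        raise DataError("no arm records")
    df = df.loc[:, list(ARM_COLUMNS)].copy()
    df["study"] = df["study"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    for col in ("r", "n"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"row {i}: column {col!r} is not an integer: {df[col].iloc[i]!r}")
        df[col] = vals.astype(int)
    for i, row in enumerate(df.itertuples(index=False)):
        if row.n <= 0:
            raise DataError(f"row {i} (study {row.study!r}): n={row.n} <= 0")
        if row.r < 0 or row.r > row.n:
            raise DataError(f"row {i} (study {row.study!r}): r={row.r} outside [0, n={row.n}]")
    dup = df.duplicated(subset=["study", "treatment"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise DataError(
            f"row {i}: duplicate (study, treatment) pair "
            f"({df['study'].iloc[i]!r}, {df['treatment'].iloc[i]!r})"
        )
    return df.reset_index(drop=True)


def read_arm_data(path: str | Path | io.IOBase) -> ArmTable:
    """Read an arms CSV with header columns ``study,treatment,r,n``.

    Zero-event arms are retained verbatim; no continuity correction is ever
    applied to the data.
    """
    df = pd.read_csv(path, dtype={"study": str, "treatment": str})
    return ArmTable(df)


def write_arm_data(table: ArmTable, path: str | Path) -> None:
    """Write the canonical CSV form (round-trips byte-for-byte)."""
    table.df.to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class TreatmentCoding:
    """Ordered treatment labels; position 0 is the reference, coded 1."""

    names: tuple[str, ...]
    reference_index: int = 1

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise DataError("treatment coding contains duplicate labels")
        if self.reference_index != 1:
            raise DataError("reference treatment must be coded 1")

    @property
    def n_treatments(self) -> int:
        return len(self.names)

    def code(self, label: str) -> int:
        try:
            return self.names.index(label) + 1
        except ValueError:
            raise DataError(f"treatment label {label!r} not in coding") from None

    def label(self, code: int) -> str:
        return self.names[code - 1]

    @classmethod
    def from_arms(cls, arms: ArmTable, reference: str | None = None) -> "TreatmentCoding":
        """Code by first appearance, with ``reference`` (default: first label) as 1."""
        labels = arms.treatments
        if reference is not None:
            if reference not in labels:
                raise DataError(f"reference treatment {reference!r} not present in data")
            labels = [reference] + [t for t in labels if t != reference]
        return cls(tuple(labels))

    @classmethod
    def from_file(cls, path: str | Path) -> "TreatmentCoding":
        lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
        return cls(tuple(ln for ln in lines if ln))


@dataclass
class TreatmentNetwork:
    """A connected evidence network of coded arms.

    ``arms`` carries an extra integer ``code`` column; ``study_baseline`` maps
    each study to its lowest-coded treatment.
    """

    arms: ArmTable
    coding: TreatmentCoding
    study_baseline: dict[str, int] = field(default_factory=dict)

    @property
    def n_studies(self) -> int:
        return len(self.study_baseline)

    @property
    def n_treatments(self) -> int:
        return int(self.arms.df["code"].nunique())

    @property
    def studies(self) -> list[str]:
        return list(self.study_baseline)

    def arms_of(self, study: str) -> pd.DataFrame:
        return self.arms.df[self.arms.df["study"] == study]


def _comparison_graph(df: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(df["code"].unique())
    for _, grp in df.groupby("study", sort=False):
        codes = sorted(grp["code"])
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                g.add_edge(a, b)
    return g


def build_network(arms: ArmTable, coding: TreatmentCoding | None = None) -> TreatmentNetwork:
    """Code treatments, pick per-study baselines and verify connectivity.

    Raises :class:`DataError` for single-arm studies or a disconnected
    comparison graph (the message names the components).
    """
    if coding is None:
        coding = TreatmentCoding.from_arms(arms)
    df = arms.df.copy()
    df["code"] = [coding.code(t) for t in df["treatment"]]

    sizes = df.groupby("study", sort=False)["code"].size()
    single = sizes[sizes < 2]
    if len(single):
        raise DataError(f"single-arm study(ies): {', '.join(map(repr, single.index))}")

    g = _comparison_graph(df)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        named = [sorted(coding.label(c) for c in comp) for comp in comps]
        raise DataError(f"network is disconnected; components: {named}")

    baseline = {s: int(grp["code"].min()) for s, grp in df.groupby("study", sort=False)}
    table = ArmTable.__new__(ArmTable)  # keep the extra code column
    table.df = df.reset_index(drop=True)
    return TreatmentNetwork(arms=table, coding=coding, study_baseline=baseline)


def pairwise_comparison_count(n_treatments: int) -> int:
    """Number of unordered treatment pairs in a K-treatment network."""
    return n_treatments * (n_treatments - 1) // 2


@dataclass
class CovariateTable:
    """Per-study covariates; empty cells are missing values.

    Units: percents in [0, 100], age in years, follow-up in months.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        cols = ["study"] + list(COVARIATE_COLUMNS.values())
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise DataError(f"covariate table missing column(s): {', '.join(missing)}")
        df = self.df.loc[:, cols].copy()
        df["study"] = df["study"].astype(str)
        if df["study"].duplicated().any():
            raise DataError("duplicate study in covariate table")
        for col in COVARIATE_COLUMNS.values():
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("prev_stroke_tia_pct", "male_pct"):
            bad = df[col].dropna()
            if ((bad < 0) | (bad > 100)).any():
                raise DataError(f"{col} outside [0, 100]")
        ages = df["mean_age_yr"].dropna()
        if ((ages <= 0) | (ages >= 120)).any():
            raise DataError("mean_age_yr outside (0, 120)")
        fu = df["follow_up_months"].dropna()
        if (fu <= 0).any():
            raise DataError("follow_up_months must be > 0")
        self.df = df.reset_index(drop=True)

    def value(self, study: str, name: str) -> float:
        col = COVARIATE_COLUMNS[name]
        sub = self.df.loc[self.df["study"] == study, col]
        return float(sub.iloc[0]) if len(sub) else float("nan")


def read_covariates(path: str | Path | io.IOBase) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, dtype={"study": str}))


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    cov.df.to_csv(path, index=False, lineterminator="\n")


def attach_covariate(
    net: TreatmentNetwork,
    cov: CovariateTable,
    name: str,
    scale: float | None = None,
) -> tuple[TreatmentNetwork, np.ndarray]:
    """Drop studies missing covariate ``name``, re-validate, center the rest.

    Returns the reduced network (shared by the adjusted fit and its matched
    unadjusted comparator) and the covariate vector, scaled by ``scale``
    (default per :data:`DEFAULT_COVARIATE_SCALE`) and centered at the
    retained-study mean, ordered as ``net.studies`` of the reduced network.
    """
    if name not in COVARIATE_COLUMNS:
        raise DataError(
            f"unknown covariate {name!r}; expected one of {sorted(COVARIATE_COLUMNS)}"
        )
    if scale is None:
        scale = DEFAULT_COVARIATE_SCALE[name]
    values = {s: cov.value(s, name) for s in net.studies}
    keep = [s for s, v in values.items() if np.isfinite(v)]
    if not keep:
        raise DataError(f"no study reports covariate {name!r}")
    df = net.arms.df[net.arms.df["study"].isin(keep)]
    reduced = build_network(ArmTable(df.loc[:, list(ARM_COLUMNS)]), net.coding)
    x = np.array([values[s] for s in reduced.studies], dtype=float) * scale
    return reduced, x - x.mean()
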