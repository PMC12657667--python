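"""Data containers and file I/O for anchored two-trial indirect comparisons.

The package works with the asymmetric data setting typical of health
technology assessment: individual participant data (IPD) are available for
the sponsor's own trial (active treatment A vs common comparator C) while
only aggregate-level data (ALD) — covariate summaries, arm sizes and event
counts — are published for the competitor trial (B vs C).

IPD files are plain CSV with columns ``y, t, x1..xK`` (binary outcome,
binary treatment indicator, covariates); ALD summaries and scenario
configurations are YAML/JSON key-value documents. All writers emit files
that round-trip exactly through the corresponding reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IPDTrial",
    "ALDSummary",
    "ScenarioConfig",
    "read_ipd",
    "write_ipd",
    "read_ald",
    "write_ald",
    "aggregate_ipd",
]


def _as_binary(name: str, values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.all(np.isin(arr, (0, 1))):
        bad = np.setdiff1d(np.unique(arr), [0, 1])
        raise ValueError(f"column '{name}' must be binary 0/1; found values {bad.tolist()}")
    return arr.astype(np.int8)


@dataclass
class IPDTrial:
    """Individual participant data for one two-arm trial.

    Attributes
    ----------
    y : (n,) array of binary outcomes.
    t : (n,) array of treatment indicators, 1 = active arm, 0 = common
        comparator.
    X : (n, K) covariate matrix; binary covariates are coded 0/1.
    covariate_names : K column labels, order preserved from the source.
    trial_label : conventional label, ``"AC"`` for the IPD trial.
    """

    y: np.ndarray
    t: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    trial_label: str = "AC"

    def __post_init__(self) -> None:
        self.y = _as_binary("y", self.y)
        self.t = _as_binary("t", self.t)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != len(self.y) or len(self.t) != len(self.y):
            raise ValueError(
                f"inconsistent lengths: y={len(self.y)}, t={len(self.t)}, X rows={self.X.shape[0]}"
            )
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names must match the number of columns of X")
        if self.X.shape[1] < 1:
            raise ValueError("at least one covariate is required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite entries")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def K(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"y": self.y, "t": self.t})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.X[:, j]
        return df


@dataclass
class ALDSummary:
    """Published aggregate-level summary of the comparator (B vs C) trial.

    Covariate summaries are pooled across arms, as commonly reported in a
    baseline characteristics table. For binary covariates the "mean" is the
    proportion and the SD entry may be null (``NaN``); consumers ignore it.
    """

    cov_means: np.ndarray
    cov_sds: np.ndarray
    n_B: int
    n_C: int
    events_B: int
    events_C: int
    covariate_names: list[str] = field(default_factory=list)
    trial_label: str = "BC"

    def __post_init__(self) -> None:
        self.cov_means = np.asarray(self.cov_means, dtype=float)
        self.cov_sds = np.asarray(self.cov_sds, dtype=float)
        if self.cov_means.shape != self.cov_sds.shape:
            raise ValueError("cov_means and cov_sds must have equal length")
        if not self.covariate_names:
            self.covariate_names = [f"x{j + 1}" for j in range(len(self.cov_means))]
        if len(self.covariate_names) != len(self.cov_means):
            raise ValueError("covariate_names must match cov_means length")
        for label, n_arm, ev in (("B", self.n_B, self.events_B), ("C", self.n_C, self.events_C)):
            if n_arm <= 0:
                raise ValueError(f"arm {label} has non-positive size {n_arm}")
            if not 0 <= ev <= n_arm:
                raise ValueError(f"arm {label}: events {ev} outside [0, {n_arm}]")
        defined = self.cov_sds[np.isfinite(self.cov_sds)]
        if np.any(defined < 0):
            raise ValueError("cov_sds must be non-negative where defined")

    @property
    def K(self) -> int:
        return len(self.cov_means)

    def to_dict(self) -> dict[str, Any]:
        sds = [None if not np.isfinite(s) else float(s) for s in self.cov_sds]
        return {
            "trial_label": self.trial_label,
            "covariate_names": list(self.covariate_names),
            "cov_means": [float(m) for m in self.cov_means],
            "cov_sds": sds,
            "n_B": int(self.n_B),
            "n_C": int(self.n_C),
            "events_B": int(self.events_B),
            "events_C": int(self.events_C),
        }


@dataclass
class ScenarioConfig:
    """One cell of the simulation design.

    The three design factors are the IPD trial size, the degree of
    population overlap between the two trial populations, and the covariate
    structure (multivariate normal vs a skewed/binary structure with
    non-linear dependence). ``outcome_coeffs`` and ``covariate_params`` are
    optional overrides; when ``None`` the defaults in
    :mod:`gmaic.dgp_scenarios` are materialized.
    """

    n_ipd: int
    overlap: str
    structure: str
    n_ald: int = 600
    control_event_rate: float = 0.35
    outcome_coeffs: Any = None  # OutcomeCoefficients, see dgp_scenarios
    covariate_params: Any = None  # dict {"AC": CovariateModel, "BC": CovariateModel}
    seed: int = 0

    OVERLAPS = ("high", "moderate", "poor")
    STRUCTURES = ("normal", "nonnormal")

    def __post_init__(self) -> None:
        if self.n_ipd <= 0 or self.n_ald <= 0:
            raise ValueError("trial sizes must be positive")
        if self.overlap not in self.OVERLAPS:
            raise ValueError(f"overlap must be one of {self.OVERLAPS}, got {self.overlap!r}")
        if self.structure not in self.STRUCTURES:
            raise ValueError(f"structure must be one of {self.STRUCTURES}, got {self.structure!r}")
        if not 0.0 < self.control_event_rate < 1.0:
            raise ValueError("control_event_rate must lie in (0, 1)")

    @property
    def scenario_id(self) -> str:
        return f"{self.structure}_{self.overlap}_n{self.n_ipd}"


def write_ipd(trial: IPDTrial, path: str | Path) -> Path:
    """Write an :class:`IPDTrial` to CSV (columns ``y, t, x1..xK``)."""
    path = Path(path)
    trial.to_dataframe().to_csv(path, index=False)
    return path


def read_ipd(path: str | Path) -> IPDTrial:
    """Read and validate an IPD CSV file.

    The header must name columns ``y`` and ``t``; every remaining column is
    taken as a covariate, in file order.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for required in ("y", "t"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column '{required}'")
    cov_cols = [c for c in df.columns if c not in ("y", "t")]
    if not cov_cols:
        raise ValueError(f"{path}: no covariate columns found besides y and t")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"{path}: missing values in columns {bad}")
    return IPDTrial(
        y=df["y"].to_numpy(),
        t=df["t"].to_numpy(),
        X=df[cov_cols].to_numpy(dtype=float),
        covariate_names=cov_cols,
    )


def write_ald(ald: ALDSummary, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(ald.to_dict(), fh, sort_keys=False)
    return path


def read_ald(path: str | Path) -> ALDSummary:
    """Read an ALD summary from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key-value document")
    required = {"cov_means", "n_B", "n_C", "events_B", "events_C"}
    missing = required - raw.keys()
    if missing:
        raise ValueError(f"{path}: missing keys {sorted(missing)}")
    means = np.asarray(raw["cov_means"], dtype=float)
    sds_raw = raw.get("cov_sds", [None] * len(means))
    sds = np.array([np.nan if s is None else float(s) for s in sds_raw])
    return ALDSummary(
        cov_means=means,
        cov_sds=sds,
        n_B=int(raw["n_B"]),
        n_C=int(raw["n_C"]),
        events_B=int(raw["events_B"]),
        events_C=int(raw["events_C"]),
        covariate_names=list(raw.get("covariate_names", [])),
        trial_label=str(raw.get("trial_label", "BC")),
    )


def aggregate_ipd(trial: IPDTrial, arm_labels: tuple[str, str] = ("B", "C")) -> ALDSummary:
    """Collapse an IPD trial to the aggregate summary a publication would report.

    Covariate summaries are pooled over both arms (means and sample SDs);
    outcome information is the per-arm sample size and event count, with the
    active arm (``t == 1``) reported under the first label.
    """
    active = trial.t == 1
    n_active, n_comp = int(active.sum()), int((~active).sum())
    if n_active == 0 or n_comp == 0:
        raise ValueError("cannot aggregate a trial with an empty arm")
    means = trial.X.mean(axis=0)
    sds = trial.X.std(axis=0, ddof=1)
    return ALDSummary(
        cov_means=means,
        cov_sds=sds,
        n_B=n_active,
        n_C=n_comp,
        events_B=int(trial.y[active].sum()),
        events_C=int(trial.y[~active].sum()),
        covariate_names=list(trial.covariate_names),
        trial_label=trial.trial_label,
    )
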