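"""Hierarchical population layer.

Each of the study datasets (one animal at one measurement day) is treated as
an independent individual.  Individual transfer constants are log-normally
distributed around covariate-adjusted typical values,

    k_i = theta * exp(beta . x_i) * exp(eta_i),   eta_i ~ N(0, omega^2),

with a diagonal inter-individual covariance (one eta per transfer constant).
Residual error on each concentration observation is mixed
additive + proportional:

    y = f (1 + eps_prop) + eps_add,   Var(y) = sigma_add^2 + (sigma_prop f)^2.

A per-dataset injection lag (truncated-normal, nuisance) shifts the kinetic
solution in time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, NumericError
from .graphs import CompartmentGraph, DEFAULT_CLEARANCE, TISSUE_TO_COMPARTMENT
from .kinetics import KineticParameters, derive_volumes, simulate_amounts

__all__ = [
    "CovariateSpec",
    "PopulationModel",
    "IndividualParameters",
    "StudyDataset",
    "apply_covariates",
    "draw_individual",
    "dataset_loglik",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class CovariateSpec:
    """A covariate effect on one transfer constant.

    ``anest`` (binary: 0 = injection anesthesia, 1 = gaseous) acts on muscle
    or liver rates; ``vti`` (ordered categorical, 4 levels, level 1 =
    pre-treatment reference) acts on tumor rates.  Effects are multiplicative
    log-linear: binary contributes ``exp(beta * x)``, categorical contributes
    ``exp(beta_level)`` with the reference level fixed at factor 1.
    """

    name: str
    target: str
    kind: str = "binary"  # "binary" | "categorical"
    levels: tuple = ()
    reference: object = None
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "categorical"):
            raise ConfigurationError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ConfigurationError(f"categorical covariate {self.name!r} needs levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            object.__setattr__(self, "reference", ref)
            free = [l for l in self.levels if l != ref]
            extra = set(self.coefficients) - set(free)
            if extra:
                raise ConfigurationError(
                    f"coefficients for non-free levels of {self.name!r}: {sorted(map(str, extra))}")

    def n_coefficients(self) -> int:
        if self.kind == "binary":
            return 1
        return len(self.levels) - 1

    def coefficient_names(self) -> list[str]:
        if self.kind == "binary":
            return [f"beta_{self.name}_{self.target}"]
        return [f"beta_{self.name}_{self.target}_lvl{l}"
                for l in self.levels if l != self.reference]

    def log_factor(self, value) -> float:
        """Log-scale adjustment for one covariate value."""
        if self.kind == "binary":
            beta = self.coefficients.get("beta", 0.0)
            return float(beta) * float(value)
        if value not in self.levels:
            raise DataError(f"unknown level {value!r} for covariate {self.name!r}")
        if value == self.reference:
            return 0.0
        return float(self.coefficients.get(value, 0.0))


def apply_covariates(theta: dict[str, float], covariates, values: dict) -> dict[str, float]:
    """Covariate-adjusted typical values, ``k_typ = theta * exp(sum beta x)``."""
    adjusted = dict(theta)
    for spec in covariates:
        if spec.target not in adjusted:
            raise ConfigurationError(f"covariate target {spec.target!r} not a model rate")
        if spec.name not in values:
            raise DataError(f"no value supplied for covariate {spec.name!r}")
        adjusted[spec.target] *= math.exp(spec.log_factor(values[spec.name]))
    return adjusted


@dataclass
class PopulationModel:
    """Typical values, inter-individual variability, residual error and the
    lag model, bound to a compartment topology."""

    graph: CompartmentGraph
    theta: dict[str, float]
    omega2: dict[str, float]
    sigma_add: float = 0.005  # [mM]
    sigma_prop: float = 0.05
    lag_mean: float = 10.0    # [s]
    lag_sd: float = 5.0       # [s]
    covariates: tuple = ()
    clearance: float = DEFAULT_CLEARANCE

    def __post_init__(self) -> None:
        names = set(self.graph.rate_names())
        if set(self.theta) != names:
            raise ConfigurationError(
                f"theta keys must match graph rates; missing {sorted(names - set(self.theta))}, "
                f"extra {sorted(set(self.theta) - names)}")
        for name, w in self.omega2.items():
            if name not in names:
                raise ConfigurationError(f"omega2 for unknown rate {name!r}")
            if w < 0:
                raise ConfigurationError(f"omega2[{name!r}] must be >= 0")
        if not (self.sigma_add > 0 or self.sigma_prop > 0):
            raise ConfigurationError("at least one residual-error component must be positive")
        for spec in self.covariates:
            if spec.target not in names:
                raise ConfigurationError(f"covariate target {spec.target!r} not a model rate")

    def with_covariates(self, covariates) -> "PopulationModel":
        return replace(self, covariates=tuple(covariates))


@dataclass
class IndividualParameters:
    """Realized parameters for one dataset."""

    dataset_id: object
    rates: dict[str, float]
    lag: float
    eta: dict[str, float] = field(default_factory=dict)


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal(mean, sd) truncated at zero, by rejection (fast for the
    default lag model where P(<0) is small)."""
    if sd == 0:
        return max(mean, 0.0)
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return x


def draw_individual(pop: PopulationModel, covariate_values: dict,
                    rng: np.random.Generator, dataset_id=None) -> IndividualParameters:
    """Draw one individual's rates and lag from the population model."""
    typ = apply_covariates(pop.theta, pop.covariates, covariate_values) \
        if pop.covariates else dict(pop.theta)
    eta = {}
    rates = {}
    for name in pop.graph.rate_names():
        w2 = pop.omega2.get(name, 0.0)
        e = rng.normal(0.0, math.sqrt(w2)) if w2 > 0 else 0.0
        eta[name] = e
        rates[name] = typ[name] * math.exp(e)
    lag = _truncated_normal(pop.lag_mean, pop.lag_sd, rng)
    return IndividualParameters(dataset_id=dataset_id, rates=rates, lag=lag, eta=eta)


def mixed_error_m2ll(y: np.ndarray, f: np.ndarray, sigma_add: float,
                     sigma_prop: float) -> float:
    """-2 log likelihood of observations under the mixed error model."""
    v = sigma_add ** 2 + (sigma_prop * f) ** 2
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise NumericError("degenerate residual variance")
    r = y - f
    return float(np.sum(np.log(v) + r * r / v) + len(y) * _LOG_2PI)


def dataset_loglik(pop: PopulationModel, ind: IndividualParameters,
                   observations: pd.DataFrame, dose: float) -> float:
    """Per-dataset objective contribution: -2 log conditional likelihood.

    ``observations`` needs columns TIME [s], TISSUE and DV [mM].  Predictions
    use the individual's rates and lag; tissue concentrations are scaled by
    the flow-balance volumes derived from the same rates.
    """
    times = observations["TIME"].to_numpy(dtype=float)
    tissues = observations["TISSUE"].to_numpy()
    y = observations["DV"].to_numpy(dtype=float)
    params = KineticParameters(dict(ind.rates), clearance=pop.clearance)
    grid = np.unique(times)
    traj = simulate_amounts(pop.graph, params, dose, ind.lag, grid)
    volumes = derive_volumes(pop.graph, params)
    pos = {t: np.searchsorted(grid, times[tissues == t]) for t in np.unique(tissues)}
    f = np.empty_like(y)
    for tissue, idx in pos.items():
        comp = TISSUE_TO_COMPARTMENT.get(tissue)
        if comp is None:
            raise DataError(f"unknown tissue label {tissue!r}")
        f[tissues == tissue] = traj.amount(comp)[idx] / volumes.volumes[comp]
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f))[0])
        raise NumericError(f"non-finite prediction at record {bad} "
                           f"(t={times[bad]}, tissue={tissues[bad]})")
    return mixed_error_m2ll(y, f, pop.sigma_add, pop.sigma_prop)


_OBS_COLUMNS = ("ID", "OCC", "TIME", "TISSUE", "DV")
_SUBJ_COLUMNS = ("ID", "OCC", "DOSE", "ANEST", "VTI")


@dataclass
class StudyDataset:
    """A collection of per-dataset concentration records with dosing and
    covariates.

    ``observations``: one row per measured concentration (ID, OCC, TIME,
    TISSUE, DV).  ``subjects``: one row per dataset (ID, OCC, DOSE [umol],
    ANEST in {0, 1}, VTI in {1, 2, 3, 4}).  ``truth`` optionally carries the
    generating parameters of synthetic data (one row per dataset).
    """

    observations: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in _OBS_COLUMNS:
            if col not in self.observations.columns:
                raise DataError(f"observations missing column {col!r}")
        for col in _SUBJ_COLUMNS:
            if col not in self.subjects.columns:
                raise DataError(f"subjects missing column {col!r}")
        obs_ids = set(self.observations["ID"])
        subj_ids = set(self.subjects["ID"])
        if not obs_ids <= subj_ids:
            raise DataError(f"observations reference unknown dataset ids: {sorted(obs_ids - subj_ids)}")
        bad = set(self.observations["TISSUE"]) - set(TISSUE_TO_COMPARTMENT)
        if bad:
            raise DataError(f"unknown tissue labels: {sorted(map(str, bad))}")
        t = self.observations["TIME"]
        if t.isna().any() or (t < 0).any() or not np.isfinite(t).all():
            raise DataError("observation times must be finite and non-negative")
        for (ds, tissue), grp in self.observations.groupby(["ID", "TISSUE"], sort=False):
            dt = np.diff(grp["TIME"].to_numpy(dtype=float))
            if np.any(dt <= 0):
                raise DataError(f"times not strictly increasing for dataset {ds!r}, tissue {tissue!r}")
        if not np.isfinite(self.observations["DV"].to_numpy(dtype=float)).all():
            raise DataError("concentrations must be finite (negative values are allowed)")

    @property
    def ids(self) -> list:
        return list(self.subjects["ID"])

    @property
    def n_datasets(self) -> int:
        return len(self.subjects)

    def observations_for(self, dataset_id) -> pd.DataFrame:
        return self.observations[self.observations["ID"] == dataset_id]

    def subject(self, dataset_id) -> pd.Series:
        row = self.subjects[self.subjects["ID"] == dataset_id]
        if row.empty:
            raise DataError(f"no dataset with id {dataset_id!r}")
        return row.iloc[0]

    def covariate_values(self, dataset_id) -> dict:
        row = self.subject(dataset_id)
        return {"anest": int(row["ANEST"]), "vti": int(row["VTI"])}

    def subset(self, ids) -> "StudyDataset":
        ids = list(ids)
        return StudyDataset(
            observations=self.observations[self.observations["ID"].isin(ids)].reset_index(drop=True),
            subjects=self.subjects[self.subjects["ID"].isin(ids)].reset_index(drop=True),
            truth=None if self.truth is None
            else self.truth[self.truth["ID"].isin(ids)].reset_index(drop=True),
        )
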