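"""Model diagnostics and Bayesian model comparison.

Covers conditional weighted residuals (CWRES), chain-stability scoring of
the MCMC traces, DIC-based model comparison, the exhaustive single-covariate
scan, and the flattening-factor display of a parameter correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComparisonError, DataError, NumericError, StateError
from .estimation import (FitResult, SamplerConfig, _Engine, build_fit_model,
                         compute_ofv, fit_model, summarize_posterior)
from .population import CovariateSpec, PopulationModel, StudyDataset

__all__ = [
    "compute_cwres",
    "chain_stability",
    "compute_dic",
    "dic_from_deviance",
    "compare_models",
    "ComparisonResult",
    "correlation_flattening",
    "covariate_scan",
    "admissible_covariate_pairs",
]


def _conditional_predictions(fit: FitResult) -> pd.DataFrame:
    """Per-observation predictions at the posterior-mean parameters,
    conditioned on the posterior-mean (empirical-Bayes) random effects."""
    engine = _Engine(fit.model, fit.data)
    lt = np.log(fit.theta.mean(axis=0))
    beta = fit.beta.mean(axis=0) if fit.beta.size else np.zeros(0)
    eta = fit.posterior_mean_eta()
    lag = fit.posterior_mean_lag()
    off = engine.cov_offsets(beta)
    rows = []
    for d, ds in enumerate(engine.ids):
        obs = fit.data.observations_for(ds)
        f = engine.predict_dataset(lt + off[d] + eta[d], lag[d], d)
        if not np.all(np.isfinite(f)):
            raise NumericError(f"non-finite conditional prediction for dataset {ds!r}")
        rows.append(pd.DataFrame({
            "ID": ds,
            "OCC": obs["OCC"].to_numpy(),
            "TISSUE": obs["TISSUE"].to_numpy(),
            "TIME": obs["TIME"].to_numpy(dtype=float),
            "DV": obs["DV"].to_numpy(dtype=float),
            "PRED": f,
        }))
    return pd.concat(rows, ignore_index=True)


def compute_cwres(fit: FitResult) -> pd.DataFrame:
    """Conditional weighted residuals.

    Residuals are standardized by the model-implied observation SD
    ``sqrt(sigma_add^2 + (sigma_prop f)^2)`` with predictions conditioned on
    each dataset's posterior-mean random effects.  If the model is right,
    CWRES are approximately standard normal with no systematic structure in
    time or tissue.
    """
    table = _conditional_predictions(fit)
    sa = float(fit.sigma_add.mean())
    sp = float(fit.sigma_prop.mean())
    sd = np.sqrt(sa ** 2 + (sp * table["PRED"].to_numpy()) ** 2)
    if np.any(sd <= 0) or not np.all(np.isfinite(sd)):
        raise NumericError("singular observation covariance in CWRES computation")
    table["RES"] = table["DV"] - table["PRED"]
    table["CWRES"] = table["RES"] / sd
    return table


def chain_stability(chains, first: float = 0.1, last: float = 0.5,
                    z_limit: float = 2.0) -> pd.DataFrame:
    """Stationarity screen of MCMC traces.

    For each chain a Geweke-style z-statistic compares the mean of the first
    10% of samples with the mean of the last 50%; ``|z| > 2`` flags the
    parameter as unstable.  A normalized running-mean slope (total drift of
    the chain in units of its SD) is reported alongside.  The model-level
    verdict is "unstable" if any parameter is flagged.
    """
    if isinstance(chains, FitResult):
        chains = chains.chains()
    rows = []
    for name, chain in chains.items():
        chain = np.asarray(chain, dtype=float)
        n = len(chain)
        if n < 100:
            raise StateError(f"chain {name!r} too short for stability assessment (n={n})")
        a = chain[: max(1, int(first * n))]
        b = chain[-max(1, int(last * n)):]
        var = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        z = 0.0 if var == 0 else float((a.mean() - b.mean()) / math.sqrt(var))
        sd = chain.std(ddof=1)
        if sd == 0:
            slope = 0.0
        else:
            x = np.arange(n, dtype=float)
            slope = float(np.polyfit(x, chain, 1)[0] * n / sd)  # drift over run, in SDs
        rows.append({"parameter": name, "z": z, "drift_sd": slope,
                     "stable": abs(z) <= z_limit})
    table = pd.DataFrame(rows).set_index("parameter")
    table.attrs["stable"] = bool(table["stable"].all())
    return table


def dic_from_deviance(deviance_trace: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """Deviance information criterion from a total-deviance trace.

    ``pD = Dbar - Dhat`` (effective number of parameters) and
    ``DIC = Dbar + pD``.
    """
    trace = np.asarray(deviance_trace, dtype=float)
    if trace.size == 0:
        raise StateError("empty deviance trace")
    dbar = float(trace.mean())
    pd_eff = dbar - float(deviance_at_mean)
    return dbar + pd_eff, pd_eff


def compute_dic(fit: FitResult) -> tuple[float, float]:
    """DIC and effective-parameter count for a fitted model.

    The deviance is the total conditional -2 log likelihood; the plug-in
    deviance is evaluated at the posterior means of the population
    parameters, random effects and lags.
    """
    from .estimation import eta_penalty
    engine = _Engine(fit.model, fit.data)
    lt = np.log(fit.theta.mean(axis=0))
    beta = fit.beta.mean(axis=0) if fit.beta.size else np.zeros(0)
    eta = fit.posterior_mean_eta()
    lag = fit.posterior_mean_lag()
    sa = float(fit.sigma_add.mean())
    sp = float(fit.sigma_prop.mean())
    off = engine.cov_offsets(beta)
    dhat = float(np.sum(eta_penalty(eta, fit.omega2.mean(axis=0))))
    for d in range(engine.N):
        m2, _ = engine.dataset_eval(lt + off[d] + eta[d], lag[d], d, sa, sp)
        dhat += m2
    return dic_from_deviance(fit.ofv_trace.sum(axis=1), dhat)


@dataclass
class ComparisonResult:
    """OFV / DIC comparison of several fits of the same data."""

    reference: str
    table: pd.DataFrame
    preferred: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ComparisonResult(reference={self.reference!r}, preferred={self.preferred!r})\n{self.table}"


def compare_models(fits: dict[str, FitResult], reference: str) -> ComparisonResult:
    """Delta-OFV (candidate - reference) and DIC for a family of fits run on
    identical data; the preferred model is the one with the lowest DIC."""
    if reference not in fits:
        raise ComparisonError(f"reference {reference!r} not among fits")
    ids = list(fits[reference].dataset_ids)
    for name, fit in fits.items():
        if list(fit.dataset_ids) != ids:
            raise ComparisonError(f"fit {name!r} was run on different datasets")
    ref_ofv = compute_ofv(fits[reference])[0]
    rows = []
    for name, fit in fits.items():
        total = compute_ofv(fit)[0]
        dic, pd_eff = compute_dic(fit)
        rows.append({"model": name, "ofv": total, "delta_ofv": total - ref_ofv,
                     "dic": dic, "pd": pd_eff})
    table = pd.DataFrame(rows).set_index("model")
    preferred = str(table["dic"].idxmin())
    return ComparisonResult(reference=reference, table=table, preferred=preferred)


def correlation_flattening(corr) -> np.ndarray:
    """Flattening factors ``f = 1 - r`` for a correlation matrix.

    ``f`` is the minor/major axis ratio of the correlation ellipse: 0 for
    perfect correlation (a line), 1 for no correlation (a circle), up to 2
    for perfect anticorrelation.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise DataError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise DataError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise DataError("correlation matrix must have unit diagonal")
    if np.any(np.abs(corr) > 1 + 1e-12):
        raise DataError("correlation coefficients must lie in [-1, 1]")
    return 1.0 - corr


# ---------------------------------------------------------------------------
# covariate scan
# ---------------------------------------------------------------------------

def admissible_covariate_pairs(graph) -> list[tuple[str, str]]:
    """The physiologically admissible (covariate, rate) pairs: the systemic
    anesthesia covariate on muscle or liver transfer constants, the local
    tumor-vitality covariate on the tumor exchange constants."""
    names = graph.rate_names()
    pairs = [("anest", n) for n in names if ("M" in n or "L" in n) and "T" not in n]
    pairs += [("vti", n) for n in ("k_T2T3", "k_T3T2") if n in names]
    return pairs


def _make_spec(covariate: str, rate: str) -> CovariateSpec:
    if covariate == "anest":
        return CovariateSpec(name="anest", target=rate, kind="binary",
                             coefficients={"beta": 0.0})
    if covariate == "vti":
        return CovariateSpec(name="vti", target=rate, kind="categorical",
                             levels=(1, 2, 3, 4), reference=1,
                             coefficients={2: 0.0, 3: 0.0, 4: 0.0})
    raise DataError(f"unknown covariate {covariate!r}")


def covariate_scan(data: StudyDataset, base_model: PopulationModel,
                   config: SamplerConfig, pairs=None,
                   base_fit: FitResult | None = None) -> pd.DataFrame:
    """Exhaustive single-covariate scan.

    Fits one covariate model per admissible (covariate, rate) pair and
    tabulates the OFV drop versus the base model together with the
    coefficient estimates and their SE%.  Models whose coefficient SE%
    explodes are the ones a covariate-selection step would discard.
    """
    if pairs is None:
        pairs = admissible_covariate_pairs(base_model.graph)
    if base_fit is None:
        base_fit = fit_model(base_model, data, config)
    base_ofv = compute_ofv(base_fit)[0]
    rows = []
    for covariate, rate in pairs:
        spec = _make_spec(covariate, rate)
        model = build_fit_model(base_model.graph, covariates=(spec,),
                                initial_rates=base_model.theta)
        fit = fit_model(model, data, config)
        total = compute_ofv(fit)[0]
        summary = summarize_posterior(fit)
        coef_rows = summary.loc[[n for n in summary.index if n.startswith("beta_")]]
        rows.append({
            "covariate": covariate, "rate": rate,
            "delta_ofv": total - base_ofv,
            "max_se_pct": float(coef_rows["se_pct"].max()),
            "coefficients": {n: float(coef_rows.loc[n, "estimate"]) for n in coef_rows.index},
        })
    return pd.DataFrame(rows)


#: Default SE% retention limits per covariate: a coefficient whose relative
#: posterior uncertainty exceeds its limit marks the model as unreliable.
SE_RETENTION_LIMITS = {"anest": 55.0, "vti": 30.0}


def retain_covariates(scan: pd.DataFrame, se_limits=None) -> pd.DataFrame:
    """Filter a covariate-scan table down to the reliable models.

    A covariate model is retained only when every coefficient's SE% stays at
    or below the covariate's limit; everything else is the scan's way of
    flagging practically unsupported effects.
    """
    limits = dict(SE_RETENTION_LIMITS)
    if se_limits:
        limits.update(se_limits)
    keep = scan.apply(lambda row: row["max_se_pct"] <= limits.get(row["covariate"], 50.0),
                      axis=1)
    return scan[keep].reset_index(drop=True)
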