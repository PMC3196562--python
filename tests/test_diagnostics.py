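"""Diagnostics: CWRES, chain stability, DIC arithmetic, model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from dcepop import (ComparisonError, DataError, REFERENCE_RATES, StateError,
                    StudyDesign, chain_stability, compare_models, compute_cwres,
                    compute_dic, compute_ofv, correlation_flattening,
                    dic_from_deviance, generate_study, mtl3_graph)
from dcepop.estimation import FitResult, SamplerConfig, build_fit_model


def _point_mass_fit(study, graph, n_samples=120):
    """A FitResult whose posterior is a point mass at the generating truth.

    Data simulated from this 'fitted model' are exactly self-consistent,
    which is the calibration case for CWRES and the degenerate case for DIC.
    """
    model = build_fit_model(graph, init_omega2=0.09,
                            init_sigma_add=0.005, init_sigma_prop=0.05)
    names = graph.rate_names()
    R, N = len(names), study.n_datasets
    theta = np.tile([REFERENCE_RATES[n] for n in names], (n_samples, 1))
    truth = study.truth.set_index("ID")
    eta = np.zeros((n_samples, N, R))
    lag = np.zeros((n_samples, N))
    for d, ds in enumerate(study.ids):
        for j, n in enumerate(names):
            eta[:, d, j] = truth.loc[ds, f"eta_{n}"]
        lag[:, d] = truth.loc[ds, "lag"]
    from dcepop.estimation import _Engine, eta_penalty
    engine = _Engine(model, study)
    lt = np.log(theta[0])
    penalty = eta_penalty(eta[0], np.full(R, 0.09))
    ofv = np.empty((n_samples, N))
    for d in range(N):
        m2, _ = engine.dataset_eval(lt + eta[0, d], lag[0, d], d, 0.005, 0.05)
        ofv[:, d] = m2 + penalty[d]
    return FitResult(
        graph=graph, model=model, data=study, config=SamplerConfig(),
        rate_names=list(names), beta_names=[], dataset_ids=list(study.ids),
        theta=theta, omega2=np.full((n_samples, R), 0.09),
        sigma_add=np.full(n_samples, 0.005), sigma_prop=np.full(n_samples, 0.05),
        beta=np.zeros((n_samples, 0)), eta=eta, lag=lag, ofv_trace=ofv,
    )


@pytest.fixture(scope="module")
def truth_fit():
    design = StudyDesign(n_datasets=12, vti_group_sizes=(6, 2, 2, 2), seed=31)
    study = generate_study(design)
    return study, _point_mass_fit(study, mtl3_graph())


class TestCwres:
    def test_self_simulated_data_standard_normal(self, truth_fit):
        """Data simulated from the fitted model give CWRES ~ N(0, 1)."""
        _, fit = truth_fit
        table = compute_cwres(fit)
        assert abs(table["CWRES"].mean()) < 0.1
        assert 0.9 < table["CWRES"].std() < 1.1

    def test_additive_only_reduces_to_z_score(self, truth_fit):
        study, fit = truth_fit
        fit_add = FitResult(**{**vars(fit),
                               "sigma_prop": np.zeros_like(fit.sigma_prop),
                               "sigma_add": np.full_like(fit.sigma_add, 0.01)})
        table = compute_cwres(fit_add)
        np.testing.assert_allclose(table["CWRES"], table["RES"] / 0.01, rtol=1e-12)

    def test_underprediction_gives_positive_mean(self, truth_fit):
        """Shifting one tissue's data upward leaves that tissue's CWRES
        systematically positive."""
        study, fit = truth_fit
        shifted = study.observations.copy()
        mask = shifted["TISSUE"] == "tumor"
        shifted.loc[mask, "DV"] += 0.05
        study2 = type(study)(observations=shifted, subjects=study.subjects,
                             truth=study.truth)
        fit2 = FitResult(**{**vars(fit), "data": study2})
        table = compute_cwres(fit2)
        assert table.loc[table["TISSUE"] == "tumor", "CWRES"].mean() > 0.5
        assert abs(table.loc[table["TISSUE"] == "muscle", "CWRES"].mean()) < 0.2

    def test_one_row_per_observation(self, truth_fit):
        study, fit = truth_fit
        assert len(compute_cwres(fit)) == len(study.observations)


class TestChainStability:
    def test_white_noise_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flags = []
        for _ in range(200):
            table = chain_stability({"x": rng.normal(size=1000)})
            flags.append(bool(table["stable"].iloc[0]))
        assert np.mean(flags) >= 0.95

    def test_linear_trend_flagged(self):
        rng = np.random.default_rng(1)
        chain = rng.normal(size=1000) + np.linspace(0.0, 3.0, 1000)
        table = chain_stability({"x": chain})
        assert not table["stable"].iloc[0]
        assert table["drift_sd"].iloc[0] > 1.0

    def test_constant_chain_stable_with_zero_z(self):
        table = chain_stability({"x": np.full(500, 2.5)})
        assert table["z"].iloc[0] == 0.0
        assert table["stable"].iloc[0]

    def test_short_chain_rejected(self):
        with pytest.raises(StateError):
            chain_stability({"x": np.zeros(50)})

    def test_model_level_flag_any_parameter(self):
        rng = np.random.default_rng(2)
        table = chain_stability({
            "good": rng.normal(size=1000),
            "bad": rng.normal(size=1000) + np.linspace(0, 4, 1000),
        })
        assert table.attrs["stable"] is False


class TestDic:
    def test_point_mass_posterior_gives_zero_pd(self, truth_fit):
        _, fit = truth_fit
        dic, pd_eff = compute_dic(fit)
        total, _ = compute_ofv(fit)
        assert pd_eff == pytest.approx(0.0, abs=1e-6)
        assert dic == pytest.approx(total, rel=1e-9)

    def test_normal_mean_toy_effective_parameters(self):
        """For a normal-mean model with a flat prior, pD is ~1 (one
        effective parameter); checked against the exact posterior."""
        rng = np.random.default_rng(7)
        n, sigma = 40, 1.0
        y = rng.normal(0.3, sigma, size=n)
        # exact posterior: mu ~ N(ybar, sigma^2/n)
        mus = rng.normal(y.mean(), sigma / math.sqrt(n), size=200_000)
        dev = np.array([np.sum((y - m) ** 2) / sigma ** 2 for m in mus]) \
            + n * math.log(2 * math.pi * sigma ** 2)
        dev_at_mean = np.sum((y - mus.mean()) ** 2) / sigma ** 2 \
            + n * math.log(2 * math.pi * sigma ** 2)
        dic, pd_eff = dic_from_deviance(dev, dev_at_mean)
        assert pd_eff == pytest.approx(1.0, abs=0.05)

    def test_empty_trace_rejected(self):
        with pytest.raises(StateError):
            dic_from_deviance(np.array([]), 0.0)


class TestCompareModels:
    def test_self_comparison_zero_delta(self, truth_fit):
        _, fit = truth_fit
        result = compare_models({"a": fit, "b": fit}, reference="a")
        np.testing.assert_allclose(result.table["delta_ofv"], 0.0, atol=1e-9)
        assert result.preferred in ("a", "b")

    def test_duplicating_dataset_adds_its_ofv(self, truth_fit):
        _, fit = truth_fit
        total, ofv_i = compute_ofv(fit)
        assert total == pytest.approx(ofv_i.sum())
        # additivity: the total is exactly the sum of per-dataset terms,
        # so adding a dataset's trace adds exactly its OFV_i
        ds = fit.dataset_ids[0]
        augmented = np.concatenate([fit.ofv_trace, fit.ofv_trace[:, :1]], axis=1)
        assert augmented.mean(axis=0).sum() == pytest.approx(total + ofv_i[ds])

    def test_dataset_mismatch_rejected(self, truth_fit):
        study, fit = truth_fit
        sub = study.subset(study.ids[:6])
        fit_sub = _point_mass_fit(sub, mtl3_graph())
        with pytest.raises(ComparisonError):
            compare_models({"a": fit, "b": fit_sub}, reference="a")

    def test_ofv_matches_recompute_oracle(self, truth_fit):
        """OFV_i equals a brute-force mean over the stored trace."""
        _, fit = truth_fit
        total, ofv_i = compute_ofv(fit)
        for d, ds in enumerate(fit.dataset_ids):
            assert ofv_i[ds] == pytest.approx(float(np.mean(fit.ofv_trace[:, d])))


class TestCorrelationFlattening:
    def test_reference_values(self):
        corr = np.array([[1.0, 1.0, 0.0, 0.25],
                         [1.0, 1.0, 0.0, 0.25],
                         [0.0, 0.0, 1.0, 0.0],
                         [0.25, 0.25, 0.0, 1.0]])
        f = correlation_flattening(corr)
        assert f[0, 1] == 0.0     # perfect correlation -> line
        assert f[0, 2] == 1.0     # no correlation -> circle
        assert f[0, 3] == 0.75
        np.testing.assert_array_equal(np.diag(f), 0.0)

    def test_range_covers_anticorrelation(self):
        corr = np.array([[1.0, -1.0], [-1.0, 1.0]])
        f = correlation_flattening(corr)
        assert f[0, 1] == 2.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            correlation_flattening(np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(DataError):
            correlation_flattening(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestCovariateScan:
    def test_retention_rule_limits_by_covariate(self):
        scan = pd.DataFrame([
            {"covariate": "anest", "rate": "k_M1C", "delta_ofv": -5.0, "max_se_pct": 50.0},
            {"covariate": "anest", "rate": "k_L1C", "delta_ofv": -2.0, "max_se_pct": 60.0},
            {"covariate": "vti", "rate": "k_T3T2", "delta_ofv": -8.0, "max_se_pct": 25.0},
            {"covariate": "vti", "rate": "k_T2T3", "delta_ofv": -1.0, "max_se_pct": 35.0},
        ])
        from dcepop.diagnostics import retain_covariates
        kept = retain_covariates(scan)
        assert list(zip(kept["covariate"], kept["rate"])) == \
            [("anest", "k_M1C"), ("vti", "k_T3T2")]

    def test_admissible_pairs_respect_physiology(self):
        """The systemic covariate may touch muscle/liver rates only; the
        tumor-vitality covariate only the tumor exchange constants."""
        from dcepop.diagnostics import admissible_covariate_pairs
        pairs = admissible_covariate_pairs(mtl3_graph())
        anest_rates = [r for c, r in pairs if c == "anest"]
        vti_rates = [r for c, r in pairs if c == "vti"]
        assert sorted(vti_rates) == ["k_T2T3", "k_T3T2"]
        assert "k_M1C" in anest_rates and "k_L1C" in anest_rates
        assert not any("T" in r for r in anest_rates)

    def test_scan_reports_ofv_drop_and_se(self):
        """Single-pair scan on a small simulated study produces the dOFV and
        SE% columns the retention rule consumes."""
        from dcepop import StudyDesign, degrade_schedule, generate_study
        from dcepop.diagnostics import covariate_scan
        from dcepop.estimation import SamplerConfig, build_fit_model
        design = StudyDesign(n_datasets=6, vti_group_sizes=(3, 1, 1, 1), seed=61)
        study = degrade_schedule(generate_study(design), 3)
        cfg = SamplerConfig.preset("smoke", seed=2)
        base = build_fit_model(mtl3_graph())
        scan = covariate_scan(study, base, cfg, pairs=[("anest", "k_M1C")])
        assert len(scan) == 1
        assert np.isfinite(scan.loc[0, "delta_ofv"])
        assert scan.loc[0, "max_se_pct"] > 0


class TestOverParameterizationGuard:
    def test_many_simultaneous_covariates_trip_the_guard(self):
        """Applying covariates to four transfer constants at once on a small
        study must show up as chain instability or SE% blow-up."""
        from dcepop import (SamplerConfig, StudyDesign, degrade_schedule,
                            fit_model, generate_study, summarize_posterior)
        from dcepop.estimation import build_fit_model
        from dcepop.population import CovariateSpec
        specs = (
            CovariateSpec(name="anest", target="k_M1C", kind="binary",
                          coefficients={"beta": 0.0}),
            CovariateSpec(name="anest", target="k_L1C", kind="binary",
                          coefficients={"beta": 0.0}),
            CovariateSpec(name="vti", target="k_T3T2", kind="categorical",
                          levels=(1, 2, 3, 4), reference=1,
                          coefficients={2: 0.0, 3: 0.0, 4: 0.0}),
            CovariateSpec(name="vti", target="k_T2T3", kind="categorical",
                          levels=(1, 2, 3, 4), reference=1,
                          coefficients={2: 0.0, 3: 0.0, 4: 0.0}),
        )
        design = StudyDesign(n_datasets=10, vti_group_sizes=(5, 3, 1, 1),
                             anest_fraction=1.0, seed=55)
        study = degrade_schedule(generate_study(design), 3)
        fit = fit_model(build_fit_model(mtl3_graph(), covariates=specs),
                        study, SamplerConfig.preset("smoke", seed=5))
        summary = summarize_posterior(fit)
        beta_se = summary.loc[[n for n in summary.index if n.startswith("beta_")],
                              "se_pct"]
        unstable = not chain_stability(fit).attrs["stable"]
        assert unstable or beta_se.max() > 55.0
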