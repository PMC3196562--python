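"""Estimation machinery: SAEM, MCMC, posterior summaries.

Heavy full-model recovery lives in the acceptance suite; here a
two-compartment toy (latent central + observed muscle) exercises the same
code paths at a fraction of the cost.
"""

import math

import numpy as np
import pandas as pd
import pytest

from dcepop import (CompartmentGraph, EstimationError, KineticParameters,
                    PopulationModel, StudyDataset, derive_volumes, draw_individual,
                    fit_model, run_mcmc, saem_initialize, simulate_amounts,
                    summarize_posterior)
from dcepop.estimation import (SamplerConfig, build_fit_model,
                               random_walk_metropolis)

TOY_TRUTH = {"k_C0": 0.013, "k_CM2": 0.1, "k_M2C": 0.01}
TOY_INIT = {"k_C0": 0.03, "k_CM2": 0.3, "k_M2C": 0.03}
ONE_COMP_TRUTH = {"k_C0": 0.013}


def toy_graph() -> CompartmentGraph:
    return CompartmentGraph(("C", "M2"), ("M2",),
                            {("C", "M2"): "k_CM2", ("M2", "C"): "k_M2C"},
                            "C", ("C", "k_C0"))


def one_comp_graph() -> CompartmentGraph:
    """Single observed compartment with first-order elimination: the dosed
    space is measured directly, so the rate is identified by both the decay
    slope and (through V = Cl/k) the concentration scale."""
    return CompartmentGraph(("M2",), ("M2",), {}, "M2", ("M2", "k_C0"))


def toy_study(n_datasets: int, seed: int, omega2: float = 0.09,
              sigma_add: float = 0.005, sigma_prop: float = 0.05,
              lag_sd: float = 5.0, at_typical: bool = False,
              graph: CompartmentGraph | None = None,
              truth_rates: dict | None = None) -> StudyDataset:
    """Simulate single-tissue bolus data from the toy truth."""
    g = toy_graph() if graph is None else graph
    truth_rates = dict(TOY_TRUTH) if truth_rates is None else dict(truth_rates)
    truth = PopulationModel(
        graph=g, theta=truth_rates,
        omega2={n: omega2 for n in g.rate_names()},
        sigma_add=max(sigma_add, 1e-300), sigma_prop=sigma_prop, lag_sd=lag_sd)
    rng = np.random.default_rng(seed)
    times = np.concatenate([np.arange(6.0, 181.0, 6.0), np.arange(204.0, 901.0, 24.0)])
    obs_rows, subj_rows = [], []
    for ds in range(1, n_datasets + 1):
        ind = draw_individual(truth, {"anest": 0, "vti": 1}, rng, dataset_id=ds)
        if at_typical:
            ind.rates = dict(truth_rates)
            ind.lag = truth.lag_mean
        params = KineticParameters(dict(ind.rates))
        traj = simulate_amounts(g, params, 60.0, ind.lag, times)
        vols = derive_volumes(g, params)
        f = traj.amount("M2") / vols.volumes["M2"]
        y = f * (1.0 + sigma_prop * rng.normal(size=f.shape)) \
            + sigma_add * rng.normal(size=f.shape)
        for t, val in zip(times, y):
            obs_rows.append({"ID": ds, "OCC": "pre", "TIME": t, "TISSUE": "muscle",
                             "DV": float(val)})
        subj_rows.append({"ID": ds, "OCC": "pre", "DOSE": 60.0, "ANEST": 0, "VTI": 1})
    return StudyDataset(pd.DataFrame(obs_rows), pd.DataFrame(subj_rows))


def toy_fit_model(**kw) -> PopulationModel:
    return build_fit_model(toy_graph(), initial_rates=TOY_INIT, **kw)


class TestSamplerConfig:
    def test_protocol_defaults(self):
        cfg = SamplerConfig()
        assert cfg.saem_iterations == 120
        assert cfg.burn_in_samples == 3000
        assert cfg.estimation_samples == 3000

    def test_fast_preset(self):
        cfg = SamplerConfig.preset("fast")
        assert (cfg.burn_in_samples, cfg.estimation_samples) == (500, 500)

    def test_invalid_counts_rejected(self):
        with pytest.raises(EstimationError):
            SamplerConfig(burn_in_samples=0)


class TestSaem:
    def test_truth_is_a_fixed_point(self):
        """Noise-free data at the typical values, initialization at truth,
        negligible residual SDs: the estimates do not move."""
        study = toy_study(5, seed=2, omega2=0.0, sigma_add=0.0, sigma_prop=0.0,
                          lag_sd=0.0, at_typical=True)
        model = build_fit_model(toy_graph(), initial_rates=TOY_TRUTH,
                                init_omega2=1e-4,
                                init_sigma_add=1e-6, init_sigma_prop=1e-6)
        cfg = SamplerConfig(saem_iterations=10, burn_in_samples=1,
                            estimation_samples=1, seed=0)
        init = saem_initialize(model, study, cfg)
        for name, value in zip(init.rate_names, init.theta):
            assert value == pytest.approx(TOY_TRUTH[name], rel=1e-6)

    def test_one_compartment_recovery_from_threefold_offset_init(self):
        """SAEM pulls the elimination rate within 10% of truth from a 3x-off
        start on 20 simulated datasets of the one-compartment toy."""
        g = one_comp_graph()
        study = toy_study(20, seed=8, graph=g, truth_rates=ONE_COMP_TRUTH)
        model = build_fit_model(g, initial_rates={"k_C0": 0.04})
        cfg = SamplerConfig(saem_iterations=80, burn_in_samples=1,
                            estimation_samples=1, seed=1)
        init = saem_initialize(model, study, cfg)
        assert init.theta[0] == pytest.approx(0.013, rel=0.10)

    def test_sigma_estimates_recovered(self):
        g = one_comp_graph()
        study = toy_study(20, seed=8, graph=g, truth_rates=ONE_COMP_TRUTH)
        model = build_fit_model(g, initial_rates={"k_C0": 0.04})
        cfg = SamplerConfig(saem_iterations=80, burn_in_samples=1,
                            estimation_samples=1, seed=1)
        init = saem_initialize(model, study, cfg)
        assert init.sigma_prop == pytest.approx(0.05, rel=0.25)
        assert init.sigma_add == pytest.approx(0.005, rel=0.5)


class TestMcmc:
    def test_fixed_seed_bit_reproducible(self):
        study = toy_study(3, seed=4)
        cfg = SamplerConfig(saem_iterations=5, burn_in_samples=20,
                            estimation_samples=30, seed=9)
        a = fit_model(toy_fit_model(), study, cfg)
        b = fit_model(toy_fit_model(), study, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.eta, b.eta)
        np.testing.assert_array_equal(a.ofv_trace, b.ofv_trace)

    def test_posterior_covers_truth_on_one_compartment_toy(self):
        g = one_comp_graph()
        study = toy_study(20, seed=5, graph=g, truth_rates=ONE_COMP_TRUTH)
        model = build_fit_model(g, initial_rates={"k_C0": 0.03})
        cfg = SamplerConfig(saem_iterations=60, burn_in_samples=200,
                            estimation_samples=200, seed=3)
        fit = fit_model(model, study, cfg)
        summary = summarize_posterior(fit)
        est = summary.loc["theta_k_C0", "estimate"]
        assert est == pytest.approx(0.013, rel=0.15)
        assert summary.loc["theta_k_C0", "ci_lower"] < est < \
            summary.loc["theta_k_C0", "ci_upper"]

    def test_clearance_never_sampled(self):
        study = toy_study(3, seed=4)
        cfg = SamplerConfig(saem_iterations=5, burn_in_samples=20,
                            estimation_samples=30, seed=9)
        fit = fit_model(toy_fit_model(), study, cfg)
        assert "Cl" not in fit.chains()
        assert fit.clearance == 0.04

    def test_posterior_contraction_with_more_data(self):
        """Doubling the number of datasets shrinks the average 95%-CI width
        of the typical values."""
        cfg = SamplerConfig(saem_iterations=40, burn_in_samples=150,
                            estimation_samples=150, seed=2)
        g = one_comp_graph()
        model = build_fit_model(g, initial_rates={"k_C0": 0.02})
        widths = {}
        for n in (6, 24):
            study = toy_study(n, seed=6, graph=g, truth_rates=ONE_COMP_TRUTH)
            fit = fit_model(model, study, cfg)
            s = summarize_posterior(fit)
            widths[n] = float(np.log(s.loc["theta_k_C0", "ci_upper"])
                              - np.log(s.loc["theta_k_C0", "ci_lower"]))
        assert widths[24] < widths[6]


class TestMetropolisKernel:
    def test_conjugate_normal_mean_posterior(self):
        """Flat-prior normal mean with known variance: the kernel reproduces
        the closed-form posterior mean and SD within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n, sigma = 25, 2.0
        y = rng.normal(1.0, sigma, size=n)
        post_mean, post_sd = y.mean(), sigma / math.sqrt(n)

        def logpdf(mu):
            return -0.5 * np.sum((y - mu) ** 2) / sigma ** 2

        chain = random_walk_metropolis(logpdf, x0=0.0, n_samples=40_000,
                                       burn_in=2_000, seed=13)
        assert chain.mean() == pytest.approx(post_mean, abs=3 * post_sd / 50)
        assert chain.std() == pytest.approx(post_sd, rel=0.05)


class TestSummaries:
    def _const_fit_frame(self, chain):
        from dcepop.estimation import FitResult
        g = toy_graph()
        model = toy_fit_model()
        S = len(chain)
        return FitResult(
            graph=g, model=model, data=None, config=SamplerConfig(),
            rate_names=["k_C0", "k_CM2", "k_M2C"], beta_names=[], dataset_ids=[1],
            theta=np.column_stack([chain, chain, chain]),
            omega2=np.full((S, 3), 0.01),
            sigma_add=np.full(S, 0.005), sigma_prop=np.full(S, 0.05),
            beta=np.zeros((S, 0)), eta=np.zeros((S, 1, 3)), lag=np.zeros((S, 1)),
            ofv_trace=np.zeros((S, 1)))

    def test_constant_chain(self):
        fit = self._const_fit_frame(np.full(100, 2.5))
        s = summarize_posterior(fit)
        row = s.loc["theta_k_C0"]
        assert row["estimate"] == 2.5
        assert row["ci_lower"] == row["ci_upper"] == 2.5
        assert row["se_pct"] == 0.0

    def test_iid_normal_se_pct(self):
        rng = np.random.default_rng(3)
        fit = self._const_fit_frame(rng.normal(2.0, 0.2, size=50_000))
        s = summarize_posterior(fit)
        assert s.loc["theta_k_C0", "se_pct"] == pytest.approx(10.0, abs=0.3)

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(4)
        chain = rng.lognormal(0.0, 1.0, size=4001)
        fit = self._const_fit_frame(chain)
        s = summarize_posterior(fit)
        srt = np.sort(chain)
        lo = np.percentile(chain, 2.5)
        hi = np.percentile(chain, 97.5)
        assert s.loc["theta_k_C0", "ci_lower"] == pytest.approx(lo)
        assert s.loc["theta_k_C0", "ci_upper"] == pytest.approx(hi)
        assert srt[int(0.025 * len(srt))] == pytest.approx(lo, rel=0.01)
        assert srt[int(0.975 * len(srt))] == pytest.approx(hi, rel=0.01)


class TestCentralCurve:
    def test_point_mass_posterior_equals_forward_solution(self):
        from dcepop import central_curve
        study = toy_study(2, seed=1)
        g = toy_graph()
        from dcepop.estimation import FitResult
        S = 50
        theta = np.tile([TOY_TRUTH[n] for n in ("k_C0", "k_CM2", "k_M2C")], (S, 1))
        fit = FitResult(
            graph=g, model=toy_fit_model(), data=study, config=SamplerConfig(),
            rate_names=["k_C0", "k_CM2", "k_M2C"], beta_names=[],
            dataset_ids=study.ids, theta=theta, omega2=np.full((S, 3), 0.01),
            sigma_add=np.full(S, 0.005), sigma_prop=np.full(S, 0.05),
            beta=np.zeros((S, 0)), eta=np.zeros((S, 2, 3)),
            lag=np.full((S, 2), 10.0), ofv_trace=np.zeros((S, 2)))
        times = np.array([10.0, 20.0, 60.0, 300.0, 900.0])
        curve = central_curve(fit, times)
        params = KineticParameters(dict(TOY_TRUTH))
        traj = simulate_amounts(g, params, 60.0, 10.0, times)
        v_c = 0.04 / TOY_TRUTH["k_C0"]
        np.testing.assert_allclose(curve["median"], traj.amount("C") / v_c, rtol=1e-10)
        np.testing.assert_allclose(curve["lower"], curve["upper"], rtol=1e-10)
        # just after the lag the curve starts at dose / V_c before distribution
        assert curve["median"][0] == pytest.approx(60.0 / v_c, rel=0.05)
        # linear elimination: eventually monotone decreasing and non-negative
        assert np.all(curve["median"] >= 0)
        assert np.all(np.diff(curve["median"][1:]) < 0)

    def test_empty_chains_rejected(self):
        from dcepop import StateError, central_curve
        from dcepop.estimation import FitResult
        fit = FitResult(
            graph=toy_graph(), model=toy_fit_model(), data=None,
            config=SamplerConfig(), rate_names=["k_C0", "k_CM2", "k_M2C"],
            beta_names=[], dataset_ids=[], theta=np.empty((0, 3)),
            omega2=np.empty((0, 3)), sigma_add=np.empty(0), sigma_prop=np.empty(0),
            beta=np.empty((0, 0)), eta=np.empty((0, 0, 3)), lag=np.empty((0, 0)),
            ofv_trace=np.empty((0, 0)))
        with pytest.raises(StateError):
            central_curve(fit, [10.0, 20.0])
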