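import math

import numpy as np
import pandas as pd
import pytest

from bpaqivive.calibration import (ChainSet, HierarchicalCalibration, PriorSpec,
                                   csaf, gelman_rubin, log_likelihood, summarize)
from bpaqivive.constants import ANALYTES
from bpaqivive.errors import DomainError
from bpaqivive.synthetic import HbmDataset


def _toy_dataset(n_ind=3, times=(1.0, 2.0, 4.0, 8.0), k_true=0.5, a_true=10.0,
                 sigma=0.0, seed=0):
    """One-compartment bolus: conc = a * BW-free exp(-k t) per analyte scale."""
    rng = np.random.default_rng(seed)
    scale = {"BPA": 1.0, "BPAG": 20.0, "BPAS": 3.0}
    rows = []
    for i in range(1, n_ind + 1):
        for a in ANALYTES:
            for t in times:
                c = a_true * scale[a] * math.exp(-k_true * t)
                c += rng.normal(0, sigma) if sigma else 0.0
                rows.append({"individual": i, "time_h": t, "analyte": a,
                             "conc": max(c, 0.0), "unit": "ug/L"})
    obs = pd.DataFrame(rows)
    bw = pd.Series({i: 70.0 for i in range(1, n_ind + 1)})
    return HbmDataset(observations=obs, body_weights=bw, dose_per_bw=100.0)


def _toy_predictor(scale):
    def predictor(params, bw, dose, times):
        k = params["K1_BPA_Urine"] * 400.0      # borrow a prior as the rate
        amp = params["MPY"]
        return {a: amp * scale[a] * np.exp(-k * np.asarray(times))
                for a in ANALYTES}
    return predictor


class TestLogLikelihood:
    def test_zero_residual_closed_form(self):
        data = _toy_dataset(n_ind=1, sigma=0.0)
        preds = {}
        for a in ANALYTES:
            d = data.observations
            preds[(1, a)] = d[(d["individual"] == 1) & (d["analyte"] == a)]["conc"].to_numpy()
        n = len(data.observations)
        ll = log_likelihood(preds, data, {a: 1.0 for a in ANALYTES})
        assert ll == pytest.approx(-n / 2 * math.log(2 * math.pi), rel=1e-12)

    def test_doubling_residuals_decreases(self):
        data = _toy_dataset(n_ind=1)
        base, doubled = {}, {}
        for a in ANALYTES:
            d = data.observations
            y = d[(d["individual"] == 1) & (d["analyte"] == a)]["conc"].to_numpy()
            base[(1, a)] = y + 0.5
            doubled[(1, a)] = y + 1.0
        s = {a: 1.0 for a in ANALYTES}
        assert log_likelihood(doubled, data, s) < log_likelihood(base, data, s)

    def test_matches_brute_force_density_sum(self):
        data = _toy_dataset(n_ind=2, sigma=0.3, seed=5)
        sig = {"BPA": 0.7, "BPAG": 5.0, "BPAS": 1.1}
        preds, brute = {}, 0.0
        for i in (1, 2):
            for a in ANALYTES:
                d = data.observations
                y = d[(d["individual"] == i) & (d["analyte"] == a)]["conc"].to_numpy()
                p = y * 0.9 + 0.1
                preds[(i, a)] = p
                for yo, pp in zip(y, p):
                    brute += math.log(
                        math.exp(-((yo - pp) ** 2) / (2 * sig[a] ** 2))
                        / math.sqrt(2 * math.pi * sig[a] ** 2))
        assert log_likelihood(preds, data, sig) == pytest.approx(brute, abs=1e-10)

    def test_order_invariance(self):
        data = _toy_dataset(n_ind=2, sigma=0.2, seed=3)
        shuffled = HbmDataset(
            observations=data.observations.sample(frac=1.0, random_state=1),
            body_weights=data.body_weights, dose_per_bw=data.dose_per_bw)
        preds = {(i, a): data.observations[
            (data.observations["individual"] == i)
            & (data.observations["analyte"] == a)]["conc"].to_numpy() * 0.95
            for i in (1, 2) for a in ANALYTES}
        s = {a: 1.0 for a in ANALYTES}
        # the likelihood is a sum over observations, so row order cannot matter
        assert log_likelihood(preds, data, s) == pytest.approx(
            log_likelihood(preds, shuffled, s))


class TestMcmc:
    def test_prior_only_recovers_prior_quantiles(self):
        data = _toy_dataset(n_ind=2)
        scale = {"BPA": 1.0, "BPAG": 20.0, "BPAS": 3.0}
        cal = HierarchicalCalibration(
            data, global_params=["FB_BPA"], individual_params=[],
            predictor=_toy_predictor(scale), use_likelihood=False)
        chains = cal.run_mcmc(chains=2, iterations=4000, seed=1)
        pooled = chains.pooled("FB_BPA")
        # uniform(0.023, 0.962) prior
        assert np.median(pooled) == pytest.approx(0.4925, abs=0.03)
        assert np.percentile(pooled, 2.5) == pytest.approx(0.0465, abs=0.04)

    def test_toy_recovery_and_convergence(self):
        scale = {"BPA": 1.0, "BPAG": 20.0, "BPAS": 3.0}
        data = _toy_dataset(n_ind=3, k_true=0.4, a_true=30.0, sigma=0.4, seed=2)
        results = []
        for seed in (1, 2):
            cal = HierarchicalCalibration(
                data, global_params=["K1_BPA_Urine"], individual_params=["MPY"],
                predictor=_toy_predictor(scale))
            chains = cal.run_mcmc(chains=2, iterations=3000, seed=seed)
            results.append(chains)
        for chains in results:
            summ = summarize(chains)
            k_med = summ.loc["K1_BPA_Urine", "median"] * 400.0
            assert k_med == pytest.approx(0.4, rel=0.15)
            for i in (1, 2, 3):
                assert summ.loc[f"MPY[{i}]", "median"] == pytest.approx(30.0, rel=0.15)
            assert (summ["rhat"].dropna() < 1.1).all()


class TestSummaries:
    def test_degenerate_chain(self):
        cs = ChainSet(samples={"x": np.full((2, 50), 3.14)}, acceptance={"x": 1.0},
                      burn_in=0, iterations=50, seed=0)
        s = summarize(cs).loc["x"]
        assert s["median"] == s["q2.5"] == s["q97.5"] == pytest.approx(3.14)

    def test_uniform_pseudo_chain_quantiles(self, rng):
        draws = rng.uniform(0, 1, size=(2, 50000))
        cs = ChainSet(samples={"u": draws}, acceptance={"u": 1.0},
                      burn_in=0, iterations=50000, seed=0)
        s = summarize(cs).loc["u"]
        assert s["median"] == pytest.approx(0.5, abs=0.01)
        assert s["q2.5"] == pytest.approx(0.025, abs=0.01)
        assert s["q97.5"] == pytest.approx(0.975, abs=0.01)
        assert s["q2.5"] <= s["median"] <= s["q97.5"]

    def test_empty_chains_error(self):
        with pytest.raises(DomainError):
            summarize(ChainSet(samples={}, acceptance={}, burn_in=0,
                               iterations=0, seed=0))

    def test_gelman_rubin_mixed_vs_separated(self, rng):
        mixed = rng.normal(0, 1, size=(4, 2000))
        assert gelman_rubin(mixed) < 1.05
        separated = np.vstack([rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])
        assert gelman_rubin(separated) > 1.5


class TestCsaf:
    def test_published_binding_fraction_ratio(self):
        assert csaf(median=0.119, q975=0.300) == pytest.approx(2.52, abs=0.005)

    def test_constant_sample(self):
        assert csaf(samples=np.full(100, 0.4)) == 1.0

    def test_lognormal_analytic_ratio(self, rng):
        x = rng.lognormal(0.0, 1.0, size=400000)
        assert csaf(samples=x) == pytest.approx(math.exp(1.959964), rel=0.02)

    def test_errors(self):
        with pytest.raises(DomainError):
            csaf(samples=np.array([]))
        with pytest.raises(DomainError):
            csaf(median=0.0, q975=1.0)


def test_prior_spec_logpdf_support():
    p = PriorSpec(name="x", dist="uniform", mean=None, sd=None, lower=1, upper=3)
    assert p.logpdf(2.0) == pytest.approx(-math.log(2.0))
    assert p.logpdf(0.5) == -math.inf
    with pytest.raises(DomainError):
        PriorSpec(name="y", dist="uniform", mean=None, sd=None, lower=3, upper=1)
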