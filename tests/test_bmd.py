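import numpy as np
import pytest

from bpaqivive.bmd import (BmdResult, DoseResponseSet, FamilyFit, _f_exp3,
                           _f_hill5, akaike_weights, apply_csaf, bmd_at_bmr,
                           bootstrap_bmdl, fit_model_family, hed_and_tdi)
from bpaqivive.errors import DomainError


def _gen_exp3(n=50, a=2.0, b=0.05, d=1.0, sigma=0.02, seed=0):
    rng = np.random.default_rng(seed)
    x = np.geomspace(0.1, 30, n)
    y = _f_exp3(x, (a, b, d)) * np.exp(rng.normal(0, sigma, n))
    return DoseResponseSet(dose=x, response=y), (a, b, d)


def _gen_hill(n_levels=6, reps=3, a=1.0, b=5.0, c=8.0, d=1.5, sigma=0.1, seed=1):
    rng = np.random.default_rng(seed)
    x = np.repeat(np.geomspace(0.3, 100, n_levels), reps)
    y = _f_hill5(x, (a, b, c, d)) * np.exp(rng.normal(0, sigma, len(x)))
    return DoseResponseSet(dose=x, response=y), (a, b, c, d)


class TestDataValidation:
    def test_needs_four_levels(self):
        with pytest.raises(DomainError):
            DoseResponseSet(dose=[0, 1, 1, 2], response=[1, 1, 1, 1])

    def test_positive_responses(self):
        with pytest.raises(DomainError):
            DoseResponseSet(dose=[0, 1, 2, 3], response=[1.0, -0.1, 1.0, 1.0])


class TestFits:
    def test_exp3_self_recovery(self):
        data, truth = _gen_exp3()
        fits = fit_model_family(data)
        th = fits["exp3"].theta
        for got, want in zip(th, truth):
            assert got == pytest.approx(want, rel=0.10)

    def test_flat_response_flagged(self):
        flat = DoseResponseSet(dose=[0, 1, 2, 3, 4], response=[2.0] * 5)
        assert fit_model_family(flat) == {}
        res = bootstrap_bmdl(flat, replicates=200, seed=0)
        assert isinstance(res, BmdResult)
        assert np.isnan(res.bmd) and res.flags

    def test_hill_data_prefers_hill_family(self):
        data, _ = _gen_hill(sigma=0.02)
        fits = fit_model_family(data)
        assert fits["hill5"].loglik >= fits["exp3"].loglik - 1e-6


class TestBmdAtBmr:
    def _fit(self, name, theta, aic):
        return FamilyFit(name=name, theta=np.asarray(theta, dtype=float),
                         loglik=-aic / 2, aic=aic, sigma_log=0.1,
                         n_params=len(theta), converged=True)

    def test_single_family_closed_form(self):
        # f = a (1 + x/(b+x)): 10% above background exactly at b*0.1/0.9
        fits = {"hill3": self._fit("hill3", (1.0, 7.0, 2.0), 10.0)}
        bmd, bmds, w, _ = bmd_at_bmr(fits, 0.10)
        assert bmd == pytest.approx(7.0 * 0.1 / 0.9, rel=1e-12)
        assert w["hill3"] == 1.0

    def test_equal_weight_families_average_arithmetically(self):
        fits = {"hill3": self._fit("hill3", (1.0, 7.0, 2.0), 10.0),
                "exp3": self._fit("exp3", (1.0, 0.1, 1.0), 10.0)}
        bmd, bmds, w, _ = bmd_at_bmr(fits, 0.10)
        assert w["hill3"] == pytest.approx(0.5)
        assert bmd == pytest.approx(0.5 * (bmds["hill3"] + bmds["exp3"]))

    def test_akaike_weights_sum_to_one(self):
        fits = {"a": self._fit("hill3", (1, 1, 2), 3.0),
                "b": self._fit("exp3", (1, 0.1, 1), 9.0)}
        w = akaike_weights(fits)
        assert sum(w.values()) == pytest.approx(1.0)
        assert w["a"] > w["b"]


class TestBootstrap:
    def test_interval_orders_and_near_zero_noise_collapse(self):
        data, _ = _gen_exp3(sigma=0.005, seed=3)
        res = bootstrap_bmdl(data, replicates=200, seed=0)
        assert res.bmdl10 <= res.bmd <= res.bmdu10
        assert (res.bmdu10 - res.bmdl10) / res.bmd < 0.15

    def test_seed_stability(self):
        data, _ = _gen_hill(sigma=0.08, seed=4)
        vals = [bootstrap_bmdl(data, replicates=1000, seed=s).bmdl10
                for s in (1, 2)]
        assert abs(vals[0] - vals[1]) / vals[1] < 0.05

    def test_scale_equivariance(self):
        data, _ = _gen_hill(sigma=0.05, seed=5)
        res1 = bootstrap_bmdl(data, replicates=200, seed=7)
        scaled = DoseResponseSet(dose=data.dose * 10.0, response=data.response)
        res2 = bootstrap_bmdl(scaled, replicates=200, seed=7)
        assert res2.bmd == pytest.approx(10.0 * res1.bmd, rel=0.02)
        assert res2.bmdl10 == pytest.approx(10.0 * res1.bmdl10, rel=0.15)

    def test_hill_design_bias(self):
        # three replicates at six concentrations, as in the published design
        biases = []
        for seed in (1, 2, 3, 4, 5):
            data, truth = _gen_hill(sigma=0.08, seed=seed)
            fits = fit_model_family(data)
            bmd, _, _, _ = bmd_at_bmr(fits, 0.10)
            a, b, c, d = truth
            true_bmd = b * (0.1 / (c - 1.1)) ** (1 / d)
            biases.append(bmd / true_bmd - 1.0)
        assert abs(np.mean(biases)) < 0.15


class TestAdjustments:
    @pytest.mark.parametrize("bmdl, csaf, expected", [
        (1300.0, 2.52, 516.0), (960.0, 2.52, 381.0)])
    def test_published_csaf_divisions(self, bmdl, csaf, expected):
        assert apply_csaf(bmdl, csaf) == pytest.approx(expected, abs=0.5)

    def test_identity_and_domain(self):
        assert apply_csaf(42.0, 1.0) == 42.0
        with pytest.raises(DomainError):
            apply_csaf(42.0, 0.5)

    def test_hed_and_tdi_published_values(self):
        hed, tdi = hed_and_tdi(8960.0, 0.068, 150.0)
        assert hed == pytest.approx(609.28, abs=0.01)
        assert tdi == pytest.approx(4.06, abs=0.01)
        assert hed_and_tdi(5.0, 1.0, 1.0) == (5.0, 5.0)
        with pytest.raises(DomainError):
            hed_and_tdi(-1.0, 0.068, 150.0)
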