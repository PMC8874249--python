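import numpy as np
import pytest

from bpaqivive import DoseEvent, default_parameters, simulate
from bpaqivive.errors import BracketingError, ConfigError, DomainError
from bpaqivive.pbk import SimOutput
from bpaqivive.reverse_dosimetry import (AbcConfig, DosePosterior, abc_mcmc,
                                         assemble_dose_response,
                                         make_pbk_summary_fn, match_summary,
                                         preprocess_response, rejection_phase,
                                         reverse_dosimetry)

# ---------------------------------------------------------------------------
# toy linear kinetic model: summary = dose * k, with k uniform on [1, 2]
# ---------------------------------------------------------------------------

TOY_RANGES = {"k": (1.0, 2.0)}


def toy_summary(overrides, dose):
    return overrides["k"] * dose


def toy_cfg(**kw):
    base = dict(target_tissue="CVli", phase1_n=4000, phase1_tol=0.075,
                phase2_chains=4, phase2_iters=2000, phase2_tol=0.05,
                sensitive_params=("k",), dose_range=(0.0001, 2.0), seed=5)
    base.update(kw)
    return AbcConfig(**base)


def grid_conditional_doses(target, tol, n=1000):
    """Brute-force conditional distribution of dose given |dk - t|/t <= tol."""
    d = np.linspace(1e-4, 2.0, n)
    k = np.linspace(1.0, 2.0, n)
    D, K = np.meshgrid(d, k)
    keep = np.abs(D * K - target) / target <= tol
    return D[keep]


class TestMatchSummary:
    def _const_sim(self, c):
        t = np.linspace(0, 24, 241)
        series = np.full_like(t, c)
        return SimOutput(time_grid=t, plasma_conc={}, tissue_conc={
            "CVli": series, "CVki": series}, compartment_amounts={})

    def test_zero_dose_zero_summary(self, central_params):
        sim = simulate(central_params, DoseEvent(0.0, 0.0, 0.1), duration=6.0)
        assert match_summary(sim, "CVli") == 0.0

    def test_constant_series_both_options(self):
        sim = self._const_sim(2.5)
        assert match_summary(sim, "CVli", "peak") == pytest.approx(2.5)
        assert match_summary(sim, "CVki", "auc_mean") == pytest.approx(2.5)

    def test_monotone_in_dose(self):
        fn = make_pbk_summary_fn(default_parameters(), "CVli",
                                 duration=8.0, solver_step=0.02)
        vals = [fn({}, d) for d in np.geomspace(0.1, 100, 8)]
        assert np.all(np.diff(vals) > 0)

    def test_unknown_method(self):
        with pytest.raises(ConfigError):
            match_summary(self._const_sim(1.0), "CVli", "median")


class TestRejectionPhase:
    def test_band_is_definitional(self, rng):
        retained, cov, acc, dr = rejection_phase(1.0, toy_cfg(), TOY_RANGES,
                                                 toy_summary, rng)
        s = retained["summary"].to_numpy()
        assert np.all(np.abs(s - 1.0) <= 0.075)

    def test_acceptance_matches_grid_area(self, rng):
        cfg = toy_cfg(phase1_n=20000)
        retained, _, acc, _ = rejection_phase(1.0, cfg, TOY_RANGES, toy_summary, rng)
        d = np.linspace(cfg.dose_range[0], cfg.dose_range[1], 1000)
        k = np.linspace(1, 2, 1000)
        D, K = np.meshgrid(d, k)
        area = np.mean(np.abs(D * K - 1.0) <= 0.075)
        assert acc == pytest.approx(area, rel=0.1)

    def test_zero_target_rejected(self):
        with pytest.raises(DomainError):
            rejection_phase(0.0, toy_cfg(), TOY_RANGES, toy_summary)

    def test_unreachable_target_brackets_error(self):
        with pytest.raises(BracketingError):
            rejection_phase(100.0, toy_cfg(), TOY_RANGES, toy_summary)


class TestAbcMcmc:
    def test_pooled_matches_grid_conditional(self):
        cfg = toy_cfg()
        post = reverse_dosimetry(1.0, cfg, TOY_RANGES, toy_summary)
        oracle = grid_conditional_doses(1.0, cfg.phase2_tol)
        # two-sample KS distance between pooled ABC doses and the oracle
        a = np.sort(post.samples)
        b = np.sort(oracle)
        grid = np.concatenate([a, b])
        fa = np.searchsorted(a, grid, side="right") / len(a)
        fb = np.searchsorted(b, grid, side="right") / len(b)
        assert np.max(np.abs(fa - fb)) < 0.05

    def test_phase1_and_phase2_means_agree(self, rng):
        cfg = toy_cfg()
        retained, cov, acc, dr = rejection_phase(1.0, cfg, TOY_RANGES,
                                                 toy_summary, rng)
        post = abc_mcmc(1.0, cfg, retained, cov, TOY_RANGES, toy_summary, dr, rng)
        # phase-2 accepts inside a narrower band; compare on phase-1 re-filtered
        s1 = retained[np.abs(retained["summary"] - 1.0) <= cfg.phase2_tol]["dose"]
        assert post.mean == pytest.approx(s1.mean(), rel=0.05)

    def test_chain_length_stability(self):
        m = []
        for iters in (2000, 4000):
            post = reverse_dosimetry(1.0, toy_cfg(phase2_iters=iters),
                                     TOY_RANGES, toy_summary)
            m.append(post.mean)
        assert abs(m[0] - m[1]) / m[1] < 0.05

    def test_quantiles_ordered_and_in_band(self):
        post = reverse_dosimetry(1.0, toy_cfg(), TOY_RANGES, toy_summary)
        assert post.q2_5 <= post.mean <= post.q97_5


class TestPreprocess:
    def test_log2_fold_induction(self):
        out = preprocess_response([2.711], "log2_fold_induction")
        assert out[0] == pytest.approx(6.55, abs=0.005)

    def test_percentage_clamp_and_shift(self):
        out = preprocess_response([-6.989, 26.914], "percentage_activity")
        assert out[0] == pytest.approx(1.00)
        assert out[1] == pytest.approx(27.914)

    def test_anomaly_exclusion_list(self):
        out = preprocess_response([2.33, 3.617], "percentage_activity",
                                  anomaly_indices=[0, 1])
        assert np.all(out == 1.0)

    def test_unknown_type(self):
        with pytest.raises(ConfigError):
            preprocess_response([1.0], "ec50")


class TestAssemble:
    def _post(self, t, m):
        return DosePosterior(target=t, samples=np.array([m]), mean=m,
                             q2_5=m * 0.5, q97_5=m * 1.5,
                             acceptance_phase1=0.1, acceptance_phase2=0.2)

    def test_pairing_and_sorting(self):
        posts = [self._post(0.2, 5.0), self._post(0.1, 2.0)]
        out = assemble_dose_response(posts, [8.0, 4.0])
        assert list(out["mean"]["target_mgL"]) == [0.1, 0.2]
        assert list(out["mean"]["response"]) == [4.0, 8.0]
        assert list(out["lower"]["dose"]) == [1.0, 2.5]

    def test_single_row(self):
        out = assemble_dose_response([self._post(0.1, 2.0)], [4.0])
        assert len(out["upper"]) == 1

    def test_shuffle_invariance(self):
        posts = [self._post(t, 10 * t) for t in (0.3, 0.1, 0.2)]
        resp = [3.0, 1.0, 2.0]
        a = assemble_dose_response(posts, resp)
        b = assemble_dose_response(posts[::-1], resp[::-1])
        assert a["mean"].equals(b["mean"])

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            assemble_dose_response([self._post(0.1, 1.0)], [1.0, 2.0])
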