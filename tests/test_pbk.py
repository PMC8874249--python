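import numpy as np
import pytest

from bpaqivive import DoseEvent, auc, default_parameters, scale_vmax, simulate
from bpaqivive.constants import ANALYTES
from bpaqivive.errors import DomainError
from bpaqivive.pbk import count_peaks


class TestScaleVmax:
    def test_unit_cancelling_identity(self):
        assert scale_vmax(1.0, 1.0, 1.0, 1e9 / 60) == pytest.approx(1.0)

    def test_whole_liver_rate(self):
        # published mean microsomal rate scaled to a 1.5 kg liver
        assert scale_vmax(4494, 34, 1500, 228.291) == pytest.approx(3139, rel=5e-3)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(DomainError):
            scale_vmax(0.0, 34, 1500, 228.291)


class TestSimulate:
    def test_zero_dose_gives_zero_series(self, central_params):
        out = simulate(central_params, DoseEvent(0.0, 0.0, 0.1), duration=6.0)
        for a in ANALYTES:
            assert np.all(out.plasma_conc[a] == 0.0)
        assert np.all(out.tissue_conc["CVli"] == 0.0)

    def test_mass_conservation_standard(self, standard_sim):
        assert standard_sim.mass_balance_rel_error[1:].max() < 1e-3

    def test_mass_conservation_random_sets(self, random_parameter_sets):
        for p in random_parameter_sets[:10]:
            out = simulate(p, DoseEvent(100.0, 0.0, 0.1))
            assert out.mass_balance_rel_error[1:].max() < 1e-3

    def test_series_nonnegative_and_cumulative_monotone(self, standard_sim):
        for k, v in standard_sim.compartment_amounts.items():
            assert np.all(v >= 0.0), k
            if k.endswith(("urine", "faeces")):
                assert np.all(np.diff(v) >= -1e-9), k

    def test_lymphatic_double_peak(self):
        p = default_parameters(Lymphlag=1.1, FracDOSELymph=0.04)
        out = simulate(p, DoseEvent(100.0, 0.0, 0.1))
        assert count_peaks(out.plasma_conc["BPA"]) >= 2
        p0 = default_parameters(FracDOSELymph=1e-9)
        out0 = simulate(p0, DoseEvent(100.0, 0.0, 0.1))
        assert count_peaks(out0.plasma_conc["BPA"]) == 1

    def test_binding_orders_unbound_peak(self):
        peaks = []
        for fb in (0.0, 0.99):
            p = default_parameters(FB_BPA=fb)
            out = simulate(p, DoseEvent(100.0, 0.0, 0.1), duration=8.0)
            unbound = out.compartment_amounts["BPA:blood_unbound"]
            peaks.append(unbound.max())
        assert peaks[0] > peaks[1]   # stronger binding -> lower unbound peak

    def test_no_metabolism_no_conjugates(self):
        p = default_parameters(Vmax_liv_BPA_in_vitro=0.0,
                               Vmax_liv_BPAS_in_vitro=0.0,
                               Vmax_gut_BPAG_in_vitro=0.0,
                               Vmax_gut_BPAS_in_vitro=0.0)
        out = simulate(p, DoseEvent(100.0, 0.0, 0.1), duration=12.0)
        assert np.all(out.plasma_conc["BPAG"] == 0.0)
        assert np.all(out.plasma_conc["BPAS"] == 0.0)

    def test_step_halving_convergence(self, central_params):
        a = []
        for h in (0.005, 0.0025):
            out = simulate(central_params, DoseEvent(100.0, 0.0, 0.1),
                           solver_step=h)
            a.append(auc(out.tissue_conc["CVli"], (0.0, 3.0), out.time_grid))
        assert abs(a[0] - a[1]) / a[1] < 1e-3

    def test_bile_lag_holds_recirculation_at_zero(self, standard_sim):
        t = standard_sim.time_grid
        recirc = standard_sim.compartment_amounts["BPA:gut_lumen_recirc"]
        assert np.all(recirc[t <= 4.0] == 0.0)
        assert recirc[t > 4.5].max() > 0.0

    def test_duration_must_cover_dose(self, central_params):
        with pytest.raises(DomainError):
            simulate(central_params, DoseEvent(100.0, 5.0, 1.0), duration=3.0)


class TestAuc:
    def test_constant_and_triangle(self):
        t = np.linspace(0, 3, 301)
        assert auc(np.ones_like(t), (0, 3), t) == pytest.approx(3.0)
        t2 = np.linspace(0, 2, 201)
        assert auc(t2, (0, 2), t2) == pytest.approx(2.0)

    def test_refinement_oracle(self, rng):
        t = np.linspace(0, 10, 101)
        y = np.interp(t, [0, 2, 5, 10], rng.uniform(0, 3, size=4))
        t_fine = np.linspace(0, 10, 1001)
        y_fine = np.interp(t_fine, t, y)
        a = auc(y, (1.0, 9.0), t)
        b = auc(y_fine, (1.0, 9.0), t_fine)
        assert a == pytest.approx(b, rel=1e-6)

    def test_empty_or_outside_window(self):
        t = np.linspace(0, 3, 31)
        with pytest.raises(DomainError):
            auc(np.ones_like(t), (2.0, 2.0), t)
        with pytest.raises(DomainError):
            auc(np.ones_like(t), (1.0, 5.0), t)


def test_dose_event_validation():
    with pytest.raises(DomainError):
        DoseEvent(-1.0)
    with pytest.raises(DomainError):
        DoseEvent(1.0, 0.0, 0.0)
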