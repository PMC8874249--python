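import numpy as np
import pandas as pd
import pytest

from bpaqivive import vcba
from bpaqivive.errors import ConfigError, DomainError
from bpaqivive.study import load_assay_table


@pytest.fixture(scope="module")
def chem():
    return vcba.load_bpa_physchem()


@pytest.fixture(scope="module")
def setup24():
    return vcba.default_setup("24-well", serum_fraction=0.05)


class TestUnitConversion:
    @pytest.mark.parametrize("um, expected", [
        (0.01, 2.28e-3), (70.0, 1.60e1), (2.0, 4.57e-1),
    ])
    def test_published_mgl_column(self, um, expected):
        got = vcba.um_to_mgl(um, 228.291)
        assert got == pytest.approx(expected, rel=5e-3)

    def test_zero_and_negative(self):
        assert vcba.um_to_mgl(0.0, 228.291) == 0.0
        with pytest.raises(DomainError):
            vcba.um_to_mgl(-1.0, 228.291)


class TestPartition:
    def test_fractions_sum_to_one(self, chem, setup24):
        r = vcba.partition(0.1, chem, setup24)
        s = (r.fraction_free_medium + r.fraction_serum_bound + r.fraction_plastic
             + r.fraction_headspace + r.fraction_cells)
        assert s == pytest.approx(1.0, abs=1e-9)
        assert r.free_concentration <= 0.1

    def test_bpa_free_fraction(self, chem, setup24):
        r = vcba.partition(vcba.um_to_mgl(0.01, chem.molecular_weight), chem, setup24)
        assert r.fraction_free_medium == pytest.approx(0.499, abs=0.005)

    def test_no_sinks_means_all_free(self, chem):
        inert = vcba.PhysChemParams(
            molecular_weight=chem.molecular_weight,
            molecular_diffusion_volume=chem.molecular_diffusion_volume,
            molar_volume=chem.molar_volume, henry_constant=0.0,
            degradation_rate_water=0.0, degradation_rate_air=0.0,
            log_kow=-30.0)
        s = vcba.AssaySetup("24-well", 1e-3, 2.4e-3, 4.5e-4, 0.0, 0.0, 24.0)
        r = vcba.partition(1.0, inert, s)
        assert r.fraction_free_medium == pytest.approx(1.0, abs=1e-6)

    def test_linearity_in_nominal(self, chem, setup24):
        r1 = vcba.partition(0.05, chem, setup24)
        r2 = vcba.partition(0.10, chem, setup24)
        assert r2.free_concentration == pytest.approx(2 * r1.free_concentration)

    def test_serum_monotonicity(self, chem):
        prev = None
        for sf in (0.0, 0.05, 0.10, 0.20):
            r = vcba.partition(1.0, chem, vcba.default_setup("24-well", sf))
            if prev is not None:
                assert r.fraction_free_medium < prev
            prev = r.fraction_free_medium

    def test_henry_monotonicity(self, chem, setup24):
        volatile = vcba.PhysChemParams(
            molecular_weight=chem.molecular_weight,
            molecular_diffusion_volume=chem.molecular_diffusion_volume,
            molar_volume=chem.molar_volume, henry_constant=100.0,
            degradation_rate_water=chem.degradation_rate_water,
            degradation_rate_air=chem.degradation_rate_air,
            log_kow=chem.log_kow)
        r0 = vcba.partition(1.0, chem, setup24)
        r1 = vcba.partition(1.0, volatile, setup24)
        assert r1.fraction_headspace > r0.fraction_headspace

    def test_ratio_concentration_independent(self, chem, setup24):
        ratios = []
        for um in (0.01, 0.03, 0.09, 0.3, 0.8, 2, 7, 20, 70):
            n = vcba.um_to_mgl(um, chem.molecular_weight)
            r = vcba.partition(n, chem, setup24)
            ratios.append(r.free_concentration / n)
        assert max(ratios) / min(ratios) < 1.01

    def test_unknown_plate_format(self):
        with pytest.raises(ConfigError):
            vcba.default_setup("6-well")


class TestTransformAssayTable:
    def test_pxr_table_ratios(self, chem, setup24):
        out = vcba.transform_assay_table(load_assay_table("ATG_PXR_TRANS_up"),
                                         chem, setup24)
        assert len(out) == 9
        assert out["free_nominal_ratio"].between(0.48, 0.50).all()
        row = out[np.isclose(out["conc_um"], 2.0)].iloc[0]
        assert row["free_mgL"] == pytest.approx(2.28e-1, rel=0.02)

    def test_empty_table(self, chem, setup24):
        out = vcba.transform_assay_table(
            pd.DataFrame(columns=["conc_um", "response"]), chem, setup24)
        assert out.empty

    def test_malformed_row_reports_index(self, chem, setup24):
        bad = pd.DataFrame({"conc_um": [1.0, "oops"], "response": [0.1, 0.2]})
        with pytest.raises(DomainError, match="row 1"):
            vcba.transform_assay_table(bad, chem, setup24)
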