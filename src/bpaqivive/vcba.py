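"""Free (bioavailable) in vitro concentration from nominal concentration.

An equilibrium mass-balance model of the assay well distributes the test
chemical among the aqueous medium, serum constituents, the well plastic, the
headspace and the cells.  The serum and plastic affinities are log-Kow
regressions; headspace follows Henry's law.  The shipped BPA configuration is
calibrated so the predicted free fraction in 5% serum / 24-well geometry
matches the measured 0.499 free/nominal ratio.  Optional first-order aqueous
degradation is applied over the exposure window (negligible for BPA).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import pandas as pd
import yaml

from .errors import ConfigError, DomainError

_DATA = importlib.resources.files("bpaqivive") / "data"
R_GAS = 8.314  # Pa m^3 / (mol K)


@dataclass(frozen=True)
class PhysChemParams:
    molecular_weight: float          # g/mol
    molecular_diffusion_volume: float
    molar_volume: float              # cm^3/mol
    henry_constant: float            # Pa m^3/mol
    degradation_rate_water: float    # 1/s
    degradation_rate_air: float      # 1/s
    log_kow: float

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise DomainError("molecular_weight must be > 0")
        if self.degradation_rate_water < 0 or self.degradation_rate_air < 0:
            raise DomainError("degradation rates must be >= 0")


@dataclass(frozen=True)
class AssaySetup:
    plate_format: str                # '24-well' or '384-well'
    medium_volume: float             # L
    headspace_volume: float          # L
    well_surface_area: float         # m^2 wetted plastic
    serum_fraction: float            # volume fraction of medium
    cell_count: float
    exposure_duration: float         # h

    def __post_init__(self):
        if self.medium_volume <= 0 or self.headspace_volume <= 0:
            raise DomainError("volumes must be > 0")
        if not (0.0 <= self.serum_fraction <= 1.0):
            raise DomainError("serum_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PartitionResult:
    fraction_free_medium: float
    fraction_serum_bound: float
    fraction_plastic: float
    fraction_headspace: float
    fraction_cells: float
    free_concentration: float        # mg/L


def load_config() -> dict:
    with (_DATA / "vcba_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_bpa_physchem() -> PhysChemParams:
    with (_DATA / "physchem_bpa.yaml").open() as fh:
        d = yaml.safe_load(fh)
    d.pop("name", None)
    return PhysChemParams(**d)


def default_setup(plate_format: str, serum_fraction: float = 0.05,
                  config: dict | None = None) -> AssaySetup:
    """Assay geometry defaults for a plate format from the packaged config."""
    cfg = config or load_config()
    try:
        plate = cfg["plates"][plate_format]
    except KeyError as exc:
        raise ConfigError(f"unparameterised plate format {plate_format!r}") from exc
    return AssaySetup(
        plate_format=plate_format,
        medium_volume=float(plate["medium_volume"]),
        headspace_volume=float(plate["headspace_volume"]),
        well_surface_area=float(plate["well_surface_area"]),
        serum_fraction=serum_fraction,
        cell_count=float(plate["cell_count"]),
        exposure_duration=float(plate["exposure_duration"]),
    )


def um_to_mgl(conc_um: float, molecular_weight: float) -> float:
    """Convert a concentration in uM to mg/L (conc * MW / 1000)."""
    if conc_um < 0:
        raise DomainError("concentration must be >= 0")
    return conc_um * molecular_weight / 1000.0


def partition(nominal_mgl: float, chem: PhysChemParams, setup: AssaySetup,
              config: dict | None = None) -> PartitionResult:
    """Equilibrium allocation of the chemical among the five well phases.

    Each sink's capacity is its partition coefficient times its volume (or
    area); the free aqueous fraction is the aqueous capacity over the total.
    ``free_concentration`` additionally carries the (optional) first-order
    aqueous degradation over the exposure window.
    """
    if nominal_mgl < 0:
        raise DomainError("nominal concentration must be >= 0")
    cfg = config or load_config()

    v_w = setup.medium_volume * (1.0 - setup.serum_fraction)
    v_s = setup.medium_volume * setup.serum_fraction
    k_serum = 10.0 ** (cfg["serum_kow_slope"] * chem.log_kow + cfg["serum_kow_intercept"])
    k_plastic = 10.0 ** (cfg["plastic_kow_slope"] * chem.log_kow + cfg["plastic_kow_intercept"])
    k_cell = 10.0 ** (cfg["cell_kow_slope"] * chem.log_kow + cfg["cell_kow_intercept"])
    v_cells = setup.cell_count * float(cfg["cell_volume_L"])
    k_aw = chem.henry_constant / (R_GAS * float(cfg["temperature_K"]))

    cap_w = v_w
    cap_s = k_serum * v_s
    cap_p = k_plastic * setup.well_surface_area
    cap_h = k_aw * setup.headspace_volume
    cap_c = k_cell * v_cells
    total = cap_w + cap_s + cap_p + cap_h + cap_c

    f_free = cap_w / total
    degr = 1.0
    if cfg.get("apply_degradation", True):
        # aqueous loss acts on the free fraction of the pool
        degr = math.exp(-chem.degradation_rate_water * 3600.0
                        * setup.exposure_duration * f_free)
    return PartitionResult(
        fraction_free_medium=f_free,
        fraction_serum_bound=cap_s / total,
        fraction_plastic=cap_p / total,
        fraction_headspace=cap_h / total,
        fraction_cells=cap_c / total,
        free_concentration=nominal_mgl * f_free * degr,
    )


def transform_assay_table(raw: pd.DataFrame, chem: PhysChemParams,
                          setup: AssaySetup, config: dict | None = None) -> pd.DataFrame:
    """Augment a dashboard-style table with nominal/free mg/L and their ratio.

    ``raw`` must carry ``conc_um`` (or ``log10_conc_um``) and ``response``
    columns; the output mirrors the published table layout.
    """
    cfg = config or load_config()
    out = raw.copy()
    if "conc_um" not in out.columns:
        if "log10_conc_um" not in out.columns:
            raise DomainError("assay table needs conc_um or log10_conc_um")
        out["conc_um"] = 10.0 ** out["log10_conc_um"].astype(float)
    nominal, free, ratio = [], [], []
    for i, row in out.reset_index(drop=True).iterrows():
        try:
            n_mgl = um_to_mgl(float(row["conc_um"]), chem.molecular_weight)
            res = partition(n_mgl, chem, setup, cfg)
        except (ValueError, TypeError) as exc:
            raise DomainError(f"malformed assay row {i}: {exc}") from exc
        nominal.append(n_mgl)
        free.append(res.free_concentration)
        ratio.append(res.free_concentration / n_mgl if n_mgl > 0 else float("nan"))
    out["nominal_mgL"] = nominal
    out["free_mgL"] = free
    out["free_nominal_ratio"] = ratio
    return out
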