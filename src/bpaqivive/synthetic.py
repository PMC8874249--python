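"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators: a virtual-population surrogate (independent truncated draws
from the prior families with flow renormalisation, standing in for a
covariance-aware population generator), virtual volunteer plasma time-courses
after a single oral dose (forward-simulated, with double-peak kinetics from
the lymphatic lag and truncated-Gaussian measurement error), and virtual
concentration-response assay tables from a Hill curve.  All generators are
pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError
from .params import ParameterSet, build_parameter_set, load_priors, prior_central_values
from .pbk import DoseEvent, simulate
from .vcba import um_to_mgl
from .constants import ANALYTES, MW_BPA

#: default sampling schedule (h): dense over the absorption phase, sparse later
DEFAULT_TIMES = tuple(np.round(np.concatenate([
    np.arange(0.25, 4.01, 0.25), [5, 6, 8, 10, 12, 16, 20, 24]]), 2))


def _draw_param(row, rng: np.random.Generator) -> float:
    if row["dist"] == "uniform":
        return float(rng.uniform(row["lower"], row["upper"]))
    if row["dist"] == "fixed":
        return float(row["mean"])
    # truncated normal by resampling (bounds are a few SD wide)
    for _ in range(1000):
        v = rng.normal(row["mean"], row["sd"])
        if row["lower"] <= v <= row["upper"]:
            break
    else:
        v = float(np.clip(v, row["lower"], row["upper"]))
    if row["dist"] == "lognormal":    # mean/sd/bounds specified on log scale
        return float(np.exp(v))
    return float(v)


def sample_parameter_set(rng: np.random.Generator,
                         priors: pd.DataFrame | None = None,
                         max_attempts: int = 200) -> ParameterSet:
    """One valid ParameterSet drawn from the prior families.

    Draws violating the volume mass-balance constraint are rejected and
    redrawn (independent truncated draws occasionally exceed unit body mass).
    """
    pri = priors if priors is not None else load_priors()
    for _ in range(max_attempts):
        d = {row["name"]: _draw_param(row, rng) for _, row in pri.iterrows()}
        try:
            return build_parameter_set(d)
        except DomainError:
            continue
    raise DomainError("could not draw a mass-balance-consistent parameter set")


def sample_population(n: int, seed: int = 0,
                      priors: pd.DataFrame | None = None) -> pd.DataFrame:
    """Virtual-population physiology table: n valid parameter draws (rows)."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [sample_parameter_set(rng, priors).to_dict() for _ in range(n)]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a virtual single-oral-dose biomonitoring study."""

    n_individuals: int = 14
    dose_per_bw: float = 100.0                    # ug/kg BW
    sampling_times: tuple = DEFAULT_TIMES         # h
    noise_sd: dict | None = None                  # per-analyte sigma, ug/L
    noise_rel: float = 0.10                       # fallback: fraction of peak
    seed: int = 0
    true_parameter_source: str = "table2_means"   # or 'sampled_from_priors'

    def __post_init__(self):
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise DomainError("sampling_times must be strictly increasing and >= 0")


@dataclass
class HbmDataset:
    """Long-format plasma biomonitoring records for a dosed cohort."""

    observations: pd.DataFrame   # individual, time_h, analyte, conc, unit
    body_weights: pd.Series      # kg, indexed by individual
    dose_per_bw: float           # ug/kg

    def for_individual(self, i: int) -> pd.DataFrame:
        return self.observations[self.observations["individual"] == i]

    def to_csv(self, path) -> None:
        df = self.observations.copy()
        df["bw_kg"] = df["individual"].map(self.body_weights)
        df["dose_ug_per_kg"] = self.dose_per_bw
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HbmDataset":
        df = pd.read_csv(path)
        bw = df.groupby("individual")["bw_kg"].first()
        dose = float(df["dose_ug_per_kg"].iloc[0])
        return cls(observations=df[["individual", "time_h", "analyte", "conc", "unit"]],
                   body_weights=bw, dose_per_bw=dose)


def generate_hbm(spec: SyntheticStudySpec,
                 individual_overrides: dict | None = None
                 ) -> tuple[HbmDataset, pd.DataFrame]:
    """Virtual volunteer study: simulate, sample, add truncated Gaussian noise.

    Returns the dataset and the generating ("true") parameter record, one row
    per individual, for parameter-recovery tests.  Noise is independent per
    observation with per-analyte sigma (defaulting to ``noise_rel`` times the
    population-median noiseless peak of that analyte) and truncation at zero.
    """
    rng = np.random.default_rng(spec.seed)
    central = prior_central_values()
    pri = load_priors()
    times = np.asarray(spec.sampling_times, dtype=float)
    duration = float(times[-1])

    records, truth_rows, sims = [], [], []
    for i in range(1, spec.n_individuals + 1):
        for attempt in range(5):
            try:
                if spec.true_parameter_source == "sampled_from_priors":
                    pset = sample_parameter_set(rng, pri)
                else:
                    d = dict(central)
                    # individual variation on the individual-scope parameters
                    for _, row in pri[pri["scope"] == "individual"].iterrows():
                        d[row["name"]] = _draw_param(row, rng)
                    pset = build_parameter_set(d)
                if individual_overrides:
                    pset = pset.replace(**individual_overrides)
                out = simulate(pset, DoseEvent(spec.dose_per_bw, 0.0, pset.DRINKTIME),
                               duration=duration)
                break
            except Exception:
                if attempt == 4:
                    raise
        sims.append((i, pset, out))
        truth_rows.append({"individual": i, **pset.to_dict()})

    sigma = dict(spec.noise_sd) if spec.noise_sd else {
        a: spec.noise_rel * float(np.median(
            [o.plasma_conc[a].max() for _, _, o in sims])) for a in ANALYTES}

    for i, pset, out in sims:
        for a in ANALYTES:
            pred = np.interp(times, out.time_grid, out.plasma_conc[a])
            noisy = pred + rng.normal(0.0, sigma[a], size=len(times)) \
                if sigma[a] > 0 else pred.copy()
            noisy = np.maximum(noisy, 0.0)
            for t, c in zip(times, noisy):
                records.append({"individual": i, "time_h": t, "analyte": a,
                                "conc": c, "unit": "ug/L"})
    obs = pd.DataFrame(records)
    bw = pd.Series({r["individual"]: r["BW"] for r in truth_rows}, name="bw_kg")
    truth = pd.DataFrame(truth_rows)
    truth.attrs["noise_sd"] = sigma
    return HbmDataset(observations=obs, body_weights=bw,
                      dose_per_bw=spec.dose_per_bw), truth


@dataclass(frozen=True)
class SyntheticAssaySpec:
    """Design of a virtual concentration-response assay."""

    ac50: float                          # uM
    top: float                           # response units (natural scale)
    hill_slope: float = 1.0
    concentrations: tuple = (0.01, 0.03, 0.09, 0.3, 0.8, 2.0, 7.0, 20.0, 70.0)
    replicates: int = 1
    noise_sd: float = 0.0
    response_type: str = "log2_fold_induction"
    baseline: float = 1.0                # natural-scale control response
    seed: int = 0

    def __post_init__(self):
        if self.ac50 <= 0:
            raise DomainError("ac50 must be > 0")
        if any(c <= 0 for c in self.concentrations):
            raise DomainError("concentrations must be > 0")


def hill_response(conc: np.ndarray, ac50: float, top: float, slope: float) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    return top * c**slope / (ac50**slope + c**slope)


def generate_assay(spec: SyntheticAssaySpec) -> pd.DataFrame:
    """Dashboard-style table from a Hill curve plus noise.

    For log2 fold induction the natural response is baseline + Hill activity
    and the stored value is log2 of it; percentage activity is stored as-is.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in spec.concentrations:
        for _ in range(spec.replicates):
            act = float(hill_response(np.array([c]), spec.ac50, spec.top,
                                      spec.hill_slope)[0])
            act += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            if spec.response_type == "log2_fold_induction":
                resp = float(np.log2(max(spec.baseline + act, 1e-9)))
            elif spec.response_type == "percentage_activity":
                resp = act
            else:
                raise DomainError(f"unknown response_type {spec.response_type!r}")
            rows.append({"conc_um": c, "log10_conc_um": float(np.log10(c)),
                         "response": resp, "response_type": spec.response_type})
    return pd.DataFrame(rows)
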