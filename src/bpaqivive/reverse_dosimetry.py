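"""Two-phase ABC reverse dosimetry.

Phase 1 (rejection): draw parameter-plus-dose sets from uniform ranges, keep
those whose predicted target-tissue concentration falls within a relative
tolerance band of the target free in vitro concentration, and estimate their
covariance.  Phase 2 (ABC MCMC): several chains of multivariate Gaussian
random-walk proposals scaled from that covariance, accepting moves that stay
inside the prior box and within a tighter band.  Pooled accepted doses form
the posterior for the oral dose (PORALDOSE) matching that target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BracketingError, ConfigError, DomainError, NumericalError
from .pbk import DoseEvent, SimOutput, auc, simulate

SummaryFn = Callable[[Mapping[str, float], float], float]
#    (sensitive-parameter values, dose ug/kg) -> scalar tissue summary (mg/L)


@dataclass(frozen=True)
class AbcConfig:
    target_tissue: str = "CVli"          # or 'CVki'
    phase1_n: int = 5000
    phase1_tol: float = 0.075
    phase2_chains: int = 4
    phase2_iters: int = 50000
    phase2_tol: float = 0.05
    sensitive_params: tuple = ()
    dose_range: tuple | None = None      # (lower, upper) ug/kg BW/day
    summary: str = "peak"                # or 'auc_mean'
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.phase2_tol < self.phase1_tol < 1.0):
            raise DomainError("need 0 < phase2_tol < phase1_tol < 1")
        if self.target_tissue not in ("CVli", "CVki"):
            raise ConfigError(f"unknown target tissue {self.target_tissue!r}")


@dataclass
class DosePosterior:
    target: float                        # free in vitro concentration, mg/L
    samples: np.ndarray                  # pooled accepted doses, ug/kg BW/day
    mean: float
    q2_5: float
    q97_5: float
    acceptance_phase1: float
    acceptance_phase2: float
    meta: dict = field(default_factory=dict)


def match_summary(sim: SimOutput, target_tissue: str, method: str = "peak",
                  window: tuple[float, float] = (0.0, 3.0)) -> float:
    """Scalar target-tissue summary compared against the in vitro target.

    ``peak``: maximum tissue concentration over the simulation; ``auc_mean``:
    time-average of the concentration over ``window``.
    """
    series = sim.tissue_conc[target_tissue]
    if method == "peak":
        return float(series.max())
    if method == "auc_mean":
        return auc(series, window, sim.time_grid) / (window[1] - window[0])
    raise ConfigError(f"unknown summary method {method!r}")


def make_pbk_summary_fn(base_params, target_tissue: str = "CVli",
                        method: str = "peak", duration: float = 24.0,
                        solver_step: float = 0.01, step: float = 0.02) -> SummaryFn:
    """Summary function driven by the kinetic model.

    ``base_params`` is a ParameterSet (or mapping); sensitive parameters are
    overridden per call, everything else stays fixed.
    """
    base = dict(base_params)

    def fn(overrides: Mapping[str, float], dose: float) -> float:
        from .params import build_parameter_set
        d = dict(base)
        d.update(overrides)
        pset = build_parameter_set(d)
        sim = simulate(pset, DoseEvent(dose, 0.0, pset.DRINKTIME),
                       duration=duration, step=step, solver_step=solver_step)
        s = match_summary(sim, target_tissue, method)
        if dose > 0 and s <= 0:
            raise NumericalError("zero tissue response to a non-zero dose")
        return s

    return fn


def bracket_dose_range(summary_fn: SummaryFn, target: float,
                       central: Mapping[str, float],
                       lo: float = 1e-4, hi: float = 1e6,
                       n_scan: int = 20) -> tuple[float, float]:
    """Log-spaced dose scan at central parameters to bracket the target."""
    doses = np.geomspace(lo, hi, n_scan)
    vals = np.array([summary_fn(central, d) for d in doses])
    ok = np.isfinite(vals) & (vals > 0)
    if not ok.any() or target > vals[ok].max() or target < vals[ok].min():
        raise BracketingError(
            f"target {target} outside achievable summary range "
            f"[{vals[ok].min():.3g}, {vals[ok].max():.3g}]; widen the dose scan")
    # widest pair of doses whose summaries straddle the target, padded 10x
    below = doses[ok][vals[ok] <= target]
    above = doses[ok][vals[ok] >= target]
    return float(below.max() / 10.0), float(above.min() * 10.0)


def rejection_phase(target: float, cfg: AbcConfig,
                    ranges: Mapping[str, tuple[float, float]],
                    summary_fn: SummaryFn,
                    rng: np.random.Generator | None = None):
    """Phase 1: uniform draws, keep sets within the tolerance band.

    Returns (retained DataFrame incl. dose and summary, covariance matrix,
    acceptance fraction).
    """
    if target <= 0:
        raise DomainError("target concentration must be > 0 (relative tolerance)")
    rng = rng or np.random.default_rng(cfg.seed)
    names = list(cfg.sensitive_params)
    if cfg.dose_range is None:
        central = {n: 0.5 * (ranges[n][0] + ranges[n][1]) for n in names}
        dose_range = bracket_dose_range(summary_fn, target, central)
    else:
        dose_range = cfg.dose_range
    lo = np.array([ranges[n][0] for n in names] + [dose_range[0]])
    hi = np.array([ranges[n][1] for n in names] + [dose_range[1]])
    X = rng.uniform(lo, hi, size=(cfg.phase1_n, len(lo)))
    kept_rows = []
    for row in X:
        overrides = {n: v for n, v in zip(names, row[:-1])}
        try:
            s = summary_fn(overrides, row[-1])
        except Exception:
            continue
        if abs(s - target) / target <= cfg.phase1_tol:
            kept_rows.append(np.append(row, s))
    if not kept_rows:
        raise BracketingError(
            "rejection phase retained nothing; widen dose_range or tolerances")
    kept = np.array(kept_rows)
    retained = pd.DataFrame(kept, columns=names + ["dose", "summary"])
    cov = np.cov(kept[:, :-1].T) if len(kept) > 1 else np.eye(len(lo))
    return retained, cov, len(kept) / cfg.phase1_n, dose_range


def abc_mcmc(target: float, cfg: AbcConfig, retained: pd.DataFrame,
             cov: np.ndarray, ranges: Mapping[str, tuple[float, float]],
             summary_fn: SummaryFn, dose_range: tuple[float, float],
             rng: np.random.Generator | None = None) -> DosePosterior:
    """Phase 2: ABC MCMC chains from random retained starting points."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    names = list(cfg.sensitive_params)
    lo = np.array([ranges[n][0] for n in names] + [dose_range[0]])
    hi = np.array([ranges[n][1] for n in names] + [dose_range[1]])
    d = len(lo)
    scale = (2.38 / np.sqrt(d)) ** 2
    cov = np.atleast_2d(cov) * scale
    # keep the proposal usable when phase 1 retained too few points for a
    # full-rank covariance: regularise toward its diagonal, then fall back
    diag = np.maximum(np.diag(cov), ((hi - lo) * 0.01) ** 2)
    try:
        chol = np.linalg.cholesky(cov + 1e-6 * np.diag(diag))
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(diag))

    pooled = []
    acc = 0
    tot = 0
    for c in range(cfg.phase2_chains):
        x = retained.iloc[rng.integers(len(retained))][names + ["dose"]].to_numpy(dtype=float)
        shrink = 1.0
        acc_c = 0
        for it in range(cfg.phase2_iters):
            tot += 1
            prop = x + shrink * (chol @ rng.standard_normal(d))
            if np.any(prop < lo) or np.any(prop > hi):
                pooled.append(x[-1])
                continue
            try:
                s = summary_fn({n: v for n, v in zip(names, prop[:-1])}, prop[-1])
            except Exception:
                pooled.append(x[-1])
                continue
            if abs(s - target) / target <= cfg.phase2_tol:
                x = prop
                acc += 1
                acc_c += 1
            pooled.append(x[-1])
            # auto-shrink if the chain is stuck
            if (it + 1) % 200 == 0 and acc_c / (it + 1) < 0.01:
                shrink *= 0.5
    doses = np.asarray(pooled)
    return DosePosterior(
        target=target, samples=doses, mean=float(doses.mean()),
        q2_5=float(np.percentile(doses, 2.5)),
        q97_5=float(np.percentile(doses, 97.5)),
        acceptance_phase1=float("nan"), acceptance_phase2=acc / max(tot, 1),
        meta={"summary": cfg.summary, "target_tissue": cfg.target_tissue,
              "dose_range": tuple(dose_range)})


def reverse_dosimetry(target: float, cfg: AbcConfig,
                      ranges: Mapping[str, tuple[float, float]],
                      summary_fn: SummaryFn) -> DosePosterior:
    """Run both phases for one target free concentration."""
    rng = np.random.default_rng(cfg.seed)
    retained, cov, acc1, dose_range = rejection_phase(target, cfg, ranges,
                                                      summary_fn, rng)
    post = abc_mcmc(target, cfg, retained, cov, ranges, summary_fn, dose_range, rng)
    post.acceptance_phase1 = acc1
    return post


def preprocess_response(values: Sequence[float], response_type: str,
                        anomaly_indices: Sequence[int] = ()) -> np.ndarray:
    """Convert raw dashboard responses to the natural scale used for BMD.

    log2 fold induction -> 2**value.  Percentage activity: negative values
    and listed anomalies (per-assay exclusion list) are set to zero, then one
    is added throughout (zero-safe for the lognormal response assumption).
    """
    v = np.asarray(values, dtype=float)
    if response_type == "log2_fold_induction":
        return 2.0 ** v
    if response_type == "percentage_activity":
        out = v.copy()
        out[out < 0] = 0.0
        idx = np.asarray(list(anomaly_indices), dtype=int)
        if idx.size:
            out[idx] = 0.0
        return out + 1.0
    raise ConfigError(f"unknown response_type {response_type!r}")


def assemble_dose_response(posteriors: Sequence[DosePosterior],
                           responses: Sequence[float]) -> dict[str, pd.DataFrame]:
    """Pair dose posterior summaries with natural-scale responses.

    Returns three (dose, response) tables keyed 'mean', 'lower', 'upper',
    sorted by target concentration.
    """
    if len(posteriors) != len(responses):
        raise DomainError("posteriors and responses must align one-to-one")
    order = np.argsort([p.target for p in posteriors], kind="stable")
    out = {}
    for key, attr in (("mean", "mean"), ("lower", "q2_5"), ("upper", "q97_5")):
        out[key] = pd.DataFrame({
            "target_mgL": [posteriors[i].target for i in order],
            "dose": [getattr(posteriors[i], attr) for i in order],
            "response": [responses[i] for i in order],
        })
    return out
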