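"""Model-averaged benchmark-dose estimation for continuous dose-response data.

Four nested continuous families (exponential and Hill, each with and without
a free shape exponent) are fitted by maximum likelihood under a lognormal
response distribution.  The benchmark dose at a 10% benchmark response (BMR)
is the dose producing a 10% change in the median response relative to the
modelled background; family BMDs are combined with Akaike weights and the
confidence limits BMDL/BMDU come from a parametric bootstrap under the
averaged (mixture) fit: per replicate a family is drawn proportional to its
weight, data are regenerated from its fit, all families are refitted and the
averaged BMD recomputed; BMDL10/BMDU10 are the 5% and 95% quantiles (the
one-sided 95% limits of the 90% interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, NumericalError

_D_BOUNDS = (0.25, 6.0)
_C_MAX = 1e4


@dataclass(frozen=True)
class DoseResponseSet:
    """Continuous dose-response observations (lognormal response assumption)."""

    dose: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.dose, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "response", r)
        if np.any(d < 0):
            raise DomainError("doses must be >= 0")
        if len(np.unique(d)) < 4:
            raise DomainError("need at least 4 distinct dose levels")
        if np.any(r <= 0):
            raise DomainError("responses must be > 0 (preprocess first)")


# ---------------------------------------------------------------------------
# model families: f(x; theta) for an increasing response
# ---------------------------------------------------------------------------

def _f_exp3(x, th):      # a * exp(b * x^d)
    a, b, d = th
    return a * np.exp(b * np.power(x, d))


def _f_exp5(x, th):      # a * (c - (c-1) exp(-b x^d))
    a, b, c, d = th
    return a * (c - (c - 1.0) * np.exp(-b * np.power(x, d)))


def _f_hill3(x, th):     # a * (1 + (c-1) x / (b + x))
    a, b, c = th
    return a * (1.0 + (c - 1.0) * x / (b + x))


def _f_hill5(x, th):     # a * (1 + (c-1) x^d / (b^d + x^d))
    a, b, c, d = th
    xd = np.power(x, d)
    return a * (1.0 + (c - 1.0) * xd / (b ** d + xd))


def _bmd_exp3(th, ratio):
    a, b, d = th
    return (math.log(ratio) / b) ** (1.0 / d) if b > 0 else math.nan


def _bmd_exp5(th, ratio):
    a, b, c, d = th
    if c <= ratio:
        return math.nan
    return (-math.log((c - ratio) / (c - 1.0)) / b) ** (1.0 / d)


def _bmd_hill3(th, ratio):
    a, b, c = th
    if c <= ratio:
        return math.nan
    return b * (ratio - 1.0) / (c - ratio)


def _bmd_hill5(th, ratio):
    a, b, c, d = th
    if c <= ratio:
        return math.nan
    return b * ((ratio - 1.0) / (c - ratio)) ** (1.0 / d)


_FAMILIES = {
    "exp3": (_f_exp3, _bmd_exp3, 3),
    "exp5": (_f_exp5, _bmd_exp5, 4),
    "hill3": (_f_hill3, _bmd_hill3, 3),
    "hill5": (_f_hill5, _bmd_hill5, 4),
}


@dataclass
class FamilyFit:
    name: str
    theta: np.ndarray
    loglik: float
    aic: float
    sigma_log: float
    n_params: int
    converged: bool


@dataclass
class BmdResult:
    bmd: float
    bmdl10: float
    bmdu10: float
    bmr: float
    weights: dict[str, float]
    fits: dict[str, FamilyFit]
    replicates: int
    seed: int | None
    flags: list[str] = field(default_factory=list)


def _starts(name, x, y):
    lo = np.median(y[x <= np.quantile(x, 0.25)])
    a0 = max(lo, 1e-6)
    c0 = max(y.max() / a0, 1.2)
    xm = np.median(x[x > 0]) if np.any(x > 0) else 1.0
    xmax = x.max() if x.max() > 0 else 1.0
    if name == "exp3":
        b0 = max(math.log(max(y.max(), 1.01 * a0) / a0) / xmax, 1e-8)
        return [(a0, b0, 1.0), (a0, b0 / 10, 2.0), (a0 * 1.2, b0 * 3, 0.5)]
    if name == "exp5":
        return [(a0, 1.0 / xm, c0, 1.0), (a0, 0.1 / xm, c0, 2.0),
                (a0, 3.0 / xm, 2 * c0, 0.5)]
    if name == "hill3":
        return [(a0, xm, c0), (a0, xmax / 3, c0 * 1.5), (a0 * 1.2, xm / 3, c0)]
    return [(a0, xm, c0, 1.0), (a0, xmax / 3, c0, 2.5), (a0, xm / 3, c0 * 1.5, 0.6)]


def _bounds(name, x, y):
    xmax = max(x.max(), 1e-12)
    amin, amax = y.min() / 100, y.max() * 100
    if name == "exp3":
        return ([amin, 1e-12, _D_BOUNDS[0]], [amax, 1e4 / xmax, _D_BOUNDS[1]])
    if name == "exp5":
        return ([amin, 1e-9 / xmax, 1.0 + 1e-9, _D_BOUNDS[0]],
                [amax, 1e5 / xmax, _C_MAX, _D_BOUNDS[1]])
    if name == "hill3":
        return ([amin, xmax * 1e-6, 1.0 + 1e-9], [amax, xmax * 1e3, _C_MAX])
    return ([amin, xmax * 1e-6, 1.0 + 1e-9, _D_BOUNDS[0]],
            [amax, xmax * 1e3, _C_MAX, _D_BOUNDS[1]])


def fit_model_family(data: DoseResponseSet,
                     init: dict | None = None) -> dict[str, FamilyFit]:
    """ML fits of the four families on the log-response scale.

    ``init`` optionally provides a warm-start parameter vector per family
    (used by the bootstrap, which refits near the original optimum).
    """
    x, y = data.dose, data.response
    logy = np.log(y)
    n = len(y)
    if np.allclose(y, y[0]):
        return {}   # flat response: BMD undefined, caller flags it
    fits = {}
    for name, (f, _, k) in _FAMILIES.items():
        best = None
        lo, hi = _bounds(name, x, y)
        if init is not None and name in init:
            starts = [np.asarray(init[name], dtype=float), _starts(name, x, y)[0]]
        else:
            starts = _starts(name, x, y)
        for th0 in starts:
            th0 = np.clip(th0, lo, hi)
            try:
                res = least_squares(
                    lambda th: np.log(np.maximum(f(x, th), 1e-300)) - logy,
                    th0, bounds=(lo, hi), max_nfev=400)
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            continue
        sse = 2 * best.cost
        sig2 = max(sse / n, 1e-300)
        # lognormal log-likelihood up to the model-independent -sum(log y)
        ll = -0.5 * n * (math.log(2 * math.pi * sig2) + 1.0)
        fits[name] = FamilyFit(name=name, theta=best.x, loglik=ll,
                               aic=2 * (k + 1) - 2 * ll,
                               sigma_log=math.sqrt(sig2), n_params=k,
                               converged=True)
    return fits


def akaike_weights(fits: dict[str, FamilyFit]) -> dict[str, float]:
    if not fits:
        return {}
    aics = np.array([f.aic for f in fits.values()])
    d = aics - aics.min()
    w = np.exp(-0.5 * d)
    w /= w.sum()
    return {name: float(wi) for name, wi in zip(fits, w)}


def bmd_at_bmr(fits: dict[str, FamilyFit], bmr: float = 0.10):
    """Akaike-weighted average of the family BMDs at the given BMR.

    Returns (averaged BMD, per-family BMDs, weights over families with a
    defined BMD, flags).
    """
    if not fits:
        raise DomainError("no converged family fits")
    ratio = 1.0 + bmr
    bmds = {}
    for name, fit in fits.items():
        b = _FAMILIES[name][1](fit.theta, ratio)
        if math.isfinite(b) and b > 0:
            bmds[name] = b
    if not bmds:
        raise DomainError("BMD undefined for every family (response below BMR)")
    w = akaike_weights({n: fits[n] for n in bmds})
    avg = sum(w[n] * bmds[n] for n in bmds)
    flags = []
    return avg, bmds, w, flags


def bootstrap_bmdl(data: DoseResponseSet, bmr: float = 0.10,
                   replicates: int = 1000, seed: int = 0) -> BmdResult:
    """Parametric bootstrap under the averaged fit; BMDL10/BMDU10 quantiles."""
    if replicates < 200:
        raise DomainError("need >= 200 bootstrap replicates")
    fits = fit_model_family(data)
    flags = []
    if not fits:
        return BmdResult(bmd=math.nan, bmdl10=math.nan, bmdu10=math.nan,
                         bmr=bmr, weights={}, fits={}, replicates=0, seed=seed,
                         flags=["flat-response: BMD undefined"])
    bmd, bmds, weights, f0 = bmd_at_bmr(fits, bmr)
    flags.extend(f0)
    if not (data.dose.min() <= bmd <= data.dose.max()):
        flags.append("extrapolation: averaged BMD outside the dose range")

    rng = np.random.default_rng(seed)
    names = list(weights)
    probs = np.array([weights[n] for n in names])
    x = data.dose
    boots = []
    failures = 0
    for _ in range(replicates):
        m = names[rng.choice(len(names), p=probs)]
        fit = fits[m]
        mu = np.log(np.maximum(_FAMILIES[m][0](x, fit.theta), 1e-300))
        ystar = np.exp(mu + rng.normal(0.0, fit.sigma_log, size=len(x)))
        try:
            fstar = fit_model_family(DoseResponseSet(dose=x, response=ystar),
                                     init={n_: f_.theta for n_, f_ in fits.items()})
            b, _, _, _ = bmd_at_bmr(fstar, bmr)
            boots.append(b)
        except Exception:
            failures += 1
    if failures > replicates / 2:
        raise NumericalError(f"bootstrap unstable: {failures}/{replicates} failures")
    boots = np.asarray(boots)
    bmdl, bmdu = np.percentile(boots, [5, 95])
    return BmdResult(bmd=float(bmd), bmdl10=float(min(bmdl, bmd)),
                     bmdu10=float(max(bmdu, bmd)), bmr=bmr, weights=weights,
                     fits=fits, replicates=len(boots), seed=seed, flags=flags)


def apply_csaf(bmdl: float, csaf: float) -> float:
    """Adjust a BMDL by a chemical-specific adjustment factor (division)."""
    if csaf < 1:
        raise DomainError("CSAF must be >= 1")
    return bmdl / csaf


def hed_and_tdi(bmdl: float, hedf: float, uf: float) -> tuple[float, float]:
    """Human equivalent dose (bmdl * hedf) and tolerable daily intake (hed / uf)."""
    if bmdl <= 0 or hedf <= 0 or uf <= 0:
        raise DomainError("all inputs must be > 0")
    hed = bmdl * hedf
    return hed, hed / uf
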