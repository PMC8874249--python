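"""Whole-body kinetic model parameter vector and its mass-balance contract.

The model is parameterised by ~78 named positive reals: physiological volumes
and flows (fractions of body weight / cardiac output), oral-uptake fractions,
plasma-binding fractions, microsomal protein yields, first-order rate
constants, in vitro metabolic constants and tissue:blood partition
coefficients.  ``build_parameter_set`` enforces the logical constraints:
fractional blood flows are renormalised to sum to one (preserving relative
magnitudes) and fractional tissue volumes must leave positive residual mass
for the carcass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, SchemaError

_DATA = importlib.resources.files("bpaqivive") / "data"

#: names of fractional blood flows (fractions of cardiac output)
FLOW_NAMES = ("QhepartC", "QstC", "QguC", "QkiC", "QfaC", "QspdC", "QrpdC")
#: names of fractional tissue volumes (fractions of body weight)
VOLUME_NAMES = (
    "VliC", "VstC", "VguC", "VkiC", "VlymphC", "VfaC", "VspdC", "VrpdC", "VBldC",
)
#: parameters constrained to [0, 1]
FRACTION_NAMES = ("FracDOSEHep", "FracDOSELymph", "FB_BPA", "FB_BPAG", "FB_BPAS")


def load_priors() -> pd.DataFrame:
    """Packaged default prior table (name, unit, mean, sd, lower, upper, dist, scope)."""
    with (_DATA / "priors_table2.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("name", drop=False)


def load_posterior_global() -> pd.DataFrame:
    """Packaged printed posterior summary for global parameters."""
    with (_DATA / "posterior_global.csv").open() as fh:
        return pd.read_csv(fh).set_index("name", drop=False)


def load_posterior_individual() -> pd.DataFrame:
    """Packaged printed posterior summaries for the 11 individual-specific parameters."""
    with (_DATA / "posterior_individual.csv").open() as fh:
        return pd.read_csv(fh)


def load_volunteer_bodyweights() -> pd.Series:
    with (_DATA / "volunteers.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("individual")["bw_kg"]


_PRIORS = load_priors()
PARAM_NAMES: tuple[str, ...] = tuple(_PRIORS["name"])
_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}


def prior_central_values() -> dict[str, float]:
    """Central value per parameter: the mean for normal/fixed families, the
    range midpoint for uniforms, exp(mean) for log-scale families."""
    out: dict[str, float] = {}
    for _, row in _PRIORS.iterrows():
        if row["dist"] == "uniform":
            out[row["name"]] = 0.5 * (row["lower"] + row["upper"])
        elif row["dist"] == "lognormal":
            out[row["name"]] = float(np.exp(row["mean"]))
        else:
            out[row["name"]] = float(row["mean"])
    return out


@dataclass(frozen=True)
class ParameterSet(Mapping):
    """Validated, flow-renormalised parameter vector (Mapping of name -> value)."""

    values: np.ndarray  # aligned with PARAM_NAMES

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[_INDEX[name]])
        except KeyError as exc:
            raise SchemaError(f"unknown parameter {name!r}") from exc

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return len(PARAM_NAMES)

    def __getattr__(self, name: str) -> float:
        if name in _INDEX:
            return float(self.values[_INDEX[name]])
        raise AttributeError(name)

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a new, re-validated set with the given parameters replaced."""
        d = dict(self)
        d.update(updates)
        return build_parameter_set(d)

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    # -- flat structured-config round trip (exact abbreviation keys) --------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return build_parameter_set(yaml.safe_load(fh))


def build_parameter_set(raw: Mapping[str, float],
                        renormalise_volumes: bool = False) -> ParameterSet:
    """Validate a raw draw and apply the mass-balance re-parameterisations.

    Fractional blood flows are rescaled by 1/sum so they total exactly one
    while preserving relative magnitudes; fractional tissue volumes must sum
    to < 1 (positive carcass residual).  With ``renormalise_volumes=True`` a
    draw whose volumes exceed the budget is instead rescaled (preserving
    relative magnitudes) to leave a 1% carcass residual — used when sweeping
    rectangular parameter ranges whose corners can overrun the budget.

    Raises
    ------
    SchemaError
        if any named parameter is missing.
    DomainError
        if a draw is non-positive, a fraction leaves [0, 1], the dose
        fractions exceed one in total, or the volumes leave no carcass mass.
    """
    missing = [n for n in PARAM_NAMES if n not in raw]
    if missing:
        raise SchemaError(f"missing parameter(s): {', '.join(missing)}")
    vec = np.array([float(raw[n]) for n in PARAM_NAMES], dtype=float)
    # zero is admissible only where it is a meaningful boundary: binding/dose
    # fractions and maximum metabolic rates (metabolism switched off)
    zero_ok = set(FRACTION_NAMES) | {n for n in PARAM_NAMES if n.startswith("Vmax_")}
    bad = [n for n, v in zip(PARAM_NAMES, vec)
           if not np.isfinite(v) or v < 0.0 or (v == 0.0 and n not in zero_ok)]
    if bad:
        raise DomainError(f"non-positive or non-finite parameter(s): {', '.join(bad)}")
    for n in FRACTION_NAMES:
        v = vec[_INDEX[n]]
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{n}={v} outside [0, 1]")
    if vec[_INDEX["FracDOSEHep"]] + vec[_INDEX["FracDOSELymph"]] > 1.0:
        raise DomainError("FracDOSEHep + FracDOSELymph exceeds 1")

    vol_idx = [_INDEX[n] for n in VOLUME_NAMES]
    vol_sum = vec[vol_idx].sum()
    if vol_sum >= 1.0:
        if renormalise_volumes:
            vec[vol_idx] *= 0.99 / vol_sum
        else:
            raise DomainError(
                f"fractional tissue volumes sum to {vol_sum:.4f} >= 1 "
                "(no carcass residual)"
            )
    flow_idx = [_INDEX[n] for n in FLOW_NAMES]
    flow_sum = vec[flow_idx].sum()
    vec[flow_idx] /= flow_sum
    return ParameterSet(values=vec)


def default_parameters(**overrides: float) -> ParameterSet:
    """ParameterSet at the prior central values (optionally overridden)."""
    d = prior_central_values()
    d.update(overrides)
    return build_parameter_set(d)
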