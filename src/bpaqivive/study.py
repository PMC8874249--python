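"""Study-specific wiring: published assay fixtures, posterior-refined
parameter ranges, sensitivity rankings and the model outputs they feed.

This module connects the generic machinery (kinetics, GSA, ABC, BMD) to the
BPA study's printed inputs: the four assay concentration-response tables, the
posterior summary tables used as refined parameter ranges, and the top-ranked
parameter lists per output.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .errors import ConfigError
from .params import (default_parameters, load_posterior_global,
                     load_posterior_individual, load_priors)
from .pbk import DoseEvent, auc, simulate

_DATA = importlib.resources.files("bpaqivive") / "data"

ASSAYS = ("ATG_ERE_CIS_up", "ATG_PXR_TRANS_up", "OT_ER_ERaERb_0480",
          "OT_ER_ERaERa_1440")
ASSAY_PLATE = {"ATG_ERE_CIS_up": "24-well", "ATG_PXR_TRANS_up": "24-well",
               "OT_ER_ERaERb_0480": "384-well", "OT_ER_ERaERa_1440": "384-well"}
ASSAY_TISSUE = {"ATG_ERE_CIS_up": "CVli", "ATG_PXR_TRANS_up": "CVli",
                "OT_ER_ERaERb_0480": "CVki", "OT_ER_ERaERa_1440": "CVki"}
AC50_UM = {"ATG_ERE_CIS_up": 0.1, "ATG_PXR_TRANS_up": 0.72,
           "OT_ER_ERaERb_0480": 0.32, "OT_ER_ERaERa_1440": 4.31}

#: eFAST-ranked most influential parameters per output (screening result)
TOP10 = {
    "CVli": ["KM_liv_BPA_in_vitro", "MPY", "KEMAX", "Vmax_liv_BPA_in_vitro",
             "VliC", "BELLYPERM", "FracDOSEHep", "Pgub", "VspdC", "Pstb"],
    "CVki": ["KM_liv_BPA_in_vitro", "K1_BPA_REMOVED_PLASMA",
             "Vmax_liv_BPA_in_vitro", "MPY", "Pkib", "VliC", "VspdC",
             "FracDOSEHep", "Pstb", "QCC"],
}


def load_assay_table(assay: str) -> pd.DataFrame:
    """Packaged dashboard-style table for one assay (raw response columns)."""
    if assay not in ASSAYS:
        raise ConfigError(f"unknown assay {assay!r}")
    path = _DATA / "assays" / f"{assay}.csv"
    try:
        with path.open() as fh:
            return pd.read_csv(fh, comment="#")
    except FileNotFoundError:
        with (_DATA / "assays" / f"{assay}.synthetic.csv").open() as fh:
            return pd.read_csv(fh, comment="#")


def load_poraldose_table(assay: str | None = None) -> pd.DataFrame:
    """Published posterior dose summaries per target free concentration."""
    with (_DATA / "table9_poraldose.csv").open() as fh:
        df = pd.read_csv(fh)
    return df if assay is None else df[df["assay"] == assay].reset_index(drop=True)


def posterior_ranges(names: list[str]) -> dict[str, tuple[float, float]]:
    """Posterior-refined range per parameter.

    Global parameters use the printed posterior 95% interval; individual-
    specific parameters take the min/max of the per-individual interval
    bounds across the cohort; parameters in neither table fall back to
    their prior range.
    """
    glob = load_posterior_global()
    indiv = load_posterior_individual()
    pri = load_priors()
    out = {}
    for n in names:
        if n in glob.index:
            out[n] = (float(glob.loc[n, "post_lo"]), float(glob.loc[n, "post_hi"]))
        elif (indiv["name"] == n).any():
            d = indiv[indiv["name"] == n]
            out[n] = (float(d["post_lo"].min()), float(d["post_hi"].max()))
        else:
            out[n] = (float(pri.loc[n, "lower"]), float(pri.loc[n, "upper"]))
    return out


def tissue_auc_model_fn(output: str = "CVli", window: tuple = (0.0, 5.0),
                        dose_per_bw: float = 100.0, instantaneous: bool = False,
                        solver_step: float = 0.01):
    """Scalar model y(parameters) = AUC of the tissue concentration.

    ``instantaneous=True`` returns the concentration at the window end
    instead of the AUC (the alternative reading of a fixed-horizon output).
    Screened-out parameters stay at their default central values.
    """
    from .params import build_parameter_set
    base = default_parameters()

    def fn(overrides):
        d = base.to_dict()
        d.update(overrides)
        pset = build_parameter_set(d, renormalise_volumes=True)
        sim = simulate(pset, DoseEvent(dose_per_bw, 0.0, pset.DRINKTIME),
                       duration=window[1], step=max(2 * solver_step, 0.02),
                       solver_step=solver_step)
        series = sim.tissue_conc[output]
        if instantaneous:
            return float(series[-1])
        return auc(series, window, sim.time_grid)

    return fn


def max_min_ac50_ratio() -> float:
    vals = np.array(list(AC50_UM.values()))
    return float(vals.max() / vals.min())
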