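#!/usr/bin/env python
"""Forward kinetics of a single 100 ug/kg oral BPA dose.

Simulates the whole-body model at central parameter values and for a
lymph-lagged variant, writes the concentration-time tables and reports the
qualitative signatures the model must show: near-complete first-pass
conjugation (plasma BPAG far above BPA) and the double plasma-BPA peak
produced by delayed lymphatic delivery.
"""

from pathlib import Path

from bpaqivive import DoseEvent, auc, default_parameters, simulate
from bpaqivive.pbk import count_peaks

OUT = Path("results")
OUT.mkdir(exist_ok=True)

p = default_parameters()
sim = simulate(p, DoseEvent(100.0, 0.0, p.DRINKTIME))
sim.to_tsv(OUT / "kinetics_central.tsv")

lagged = default_parameters(Lymphlag=1.1, FracDOSELymph=0.05)
sim_lag = simulate(lagged, DoseEvent(100.0, 0.0, lagged.DRINKTIME))
sim_lag.to_tsv(OUT / "kinetics_lymph_lagged.tsv")

print("== single oral dose, 100 ug/kg ==")
print(f"peak plasma BPA   : {sim.plasma_conc['BPA'].max():8.3f} ug/L")
print(f"peak plasma BPAG  : {sim.plasma_conc['BPAG'].max():8.3f} ug/L")
print(f"peak plasma BPAS  : {sim.plasma_conc['BPAS'].max():8.3f} ug/L")
print(f"peak CVli         : {sim.tissue_conc['CVli'].max():8.5f} mg/L")
print(f"peak CVki         : {sim.tissue_conc['CVki'].max():8.5f} mg/L")
print(f"AUC CVli 0-3 h    : {auc(sim.tissue_conc['CVli'], (0, 3), sim.time_grid):8.5f} mg/L*h")
print(f"mass-balance error: {sim.mass_balance_rel_error[1:].max():.2e} (max relative)")
print(f"plasma BPA peaks, central params      : {count_peaks(sim.plasma_conc['BPA'])}")
print(f"plasma BPA peaks, lymph-lagged variant: {count_peaks(sim_lag.plasma_conc['BPA'])}")
print(f"wrote {OUT/'kinetics_central.tsv'} and {OUT/'kinetics_lymph_lagged.tsv'}")
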