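# bpaqivive

Probabilistic quantitative in vitro to in vivo extrapolation (QIVIVE) for
bisphenol A (BPA), built as a chain of reusable components around a
physiologically based kinetic (PBK) model of BPA and its glucuronide (BPAG)
and sulphate (BPAS) conjugates.

The problem: high-throughput in vitro assays report concentration-response
for BPA (estrogen- and pregnane-X-receptor activation in human liver and
kidney cell lines), but health-based guidance values need an **oral dose**.
The package answers "which ingested dose produces liver/kidney tissue
concentrations equal to the *free* concentration active in the assay well?",
propagating parameter and model uncertainty instead of matching doses at
fixed parameter values, and converts the resulting in vivo dose-response
into a benchmark dose (BMDL₁₀).

## What is inside

| stage | module | method |
|---|---|---|
| forward dosimetry | `pbk` | flow-limited PBK model, delay differential equations (4 h biliary recirculation lag, sampled lymphatic lag), conservative exponential-midpoint integrator (numba) |
| in vitro fate | `vcba` | equilibrium mass balance of the assay well: medium, serum (log-Kow regression), plastic, headspace (Henry), cells → free/nominal ratio |
| sensitivity | `gsa` | Morris elementary-effects screening + eFAST variance decomposition, Lowry interaction ribbon |
| calibration | `calibration` | hierarchical Bayesian (global + per-individual parameters), Gaussian error per analyte, adaptive Metropolis-within-Gibbs |
| reverse dosimetry | `reverse_dosimetry` | two-phase approximate Bayesian computation: rejection within ±7.5% of the target tissue concentration, then ABC MCMC within ±5% |
| hazard metrics | `bmd` | four continuous families (exponential/Hill, 3- and 5-parameter), lognormal ML, Akaike-weight model averaging, parametric-bootstrap BMDL₁₀/BMDU₁₀, CSAF/HED/t_TDI arithmetic |
| virtual data | `synthetic` | virtual population, virtual volunteer plasma time-courses (double-peak lymphatic kinetics), virtual Hill-curve assays |
| orchestration | `workflow`, `cli` | staged pipeline with seed management and manifests |

The kinetic core solves, per analyte, tissue mass balances of the
venous-equilibration form

```
V_t dC_t/dt = Q_t (C_art − C_t/P_t) + sources − sinks
```

with Michaelis–Menten conjugation in gut and liver
(`V_max C/(K_m + C)`, in vitro rates scaled by microsomal protein yield),
bound/unbound plasma pools (only unbound distributes), first-order biliary
uptake reappearing in the small intestine after a fixed 4 h delay, and a
lymphatic uptake route that bypasses first-pass metabolism and delivers to
venous blood after a lag — the mechanism behind the double plasma-BPA peak
seen in some volunteers.

## Worked example

```python
from bpaqivive import DoseEvent, default_parameters, simulate, auc

p = default_parameters()                       # prior central values
sim = simulate(p, DoseEvent(100.0, 0.0, p.DRINKTIME))   # 100 ug/kg oral
print(round(sim.plasma_conc["BPA"].max(), 3))  # 2.226  ug/L  peak plasma BPA
print(round(sim.plasma_conc["BPAG"].max(), 1)) # 128.9  ug/L  peak plasma BPAG
print(round(sim.tissue_conc["CVli"].max(), 5)) # 0.00481 mg/L peak liver conc
print(round(auc(sim.tissue_conc["CVli"], (0, 3), sim.time_grid), 5))  # 0.00143
```

Plasma BPAG two orders of magnitude above parent BPA is the signature of
near-complete first-pass conjugation; `CVli` (free liver BPA concentration)
is the dosimetry metric matched against free in vitro concentrations.

The numbered drivers under `analysis/` run the study end to end and print
what they find, e.g.

```
$ python analysis/04_free_concentrations.py
ATG_PXR_TRANS_up       (24-well): ratio 0.494 over 9 concentrations
$ python analysis/06_benchmark_dose.py
CSAF from the FB_BPA posterior: 2.52
ATG_PXR_TRANS_up: BMDL10   1206.0 ng/kg/day (BMD 1935.5, BMDU 2908.9); /CSAF ->   478.4
reference chain: 8960 * 0.068 = HED 609 ug/kg/day; /150 = t_TDI 4.06 ug/kg/day
```

i.e. roughly half of each nominal assay concentration is bioavailable in 5%
serum, and the pregnane-X-receptor dose-response yields a benchmark dose
around 1.2 µg/kg bw/day (1206 ng) before the chemical-specific adjustment
factor (the 97.5%/median posterior ratio of the plasma-binding fraction).

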