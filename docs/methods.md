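# Methods

This note documents the models, the numerical choices and the scope of what
the test-suite demonstrates.  It states no number that the code does not
itself compute.

## Kinetic model

BPA enters by ingestion (zero-order over `DRINKTIME`, default 0.1 h — a
bolus eaten in minutes; no published value, the choice is documented here
and configurable).  The administered dose is split at intake into three
routes: a fraction `FracDOSEHep` absorbed toward the hepatic portal vein, a
fraction `FracDOSELymph` absorbed into the lymphatic system (bypassing
first-pass metabolism, reaching venous blood after the sampled lag
`Lymphlag`), and the remainder passing unabsorbed to faeces.  Stomach
emptying is first order with a declining rate

```
k_e(t) = KEMIN + (KEMAX − KEMIN) · exp(−t/DRINKTIME)
```

an assumption (no functional form is published for the KEMAX/KEMIN pair):
the emptying rate starts near its maximum while the meal is present and
relaxes to the slow inter-digestive rate.  Absorption rates are
`BELLYPERM`/`GIPERM` (hepatic route; gut absorption passes through gut
tissue, so gut-wall conjugation acts before portal transfer) and
`BELLYPERMLymph`/`GIPERMLymph` (lymphatic route).

All tissues are flow-limited: the concentration leaving tissue *t* is
`C_t/P_t` with `P_t` the tissue:blood partition coefficient.  Stomach and
gut venous blood drains into the liver.  Conjugation of BPA to BPAG and
BPAS follows Michaelis–Menten kinetics on the free (venous-equilibrium)
tissue concentration, with in vitro maxima scaled to the whole organ by
`V_max,organ = V_max,microsomal · MPY · organ mass · 60 · MW · 1e-9` (mg/h).
Metabolite masses are tracked in their own units; mass-balance checks
convert to BPA equivalents with molecular-weight ratios (BPAG 404.37,
BPAS 308.35 g/mol).

Each analyte has bound and unbound blood pools: a fraction `FB_x` of the
venous inflow enters the bound pool, which releases to the unbound pool at
first order (`K1_x_REMOVED_PLASMA`); only the unbound pool perfuses
tissues.  Elimination is urinary (first order on kidney amount) and
biliary: first-order hepatic uptake into a bile-transit pool whose content
reappears in the small intestine exactly 4 h later, where reabsorption
(`GIPERM`) competes with faecal loss (`K1_x_GUT`).  The faecal-loss rate is
applied to the recirculated pool (the reading adopted for an ambiguous
description; a switch would be a one-line change in the kernel).

### Parameter table

`data/priors_table2.csv` carries the default distributions.  Two published
blocks conflict for several parameters; for each parameter the block whose
range is consistent with the printed prior summaries was used (materially:
KEMAX 0.1–25, BELLYPERM 0.1–10, GIPERM 0.5–25; everything else from the
second block).  `BW` is specified on the log scale (mean 4.36 ≈ 78 kg).
`QkiC`'s printed SD (0.0015) is inconsistent with its own printed prior
interval and was replaced by 0.05, which reproduces it.  Fractional blood
flows are renormalised to sum to one (preserving ratios); fractional tissue
volumes must leave a positive carcass residual — range-sweeping callers
(GSA) may opt into the analogous volume renormalisation because rectangular
range corners can overrun the budget by ≲1%.

### Integrator

Hepatic conjugation is fast enough (effective first-order rates up to 1e5/h
across the prior ranges) to make the system stiff, and the two transport
lags make it a DDE.  The solver is a **conservative exponential midpoint
scheme** on a uniform grid (default 0.005 h): every state has the
production/decay form `y' = P − D·y`; decay coefficients and outflow
routing fractions are frozen at a predictor midpoint; each donor's outflow
mass over the step has a closed form, and a few fixed-point sweeps make
every receiver's inflow equal the routed donor outflows plus the exact
external inputs (ingestion, delayed biliary/lymphatic arrivals).  The
update is unconditionally stable in `D`, positivity-preserving, second
order, and conserves mass by construction; lags are resolved by the method
of steps (the grid history is interpolated at `t − τ`, and every lag far
exceeds the step).  Halving the step changes the 0–3 h liver AUC by ~2e-5
relative; the worst mass-balance error over random parameter sets is ~1e-4.

## In vitro free concentration

The well model allocates the chemical at equilibrium among aqueous medium,
serum, plastic, headspace and cells; each sink's capacity is a partition
coefficient times its volume (or area).  Serum and plastic coefficients are
log-Kow regressions; the serum intercept is **calibrated** so BPA in 5%
serum and 24-well geometry reproduces the measured free fraction 0.499 (the
original regression constants are not recoverable; the config documents
this).  The same constants predict 0.483 for the 384-well geometry, close
to the 0.482 reported for the kidney-cell assays.  Well geometries are
standard plate specifications (24-well: 1 mL medium, 4.5 cm² wetted
plastic; 384-well: 40 µL, 0.3 cm²).  First-order aqueous degradation over
the exposure window is on by default and costs BPA ≈1% — hence the
free/nominal *ratio* column reads ≈0.494 while the equilibrium free
fraction is 0.499.  Cell growth, toxicity and time-resolved fate are out of
scope.

## Sensitivity analysis

Morris screening uses trajectory designs (default 50 trajectories, 8
levels); because rankings are stochastic the final rank is the mode over
repeats (default 6), ties broken by mean rank.  eFAST assigns the driven
parameter the top frequency (`(N−1)/2M`, interference factor M=4) and
complementary parameters low frequencies; first-order indices come from the
drive harmonics and total-order indices from the complementary spectrum.
Optional phase-resampling averages several search curves — the single-curve
estimator of a strongly multiplicative model is noisy at small N.  The
screened-out parameters stay at prior central values; ranges for the
top-ranked parameters are the printed posterior 95% intervals
(individual-specific: min/max bounds across the 14 volunteers).  The
headline output is the tissue AUC over 0–5 h; the instantaneous alternative
sits behind a flag.  In this implementation the three top parameters (MPY,
Vmax and KM of hepatic conjugation) carry ~95% of the variance of liver
AUC — liver dosimetry is clearance-dominated under the printed 3–4×
parameter spans — whereas the published spectrum is flatter; the ranking
agrees on the dominant cluster but not on the shares.

## Calibration

The error model is Gaussian per analyte on the natural concentration scale
(µg/L; the synthetic pipeline fixes this unit), with uniform priors on the
σs spanning the printed prior intervals.  Individual-scope parameters get
independent truncated priors per individual (no hyper-distribution),
matching the published table structure.  The sampler is component-wise
random-walk Metropolis-within-Gibbs with proposal scales adapted during
burn-in toward a 0.23–0.44 acceptance band; per-individual residual sums of
squares are cached so σ updates cost no model runs.  Convergence is
monitored with split-R̂.  Because the volunteer plasma data are not public,
calibration quality is demonstrated by parameter recovery on synthetic
cohorts (coverage of generating values by 95% intervals).

## Reverse dosimetry

The matched summary is the **peak** target-tissue concentration over the
simulation window (the published figures show whole concentration-time
profiles confined to the tolerance band); a time-averaged 0–3 h AUC
alternative is selectable and recorded in output metadata.  The dose range
is auto-bracketed by a 20-point logarithmic dose scan at central
parameters.  Phase 1 draws (sensitive parameters, dose) uniformly and
retains sets within ±7.5%; phase 2 runs 4 ABC-MCMC chains with multivariate
Gaussian proposals scaled from the phase-1 covariance (2.38²/d), accepting
moves inside the prior box and within ±5%; the proposal shrinks
automatically if a chain's acceptance falls below 1%.  Non-sensitive
parameters stay fixed.  A zero target is rejected (relative tolerance
undefined).  Per-assay anomaly exclusions (the two positive responses at
the lowest concentration of the kidney ERa/ERb assay) are an explicit index
list, not an automatic filter.

## Benchmark dose

Responses are continuous individual observations assumed lognormal;
percentage-activity responses are clamped (negatives and listed anomalies →
0) and shifted by +1 before fitting.  Four families are fitted by ML on the
log scale — `a·exp(b·x^d)`, `a(c−(c−1)exp(−b·x^d))`, `a(1+(c−1)x/(b+x))`,
`a(1+(c−1)x^d/(b^d+x^d))` — with bounded multi-start least squares
(`d ∈ [0.25, 6]`, `c > 1`, bounds fixed a priori).  BMD solves
`f(x) = 1.1·f(0)` in closed form per family; model averaging uses Akaike
weights; BMDL₁₀/BMDU₁₀ are the 5%/95% quantiles of a parametric bootstrap
under the weighted mixture (per replicate: draw a family by weight,
regenerate data from its fit, refit all families warm-started at the
original optima, recompute the averaged BMD).  BMDLs are reported in ng/kg
bw/day, the scale on which the published headline values are stated.  Where
the dose-response contains no observations between background and the first
clearly elevated dose, the BMDL is a low-dose extrapolation and is
implementation-sensitive; this applies to the estrogen-receptor (liver)
assay, where different fitting engines can disagree by small multiples.

## Synthetic data

The virtual population draws each parameter independently from its prior
family truncated at the printed bounds, then renormalises flows; draws
violating the volume budget are rejected and redrawn.  Organ-mass
covariance of a true population generator is **not** reproduced — passing
recovery tests therefore show sampler correctness, not robustness to
correlated physiology.  Virtual volunteer studies simulate each individual
forward (individual-scope parameters re-drawn per individual), sample at a
0–24 h schedule densified over the absorption phase, and add independent
zero-truncated Gaussian noise; the default σ per analyte is 10% of the
population-median noiseless peak, the same order as the published
posterior σs relative to plasma peaks.  Virtual assays come from a Hill
curve (`top·C^h/(AC50^h+C^h)`) encoded as log2 fold induction or percentage
activity.  The packaged table for the 1440-min kidney ER assay is a
synthetic stand-in (real concentrations, Hill-generated responses) and is
labelled as such in the file.

## Problem sizes

Defaults are chosen so a full run completes on a workstation: ABC 5000
rejection draws and 4×50 000 MCMC iterations match the published settings,
while the packaged pipeline/test configurations use reduced sizes
(hundreds of draws, hundreds of iterations, 3–4 virtual individuals,
400–1000 bootstrap replicates, ≥513 eFAST samples per parameter); each
driver and test states its own sizes.  All stages are pure functions of
their configuration and seed.

## Known limitations

- The published DDE source is unavailable; structural choices (emptying
  law, binding pools, recirculated-pool faecal loss) are documented
  assumptions, and quantities dominated by those choices (variance shares,
  low-dose BMDL extrapolations, absolute dose posteriors) reproduce the
  published values only in part.
- No inhalation/dermal routes, repeated-dose regimens beyond dose-event
  sequences, or gestational sub-models.
- The calibration demonstrations use small cohorts and short chains; real
  applications should scale `iterations` and monitor R̂.
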