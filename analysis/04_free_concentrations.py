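#!/usr/bin/env python
"""Free (bioavailable) in vitro concentrations for the four assays.

Transforms each packaged dashboard table with the well fate-and-distribution
model (5% serum) and writes tables mirroring the published layout: nominal
mg/L, free mg/L and the free/nominal ratio.
"""

from pathlib import Path

from bpaqivive.study import ASSAY_PLATE, ASSAYS, load_assay_table
from bpaqivive.vcba import default_setup, load_bpa_physchem, transform_assay_table

OUT = Path("results")
OUT.mkdir(exist_ok=True)

chem = load_bpa_physchem()
print("== free/nominal in vitro concentrations (5% serum) ==")
for assay in ASSAYS:
    setup = default_setup(ASSAY_PLATE[assay], serum_fraction=0.05)
    tab = transform_assay_table(load_assay_table(assay), chem, setup)
    tab.to_csv(OUT / f"free_conc_{assay}.csv", index=False)
    print(f"{assay:22s} ({setup.plate_format}): "
          f"ratio {tab['free_nominal_ratio'].mean():.3f} "
          f"over {len(tab)} concentrations")
print(f"wrote per-assay tables to {OUT}/free_conc_*.csv")
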