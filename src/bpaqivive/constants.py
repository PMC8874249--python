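"""Chemical constants for BPA and its conjugates.

Metabolite amounts are tracked in their own mass units; mass-balance checks
convert to BPA equivalents with the molecular-weight ratios below.
"""

MW_BPA = 228.291    # g/mol, bisphenol A
MW_BPAG = 404.37    # g/mol, BPA mono-glucuronide
MW_BPAS = 308.35    # g/mol, BPA mono-sulphate

ANALYTES = ("BPA", "BPAG", "BPAS")
MW = {"BPA": MW_BPA, "BPAG": MW_BPAG, "BPAS": MW_BPAS}

#: biliary transit time between hepatic uptake and reappearance in the small
#: intestine (enterohepatic recirculation delay), hours
BILE_LAG_H = 4.0
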