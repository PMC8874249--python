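# Physicochemical constants for bisphenol A used by the in vitro
# fate-and-distribution (free concentration) model.
name: bisphenol A
molecular_weight: 228.291        # g/mol
molecular_diffusion_volume: 220.14
molar_volume: 200.0              # cm^3/mol
henry_constant: 9.28e-7          # Pa*m^3/mol
degradation_rate_water: 2.14e-7  # 1/s
degradation_rate_air: 6.42e-5    # 1/s
log_kow: 3.32
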