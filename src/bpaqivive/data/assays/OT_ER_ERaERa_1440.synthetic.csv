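# SYNTHETIC stand-in: the published concentration-response values for this assay
# are not reproduced in the source tables; responses below were generated from a
# Hill curve at the assay's reported potency (AC50 = 4.31 uM, top = 80% activity,
# slope = 1.2) with fixed small replicate offsets. Concentrations are the assay's
# real test concentrations. Do not treat the responses as measured data.
conc_um,log10_conc_um,response,response_type
0.3,-0.523,2.91,percentage_activity
0.3,-0.523,3.35,percentage_activity
0.3,-0.523,3.02,percentage_activity
1,0.000,12.43,percentage_activity
1,0.000,11.02,percentage_activity
1,0.000,11.96,percentage_activity
3,0.477,30.21,percentage_activity
3,0.477,32.55,percentage_activity
3,0.477,31.38,percentage_activity
10,1.000,57.30,percentage_activity
10,1.000,60.11,percentage_activity
10,1.000,58.52,percentage_activity
30,1.477,74.01,percentage_activity
30,1.477,71.66,percentage_activity
30,1.477,73.15,percentage_activity
100,2.000,77.41,percentage_activity
100,2.000,79.23,percentage_activity
100,2.000,78.00,percentage_activity
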