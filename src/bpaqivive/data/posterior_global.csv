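name,prior_median,prior_lo,prior_hi,post_median,post_lo,post_hi
FB_BPA,0.488,0.023,0.962,0.119,0.006,0.300
FB_BPAG,0.845,0.707,0.982,0.920,0.905,0.935
FB_BPAS,0.845,0.707,0.982,0.855,0.744,0.927
KM_liv_BPA_in_vitro,1.31,0.154,2.44,1.543,0.750,2.44
Vmax_liv_BPA_in_vitro,4494,1183,7839,3603,1726,6268
KM_gut_BPAG_in_vitro,22.98,9.80,35.91,27.8,12.12,36.07
Vmax_gut_BPAG_in_vitro,610,262,957,433,252,922
KM_liv_BPAS_in_vitro,4.00,1.63,6.37,4.08,1.63,6.38
Vmax_liv_BPAS_in_vitro,73,16.50,132.18,70.31,21.77,123.45
KM_gut_BPAS_in_vitro,4.00,1.63,6.37,5.16,2.23,6.44
Vmax_gut_BPAS_in_vitro,73,16.50,132.18,40.39,14.93,87.92
KEMAX,12.36,0.70,24.37,1.52,0.81,2.85
GIPERM,12.85,1.05,24.46,15.13,6.60,24.33
BELLYPERM,5.05,0.36,9.75,0.78,0.11,1.89
Pfab,8.02,1.35,14.67,11.58,1.03,14.83
Pgub,8.02,1.35,14.67,3.38,1.74,6.62
Pstb,8.02,1.35,14.67,1.27,1.01,3.84
Pkib,8.02,1.35,14.67,12.00,5.59,14.85
PliG,12.01,1.59,22.49,1.19,1.00,1.85
PliS,12.01,1.59,22.49,3.20,1.03,16.44
PguG,12.01,1.59,22.49,16.75,4.43,22.77
PguS,12.01,1.59,22.49,1.75,1.01,8.46
PkiG,12.01,1.59,22.49,17.94,7.85,22.75
PkiS,12.01,1.59,22.49,11.68,2.92,22.31
K1_BPA_REMOVED_PLASMA,49.99,2.41,97.48,76.38,28.00,98.94
K1_BPAG_REMOVED_PLASMA,79.83,13.22,146.58,118,55.14,148.83
K1_BPAS_REMOVED_PLASMA,49.99,2.41,97.48,46.55,11.51,97.03
K1_BPAG_GUT,9.83,0.50,19.53,15.11,5.80,19.74
K1Lymph,0.497,0.262,0.738,0.592,0.512,0.688
sigma_BPA,6.72,0.32,22.58,0.606,0.551,0.667
sigma_BPAG,166.68,8.36,551.93,198.85,166.50,236.14
sigma_BPAS,16.88,0.76,56.71,23.34,19.16,29.02
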