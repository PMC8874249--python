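name,unit,mean,sd,lower,upper,dist,scope
BW,kg(log-scale),4.36,0.313,3.747,4.973,lognormal,individual
VliC,L/kg,0.0350,0.00758,0.021,0.0490,normal,individual
VstC,L/kg,0.0210,0.00069,0.021,0.0235,normal,global
VguC,L/kg,0.0150,0.00234,0.008,0.0220,normal,global
VkiC,L/kg,0.0058,0.00148,0.002,0.0100,normal,global
VlymphC,L/kg,0.0036,0.0007,0.0022,0.0050,normal,global
VfaC,L/kg,0.1950,0.0400,0.1200,0.2800,normal,global
VspdC,L/kg,0.6050,0.1000,0.4500,0.7500,normal,global
VrpdC,L/kg,0.0284,0.0020,0.0120,0.0450,normal,individual
VBldC,L/kg,0.0600,0.0080,0.0410,0.0790,normal,individual
QCC,L/h/kg^0.75,12.0,2.0,11.01,12.98,normal,individual
QhepartC,,0.0690,0.0060,0.0500,0.0900,normal,global
QstC,,0.0110,0.0009,0.0040,0.0160,normal,individual
QguC,,0.1700,0.0130,0.1100,0.2300,normal,individual
QkiC,,0.2000,0.0500,0.1000,0.2980,normal,individual
QfaC,,0.0500,0.0050,0.0300,0.0699,normal,global
QspdC,,0.2870,0.0221,0.2100,0.3600,normal,global
QrpdC,,0.2100,0.0168,0.1600,0.2700,normal,global
FracDOSEHep,,,,0.715,0.914,uniform,individual
FracDOSELymph,,,,0.021,0.079,uniform,individual
DRINKTIME,h,0.1,,,,fixed,global
FB_BPA,,,,0.023,0.962,uniform,global
FB_BPAG,,,,0.707,0.982,uniform,global
FB_BPAS,,,,0.707,0.982,uniform,global
MPY,mg/g,34,7,14.6,53.7,normal,individual
MPYgu,mg/g,3.9,0.8,2.3,5.5,normal,global
BELLYPERM,1/h,,,0.1,10,uniform,global
GIPERM,1/h,,,0.5,25,uniform,global
BELLYPERMLymph,1/h,,,0.84,2.5,uniform,global
GIPERMLymph,1/h,,,0.55,1.6,uniform,global
KEMAX,1/h,,,0.1,25,uniform,global
KEMIN,1/h,,,0.0025,0.0075,uniform,global
K1_BPA_GUT,1/h,,,0.55,1.6,uniform,global
K1_BPAG_GUT,1/h,,,0.50,19.3,uniform,global
K1_BPAS_GUT,1/h,,,0.55,1.6,uniform,global
K1_BPA_LIVER,1/h,,,0.55,1.6,uniform,global
K1_BPAG_LIVER,1/h,,,0.005,0.015,uniform,global
K1_BPAS_LIVER,1/h,,,0.005,0.015,uniform,global
K1_BPA_Urine,1/h,,,0.0005,0.0015,uniform,global
K1_BPAG_Urine,1/h,,,0.0005,0.0015,uniform,global
K1_BPAS_Urine,1/h,,,0.00005,0.00015,uniform,global
K1_BPA_REMOVED_PLASMA,1/h,,,2.41,97.48,uniform,global
K1_BPAG_REMOVED_PLASMA,1/h,,,13.22,146.58,uniform,global
K1_BPAS_REMOVED_PLASMA,1/h,,,2.41,97.48,uniform,global
K1Lymph,1/h,,,0.262,0.738,uniform,global
Lymphlag,h,,,0.28,1.47,uniform,individual
Vmax_liv_BPA_in_vitro,pmol/min/mg,4494,900,1183,7839,normal,global
KM_liv_BPA_in_vitro,mg/L,1.31,0.20,0.154,2.44,normal,global
Vmax_liv_BPAG_in_vitro,pmol/min/mg,487,100,290,690,normal,global
KM_liv_BPAG_in_vitro,mg/L,18.29,4,10,26,normal,global
Vmax_liv_BPAS_in_vitro,pmol/min/mg,73,40,16.50,132.18,normal,global
KM_liv_BPAS_in_vitro,mg/L,4.00,0.6,1.63,6.37,normal,global
Vmax_gut_BPAG_in_vitro,pmol/min/mg,610,100,262,957,normal,global
KM_gut_BPAG_in_vitro,mg/L,22.98,4,9.8,35.10,normal,global
Vmax_gut_BPAS_in_vitro,pmol/min/mg,73,10,16.5,132.18,normal,global
KM_gut_BPAS_in_vitro,mg/L,4.00,0.6,1.63,6.37,normal,global
Pbab,,,,0.36,1.1,uniform,global
Plib,,,,0.36,1.1,uniform,global
Pkib,,,,1.35,14.67,uniform,global
Pfab,,,,1.35,14.67,uniform,global
Pgub,,,,1.35,14.67,uniform,global
Pstb,,,,1.35,14.67,uniform,global
Prpdb,,,,1.4,4.2,uniform,global
Pspdb,,,,1.4,4.2,uniform,global
PbaG,,,,0.7,2.1,uniform,global
PliG,,,,1.59,22.49,uniform,global
PkiG,,,,1.59,22.49,uniform,global
PfaG,,,,1.2,3.60,uniform,global
PguG,,,,1.59,22.49,uniform,global
PstG,,,,1.70,5.3,uniform,global
PrpdG,,,,2.1,6.4,uniform,global
PspdG,,,,1,3,uniform,global
PbaS,,,,0.7,2.1,uniform,global
PliS,,,,1.59,22.49,uniform,global
PkiS,,,,1.59,22.49,uniform,global
PfaS,,,,1.3,3.9,uniform,global
PguS,,,,1.59,22.49,uniform,global
PstS,,,,1.9,5.7,uniform,global
PrpdS,,,,2.3,6.8,uniform,global
PspdS,,,,1,3.1,uniform,global
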