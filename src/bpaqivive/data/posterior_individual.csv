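name,individual,post_median,post_lo,post_hi
FracDOSEHep,1,0.895,0.816,0.918
FracDOSEHep,2,0.782,0.704,0.900
FracDOSEHep,3,0.782,0.706,0.900
FracDOSEHep,4,0.789,0.705,0.906
FracDOSEHep,5,0.852,0.729,0.916
FracDOSEHep,6,0.791,0.708,0.906
FracDOSEHep,7,0.889,0.793,0.918
FracDOSEHep,8,0.729,0.701,0.840
FracDOSEHep,9,0.874,0.749,0.918
FracDOSEHep,10,0.754,0.703,0.883
FracDOSEHep,11,0.907,0.859,0.919
FracDOSEHep,12,0.795,0.706,0.909
FracDOSEHep,13,0.715,0.700,0.778
FracDOSEHep,14,0.775,0.704,0.898
FracDOSELymph,1,0.040,0.030,0.051
FracDOSELymph,2,0.054,0.042,0.067
FracDOSELymph,3,0.067,0.052,0.079
FracDOSELymph,4,0.054,0.042,0.068
FracDOSELymph,5,0.030,0.021,0.042
FracDOSELymph,6,0.032,0.0234,0.0437
FracDOSELymph,7,0.042,0.032,0.055
FracDOSELymph,8,0.034,0.024,0.045
FracDOSELymph,9,0.033,0.022,0.044
FracDOSELymph,10,0.063,0.049,0.077
FracDOSELymph,11,0.033,0.021,0.047
FracDOSELymph,12,0.045,0.030,0.061
FracDOSELymph,13,0.023,0.020,0.029
FracDOSELymph,14,0.061,0.046,0.077
Lymphlag,1,1.14,0.993,1.28
Lymphlag,2,0.929,0.684,1.28
Lymphlag,3,0.38,0.292,0.657
Lymphlag,4,0.936,0.800,0.989
Lymphlag,5,1.12,0.267,1.32
Lymphlag,6,0.877,0.783,0.979
Lymphlag,7,0.636,0.316,0.728
Lymphlag,8,0.641,0.366,0.984
Lymphlag,9,0.315,0.253,0.480
Lymphlag,10,0.713,0.668,0.741
Lymphlag,11,0.772,0.736,0.814
Lymphlag,12,0.432,0.290,0.580
Lymphlag,13,0.734,0.524,0.995
Lymphlag,14,0.575,0.268,0.719
MPY,1,48.5,40.3,53.6
MPY,2,36.5,27.5,48.4
MPY,3,45.2,35.1,53.1
MPY,4,30.7,23.3,40.2
MPY,5,16.3,14.1,21.9
MPY,6,45.2,36.2,53.0
MPY,7,49.5,40.5,53.7
MPY,8,36.9,26.8,48.8
MPY,9,41.3,32.2,51.6
MPY,10,34.0,25.9,43.8
MPY,11,14.5,14.0,16.4
MPY,12,19.9,14.7,28.2
MPY,13,25.4,17.7,37.1
MPY,14,41.8,31.2,52.6
VrpdC,1,0.030,0.014,0.043
VrpdC,2,0.032,0.017,0.043
VrpdC,3,0.032,0.017,0.044
VrpdC,4,0.029,0.016,0.042
VrpdC,5,0.025,0.013,0.041
VrpdC,6,0.028,0.014,0.043
VrpdC,7,0.028,0.014,0.042
VrpdC,8,0.030,0.017,0.043
VrpdC,9,0.028,0.015,0.042
VrpdC,10,0.032,0.016,0.044
VrpdC,11,0.029,0.015,0.043
VrpdC,12,0.028,0.014,0.042
VrpdC,13,0.030,0.016,0.043
VrpdC,14,0.029,0.015,0.042
VliC,1,0.029,0.021,0.043
VliC,2,0.039,0.024,0.050
VliC,3,0.042,0.027,0.050
VliC,4,0.031,0.021,0.047
VliC,5,0.035,0.023,0.048
VliC,6,0.031,0.021,0.047
VliC,7,0.025,0.020,0.044
VliC,8,0.043,0.027,0.050
VliC,9,0.034,0.021,0.049
VliC,10,0.045,0.032,0.049
VliC,11,0.021,0.020,0.023
VliC,12,0.038,0.023,0.049
VliC,13,0.048,0.040,0.050
VliC,14,0.035,0.021,0.049
VBldC,1,0.052,0.041,0.070
VBldC,2,0.062,0.044,0.080
VBldC,3,0.057,0.042,0.075
VBldC,4,0.068,0.049,0.085
VBldC,5,0.052,0.041,0.071
VBldC,6,0.058,0.042,0.077
VBldC,7,0.059,0.043,0.077
VBldC,8,0.059,0.042,0.078
VBldC,9,0.066,0.047,0.083
VBldC,10,0.052,0.041,0.070
VBldC,11,0.055,0.041,0.074
VBldC,12,0.062,0.045,0.081
VBldC,13,0.063,0.045,0.081
VBldC,14,0.060,0.044,0.079
QCC,1,12.00,11.18,12.85
QCC,2,12.00,11.19,12.84
QCC,3,12.25,11.35,12.92
QCC,4,11.85,11.08,12.73
QCC,5,12.42,11.56,12.95
QCC,6,12.05,11.20,12.85
QCC,7,11.82,11.08,12.72
QCC,8,12.17,11.29,12.91
QCC,9,11.66,11.04,12.56
QCC,10,12.31,11.47,12.93
QCC,11,12.33,11.48,12.94
QCC,12,11.94,11.13,12.79
QCC,13,12.05,11.18,12.82
QCC,14,12.04,11.20,12.86
QguC,1,0.187,0.142,0.234
QguC,2,0.130,0.095,0.182
QguC,3,0.183,0.134,0.231
QguC,4,0.116,0.092,0.171
QguC,5,0.220,0.172,0.247
QguC,6,0.180,0.134,0.229
QguC,7,0.166,0.120,0.219
QguC,8,0.172,0.118,0.226
QguC,9,0.102,0.090,0.152
QguC,10,0.200,0.150,0.244
QguC,11,0.235,0.199,0.249
QguC,12,0.168,0.117,0.220
QguC,13,0.129,0.092,0.202
QguC,14,0.167,0.115,0.221
QstC,1,0.011,0.007,0.015
QstC,2,0.009,0.005,0.014
QstC,3,0.010,0.006,0.014
QstC,4,0.008,0.005,0.013
QstC,5,0.013,0.007,0.015
QstC,6,0.009,0.005,0.014
QstC,7,0.010,0.006,0.014
QstC,8,0.009,0.005,0.014
QstC,9,0.009,0.005,0.014
QstC,10,0.011,0.006,0.015
QstC,11,0.013,0.009,0.015
QstC,12,0.009,0.006,0.014
QstC,13,0.007,0.005,0.013
QstC,14,0.009,0.006,0.014
QkiC,1,0.133,0.102,0.210
QkiC,2,0.172,0.110,0.259
QkiC,3,0.218,0.135,0.282
QkiC,4,0.217,0.134,0.289
QkiC,5,0.190,0.117,0.271
QkiC,6,0.222,0.141,0.289
QkiC,7,0.160,0.104,0.259
QkiC,8,0.222,0.146,0.292
QkiC,9,0.204,0.115,0.291
QkiC,10,0.207,0.133,0.285
QkiC,11,0.158,0.110,0.236
QkiC,12,0.231,0.152,0.292
QkiC,13,0.249,0.170,0.297
QkiC,14,0.189,0.115,0.275
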