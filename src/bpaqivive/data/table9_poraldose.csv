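assay,free_conc_mgL,dose_mean,dose_lo,dose_hi
ATG_ERE_CIS_up,0.0011,0.073,0.044,0.101
ATG_ERE_CIS_up,0.0034,0.207,0.113,0.296
ATG_ERE_CIS_up,0.0103,0.617,0.340,0.892
ATG_ERE_CIS_up,0.0342,1.983,1.164,2.796
ATG_ERE_CIS_up,0.0912,4.932,3.072,6.767
ATG_ERE_CIS_up,0.2280,11.054,5.691,16.713
ATG_ERE_CIS_up,0.7979,28.415,18.999,37.114
ATG_ERE_CIS_up,2.2794,47.675,29.234,65.224
ATG_ERE_CIS_up,7.9735,63.492,39.384,91.921
ATG_PXR_TRANS_up,0.0011,0.071,0.045,0.099
ATG_PXR_TRANS_up,0.0034,0.206,0.112,0.295
ATG_PXR_TRANS_up,0.0103,0.636,0.325,0.892
ATG_PXR_TRANS_up,0.0342,2.000,1.136,2.780
ATG_PXR_TRANS_up,0.0912,5.067,3.191,6.892
ATG_PXR_TRANS_up,0.2280,11.668,6.316,17.315
ATG_PXR_TRANS_up,0.7979,27.969,18.873,37.635
ATG_PXR_TRANS_up,2.2794,46.346,30.225,65.934
ATG_PXR_TRANS_up,7.9735,71.190,42.385,99.022
OT_ER_ERaERb_0480,0.000342,0.064,0.036,0.088
OT_ER_ERaERb_0480,0.000342,0.064,0.037,0.091
OT_ER_ERaERb_0480,0.000342,0.066,0.041,0.089
OT_ER_ERaERb_0480,0.00114,0.218,0.123,0.302
OT_ER_ERaERb_0480,0.00114,0.210,0.108,0.293
OT_ER_ERaERb_0480,0.00114,0.222,0.115,0.297
OT_ER_ERaERb_0480,0.00342,0.641,0.370,0.918
OT_ER_ERaERb_0480,0.00342,0.606,0.317,0.848
OT_ER_ERaERb_0480,0.00342,0.636,0.322,0.881
OT_ER_ERaERb_0480,0.0114,1.944,1.028,2.660
OT_ER_ERaERb_0480,0.0114,1.946,1.077,2.770
OT_ER_ERaERb_0480,0.0114,1.900,1.018,2.686
OT_ER_ERaERb_0480,0.0342,5.818,3.056,8.414
OT_ER_ERaERb_0480,0.0342,5.908,3.096,8.405
OT_ER_ERaERb_0480,0.0342,5.539,2.809,8.167
OT_ER_ERaERb_0480,0.1140,16.179,8.797,23.327
OT_ER_ERaERb_0480,0.1140,15.493,7.909,22.599
OT_ER_ERaERb_0480,0.1140,15.608,8.027,22.916
OT_ER_ERaERa_1440,0.0342,5.506,2.647,8.286
OT_ER_ERaERa_1440,0.0342,5.984,3.199,8.671
OT_ER_ERaERa_1440,0.0342,5.776,2.937,8.357
OT_ER_ERaERa_1440,0.1140,15.756,8.346,23.086
OT_ER_ERaERa_1440,0.1140,16.479,9.024,23.656
OT_ER_ERaERa_1440,0.1140,15.792,9.130,23.596
OT_ER_ERaERa_1440,0.3300,35.363,15.713,50.038
OT_ER_ERaERa_1440,0.3300,35.934,18.461,54.609
OT_ER_ERaERa_1440,0.3300,37.669,17.623,53.009
OT_ER_ERaERa_1440,1.1000,55.016,36.066,80.310
OT_ER_ERaERa_1440,1.1000,61.304,35.836,84.071
OT_ER_ERaERa_1440,1.1000,60.767,35.497,87.693
OT_ER_ERaERa_1440,3.3000,71.272,41.800,102.735
OT_ER_ERaERa_1440,3.3000,83.133,41.956,117.018
OT_ER_ERaERa_1440,3.3000,73.174,39.195,109.996
OT_ER_ERaERa_1440,11.000,89.123,53.953,137.919
OT_ER_ERaERa_1440,11.000,88.440,53.447,132.985
OT_ER_ERaERa_1440,11.000,101.950,54.850,142.909
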