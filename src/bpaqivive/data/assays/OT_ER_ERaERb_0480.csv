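conc_um,log10_conc_um,response,response_type
0.003,-2.523,-6.989,percentage_activity
0.003,-2.523,-4.593,percentage_activity
0.003,-2.523,-4.548,percentage_activity
0.01,-2.000,2.330,percentage_activity
0.01,-2.000,-0.599,percentage_activity
0.01,-2.000,3.617,percentage_activity
0.03,-1.523,-5.303,percentage_activity
0.03,-1.523,-5.480,percentage_activity
0.03,-1.523,-0.333,percentage_activity
0.1,-1.000,-0.954,percentage_activity
0.1,-1.000,-1.176,percentage_activity
0.1,-1.000,2.019,percentage_activity
0.3,-0.523,26.914,percentage_activity
0.3,-0.523,30.286,percentage_activity
0.3,-0.523,24.074,percentage_activity
1,0.000,72.620,percentage_activity
1,0.000,78.744,percentage_activity
1,0.000,60.373,percentage_activity
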