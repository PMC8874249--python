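conc_um,log10_conc_um,response,response_type
0.01,-2.000,-0.050,log2_fold_induction
0.03,-1.523,0.257,log2_fold_induction
0.09,-1.046,0.056,log2_fold_induction
0.3,-0.523,0.277,log2_fold_induction
0.8,-0.097,1.689,log2_fold_induction
2,0.301,2.711,log2_fold_induction
7,0.845,2.740,log2_fold_induction
20,1.301,2.547,log2_fold_induction
70,1.845,2.340,log2_fold_induction
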