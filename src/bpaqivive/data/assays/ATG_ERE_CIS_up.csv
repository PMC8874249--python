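conc_um,log10_conc_um,response,response_type
0.01,-2.000,-0.122,log2_fold_induction
0.03,-1.523,0.239,log2_fold_induction
0.09,-1.046,1.144,log2_fold_induction
0.3,-0.523,2.046,log2_fold_induction
0.8,-0.097,2.442,log2_fold_induction
2,0.301,2.717,log2_fold_induction
7,0.845,2.368,log2_fold_induction
20,1.301,2.053,log2_fold_induction
70,1.845,2.427,log2_fold_induction
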