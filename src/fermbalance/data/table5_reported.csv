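sample,gene,ratio,copies
ER_T12,temA,4.46,4
ER_T12,temG_Opt,7.20,7
M2n_T1,temA,0.92,1
M2n_T1,temG_Opt,0.99,1
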