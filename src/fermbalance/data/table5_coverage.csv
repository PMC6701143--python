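sample,gene,avg_coverage,role
ER_T12,temA,152,target
ER_T12,temG_Opt,245,target
ER_T12,ALG9,34,housekeeping
ER_T12,TFC1,34,housekeeping
ER_T12,PGK1,34,housekeeping
ER_T12,ACT1,35,housekeeping
M2n_T1,temA,39,target
M2n_T1,temG_Opt,41,target
M2n_T1,ALG9,43,housekeeping
M2n_T1,TFC1,42,housekeeping
M2n_T1,PGK1,38,housekeeping
M2n_T1,ACT1,44,housekeeping
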