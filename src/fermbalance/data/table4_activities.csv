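strain,substrate_form,substrate_load_pct,temperature_c,assay_kind,activity_u_ml
ER_T1,raw,2.0,30,reducing_sugar,0.29
ER_T12,raw,2.0,30,reducing_sugar,0.99
M2n_T1,raw,2.0,30,reducing_sugar,0.33
M2n_T2,raw,2.0,30,reducing_sugar,0.20
ER_T1,raw,2.0,37,reducing_sugar,0.42
ER_T12,raw,2.0,37,reducing_sugar,1.38
M2n_T1,raw,2.0,37,reducing_sugar,0.48
M2n_T2,raw,2.0,37,reducing_sugar,0.29
ER_T1,raw,2.0,30,glucose_only,0.15
ER_T12,raw,2.0,30,glucose_only,0.44
M2n_T1,raw,2.0,30,glucose_only,0.27
M2n_T2,raw,2.0,30,glucose_only,0.16
ER_T1,raw,2.0,37,glucose_only,0.16
ER_T12,raw,2.0,37,glucose_only,0.48
M2n_T1,raw,2.0,37,glucose_only,0.29
M2n_T2,raw,2.0,37,glucose_only,0.17
ER_T1,soluble,0.2,30,reducing_sugar,2.03
ER_T12,soluble,0.2,30,reducing_sugar,9.11
M2n_T1,soluble,0.2,30,reducing_sugar,2.21
M2n_T2,soluble,0.2,30,reducing_sugar,1.28
ER_T1,soluble,0.2,37,reducing_sugar,3.39
ER_T12,soluble,0.2,37,reducing_sugar,15.30
M2n_T1,soluble,0.2,37,reducing_sugar,3.99
M2n_T2,soluble,0.2,37,reducing_sugar,2.46
ER_T1,soluble,0.2,30,glucose_only,1.47
ER_T12,soluble,0.2,30,glucose_only,4.43
M2n_T1,soluble,0.2,30,glucose_only,1.11
M2n_T2,soluble,0.2,30,glucose_only,0.65
ER_T1,soluble,0.2,37,glucose_only,2.12
ER_T12,soluble,0.2,37,glucose_only,6.32
M2n_T1,soluble,0.2,37,glucose_only,1.59
M2n_T2,soluble,0.2,37,glucose_only,0.96
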