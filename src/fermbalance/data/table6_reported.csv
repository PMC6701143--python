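strain,total_products,carbon_conversion_pct,ethanol_yield_pct,ethanol_productivity
ER_SSF_30C_GSHE28.3,192.51,92,92,0.50
M2n_SSF_30C_GSHE28.3,195.77,94,93,0.51
ER_T12_30C_GSHE2.8,196.07,94,93,0.51
M2n_T1_30C_GSHE2.8,199.98,96,94,0.51
ER_T12_30C_GSHE0,180.79,87,86,0.47
M2n_T1_30C_GSHE0,196.78,94,94,0.51
ER_SSF_37C_GSHE28.3,207.00,99,78,0.42
M2n_SSF_37C_GSHE28.3,196.33,94,61,0.33
ER_T12_37C_GSHE2.8,208.63,100,73,0.40
M2n_T1_37C_GSHE2.8,204.25,98,55,0.30
ER_T12_37C_GSHE0,169.66,81,60,0.33
M2n_T1_37C_GSHE0,173.62,83,26,0.14
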