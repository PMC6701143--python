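strain,time_h,glucose,maltose,glycerol,acetic_acid,ethanol,co2
ER_SSF_30C_GSHE28.3,192,0.02,0.79,4.07,0.00,95.90,91.73
M2n_SSF_30C_GSHE28.3,192,0.31,0.71,4.30,0.00,97.34,93.11
ER_T12_30C_GSHE2.8,192,0.02,0.31,4.76,0.90,97.16,92.93
M2n_T1_30C_GSHE2.8,192,3.28,0.37,4.59,0.31,97.84,93.59
ER_T12_30C_GSHE0,192,0.22,1.95,3.18,0.64,89.35,85.46
M2n_T1_30C_GSHE0,192,0.09,0.96,3.73,0.00,98.13,93.87
ER_SSF_37C_GSHE28.3,192,40.12,1.27,5.72,0.83,81.30,77.76
M2n_SSF_37C_GSHE28.3,192,62.30,2.53,5.64,0.66,63.99,61.21
ER_T12_37C_GSHE2.8,192,50.79,2.14,6.07,0.95,75.99,72.69
M2n_T1_37C_GSHE2.8,192,83.92,3.23,5.54,0.39,56.82,54.35
ER_T12_37C_GSHE0,192,39.62,0.70,5.50,1.28,62.64,59.92
M2n_T1_37C_GSHE0,192,113.91,3.37,2.63,0.95,26.96,25.79
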