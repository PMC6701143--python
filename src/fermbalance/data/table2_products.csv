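strain,time_h,glucose,maltose,glycerol,acetic_acid,ethanol,co2
Y294[TemG_Opt-AmyA],192,2.72,1.09,4.76,1.91,47.40,45.33
Y294[TemG_Opt-TemA],192,46.30,1.03,6.64,1.66,62.20,59.50
Y294[TemG_Opt-TemA_Opt],192,1.67,1.07,2.40,0.60,48.71,46.59
Y294[TemG_Opt-AteA],192,1.94,1.14,3.43,0.85,53.46,51.13
Y294[TemG_Opt-ApuA],192,1.21,0.95,2.45,0.61,43.12,41.25
Y294[GlaA-TemA],192,4.12,1.17,2.26,0.56,46.56,44.53
Y294[AmyA-GlaA],192,5.30,1.02,2.46,0.61,52.78,50.48
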