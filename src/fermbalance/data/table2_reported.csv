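strain,total_products,carbon_conversion_pct,ethanol_yield_pct,ethanol_productivity
Y294[TemG_Opt-AmyA],103.21,50,46,0.25
Y294[TemG_Opt-TemA],177.33,85,60,0.32
Y294[TemG_Opt-TemA_Opt],101.04,49,47,0.25
Y294[TemG_Opt-AteA],111.95,54,51,0.28
Y294[TemG_Opt-ApuA],89.60,43,41,0.23
Y294[GlaA-TemA],99.20,48,45,0.24
Y294[AmyA-GlaA],112.65,54,51,0.28
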