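# Reference loading: 200 g/l raw corn starch as-is (183.3 g/l dry weight)
# plus 5 g/l free glucose in the medium.
starch_as_is: 200.0
starch_dry: 183.3
added_glucose: 5.0
hydrolysis_factor: 1.11
theoretical_factor: 0.50
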