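# Overall trial cohort, lifelong treatment (rho = 0.316), no discontinuation.
profile: overall
mode: mean
effect_measure: reciprocal_creatinine
subgroup: overall
discontinuation: false
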