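# Rapidly progressing Mayo 1C-1E subgroup, CKD-EPI effect size (rho = 0.282).
profile: mayo_1c_1e
mode: mean
effect_measure: ckd_epi
subgroup: mayo_1c_1e
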