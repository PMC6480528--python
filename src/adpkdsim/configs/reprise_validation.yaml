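# Later-stage validation cohort, CKD-EPI overall effect (rho = 0.264).
profile: reprise
mode: mean
effect_measure: ckd_epi
subgroup: overall
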