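# CKD stage 3 subgroup at baseline, base-case effect size.
profile: ckd3
mode: mean
effect_measure: reciprocal_creatinine
subgroup: overall
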