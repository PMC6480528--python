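# Overall cohort with the published annual discontinuation schedule applied.
profile: overall
mode: mean
effect_measure: reciprocal_creatinine
subgroup: overall
discontinuation: true
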