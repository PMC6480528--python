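# Early-treated extension cohort: 3 yr on treatment, 3-month washout, resume.
profile: tempo44
mode: mean
effect_measure: ckd_epi
subgroup: overall
stop_time: 3.0
washout_gap: 0.25
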