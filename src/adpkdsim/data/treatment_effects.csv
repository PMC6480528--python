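measure,subgroup,rho
reciprocal_creatinine,overall,0.316
ckd_epi,overall,0.264
reciprocal_creatinine,ckd1,0.147
reciprocal_creatinine,ckd2,0.310
reciprocal_creatinine,ckd3,0.405
ckd_epi,ckd1,0.155
ckd_epi,ckd2,0.291
ckd_epi,ckd3,0.310
ckd_epi,mayo_1c_1e,0.282
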