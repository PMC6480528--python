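name,n,mean_age,pct_female,mean_egfr,mean_tkv,se_age,se_pct_female,se_egfr,se_tkv
TEMPO 3:4 overall,1445,38.7,48.4,81.61,1692.30,,,,
CKD 1,502,34.3,52.7,105.69,1353.76,,,,
CKD 2,689,40.3,49.5,75.00,1712.00,,,,
CKD 3,248,42.0,36.7,51.34,2323.18,,,,
Mayo 1C-1E,1285,38.0,46.1,81.29,1760.40,,,,
TEMPO 4:4 early-treated,557,38.95,45.60,81.35,1706.00,0.29,2.11,0.68,37.35
REPRISE overall,1370,47.50,50.40,41.00,2026.30,0.22,0.01,0.30,37.88
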