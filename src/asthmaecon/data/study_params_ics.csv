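strategy,state,cost_cny,probability,utility_qaly
A1,hospitalization,132.26,0.1739,11.646
A1,outpatient_exacerbation,44.09,0.1739,13.806
A1,symptom_free,247.99,0.6522,15.606
A2,hospitalization,197.4,0.1474,11.646
A2,outpatient_exacerbation,141.0,0.1789,13.806
A2,symptom_free,502.23,0.6737,15.606
A,hospitalization,180.03,0.1525,11.646
A,outpatient_exacerbation,106.8,0.178,13.806
A,symptom_free,432.09,0.6695,15.606
B1,hospitalization,145.31,0.064,11.646
B1,outpatient_exacerbation,159.81,0.1366,13.806
B1,symptom_free,857.25,0.7994,15.606
B2,hospitalization,143.68,0.0394,11.646
B2,outpatient_exacerbation,327.08,0.1232,13.806
B2,symptom_free,1881.11,0.8374,15.606
B,hospitalization,144.86,0.0548,11.646
B,outpatient_exacerbation,215.56,0.1316,13.806
B,symptom_free,1139.7,0.8135,15.606
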