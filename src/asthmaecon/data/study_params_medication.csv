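strategy,state,cost_cny,probability,utility_qaly
A1,hospitalization,1989.6,0.1739,11.646
A1,outpatient_exacerbation,242.69,0.1739,13.806
A1,symptom_free,1652.4,0.6522,15.606
A2,hospitalization,1979.7,0.1474,11.646
A2,outpatient_exacerbation,573.7,0.1789,13.806
A2,symptom_free,1124.17,0.6737,15.606
A,hospitalization,1982.34,0.1525,11.646
A,outpatient_exacerbation,456.87,0.178,13.806
A,symptom_free,1269.89,0.6695,15.606
B1,hospitalization,1746.83,0.064,11.646
B1,outpatient_exacerbation,627.79,0.1366,13.806
B1,symptom_free,3066.38,0.7994,15.606
B2,hospitalization,1839.83,0.0394,11.646
B2,outpatient_exacerbation,1002.77,0.1232,13.806
B2,symptom_free,5923.5,0.8374,15.606
B,hospitalization,1772.49,0.0548,11.646
B,outpatient_exacerbation,752.78,0.1316,13.806
B,symptom_free,3854.55,0.8135,15.606
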