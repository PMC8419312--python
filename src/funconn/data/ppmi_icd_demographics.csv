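variable,group,mean,sd,n,printed_p
age,HC,64.75,9.28,16,0.44
age,PD_nICD,59.69,11.64,18,0.44
age,PD_ICD,62.13,12.53,18,0.44
disease_duration,PD_nICD,1.90,0.81,18,0.06
disease_duration,PD_ICD,2.62,1.33,18,0.06
updrs_iii,PD_nICD,19.67,8.22,18,0.40
updrs_iii,PD_ICD,22.39,10.72,18,0.40
hoehn_yahr,PD_nICD,1.78,0.43,18,0.73
hoehn_yahr,PD_ICD,1.83,0.51,18,0.73
moca,HC,27.75,1.25,16,0.10
moca,PD_nICD,27.44,2.25,18,0.10
moca,PD_ICD,25.67,4.39,18,0.10
education,HC,16.88,2.66,16,0.37
education,PD_nICD,15.56,2.91,18,0.37
education,PD_ICD,15.78,2.96,18,0.37
depression_gds15,HC,2.19,2.95,16,0.40
depression_gds15,PD_nICD,2.06,1.92,18,0.40
depression_gds15,PD_ICD,3.11,2.61,18,0.40
quip_cs,HC,0.0,0.0,16,
quip_cs,PD_nICD,0.0,0.0,18,
quip_cs,PD_ICD,1.22,0.55,18,
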