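group,male,female
HC,13,3
PD_nICD,12,6
PD_ICD,12,6
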