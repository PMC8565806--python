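case,sex,age_years,drug,disease,dose_g,adr
1,male,1,Ceftriaxone,upper respiratory tract infection,1,anaphylactic shock
2,female,5,Ceftriaxone,urinary tract infection,2,anaphylactoid reaction
3,male,5,Ceftriaxone,acute bronchitis,2,anaphylactic shock
4,female,14,Ceftazidime,upper respiratory tract infection,2,dyspnoea
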