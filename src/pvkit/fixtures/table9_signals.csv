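generation,drug,adr,off_label
1st,Ceftezole,tremor,true
1st,Ceftezole,cyanosis,true
1st,Ceftezole,pallor,true
1st,Ceftezole,rigors,true
1st,Ceftezole,palpitation,true
1st,Ceftezole,dizziness,true
1st,Ceftezole,face oedema,true
1st,Ceftezole,agitation,true
1st,Ceftezole,rash,false
1st,Ceftezole,pruritus,false
1st,Ceftezole,erythematous rash,false
1st,Ceftezole,urticaria,false
1st,Ceftezole,urticaria acute,false
1st,Ceftezole,nausea,false
1st,Ceftezole,vomiting,false
1st,Ceftezole,abdominal pain,false
1st,Ceftezole,flushing,false
1st,Ceftezole,sweating increased,false
1st,Ceftezole,fever,false
1st,Ceftezole,hyperpyrexia,false
1st,Ceftezole,coughing,false
1st,Ceftezole,allergic reaction,false
1st,Ceftezole,dyspnoea,false
1st,Cefathiamidine,dermatitis,true
1st,Cefathiamidine,coughing,true
1st,Cefathiamidine,lip disorder,true
1st,Cefathiamidine,rash,false
1st,Cefathiamidine,pruritus,false
1st,Cefathiamidine,urticaria,false
1st,Cefathiamidine,skin disorder,false
1st,Cefathiamidine,hyperpyrexia,false
1st,Cefathiamidine,rigors,false
1st,Cefathiamidine,oedema,false
1st,Cefathiamidine,anaphylactoid reaction,false
1st,Cefazolin,vesicular rash,true
1st,Cefazolin,abdominal pain,true
1st,Cefazolin,nausea,false
1st,Cefazolin,vomiting,false
1st,Cefazolin,allergic reaction,false
1st,Cefazolin pentahydrate,rash maculo-papular,true
1st,Cefazolin pentahydrate,dermatitis,true
1st,Cefazolin pentahydrate,urticaria,true
1st,Cefazolin pentahydrate,rash,false
1st,Cefazolin pentahydrate,pruritus,false
1st,Cefazedone,coughing,true
1st,Cefazedone,pruritus,true
1st,Cefazedone,rash,false
1st,Cefadroxil,nausea,false
1st,Cefadroxil,allergic reaction,false
1st,Cefradine,nausea,false
1st,Cefradine,vomiting,false
1st,Cefalexin,nausea,false
1st,Cefalexin,vomiting,false
2nd,Cefuroxime,tremor,true
2nd,Cefuroxime,injection site pruritus,true
2nd,Cefuroxime,rash,false
2nd,Cefuroxime,pruritus,false
2nd,Cefuroxime,nausea,false
2nd,Cefuroxime,vomiting,false
2nd,Cefuroxime,abdominal pain,false
2nd,Cefuroxime,rigors,false
2nd,Cefuroxime,fever,false
2nd,Cefuroxime,hyperpyrexia,false
2nd,Cefuroxime,dizziness,false
2nd,Cefuroxime,palpitation,false
2nd,Cefuroxime,anaphylactoid reaction,false
2nd,Cefuroxime,allergic reaction,false
2nd,Cefuroxime,dyspnoea,false
2nd,Cefuroxime,injection site reaction,false
2nd,Cefamandole nafate,pruritus,true
2nd,Cefamandole nafate,coughing,true
2nd,Cefamandole nafate,abdomen enlarged,true
2nd,Cefamandole nafate,chest pain,true
2nd,Cefamandole nafate,face oedema,true
2nd,Cefamandole nafate,agitation,true
2nd,Cefamandole nafate,rash,false
2nd,Cefamandole nafate,urticaria,false
2nd,Cefamandole nafate,skin disorder,false
2nd,Cefamandole nafate,fever,false
2nd,Cefamandole nafate,hyperpyrexia,false
2nd,Cefamandole nafate,injection site reaction,false
2nd,Cefaclor,dermatitis,true
2nd,Cefaclor,abdominal pain,true
2nd,Cefaclor,flushing,true
2nd,Cefaclor,vomiting,false
2nd,Cefaclor,nausea,false
2nd,Cefaclor,diarrhoea,false
2nd,Cefaclor,allergic reaction,false
2nd,Cefotiam,face oedema,true
2nd,Cefotiam,rash,false
2nd,Cefotiam,rash erythematous,false
2nd,Cefotiam,urticaria,false
2nd,Cefotiam,flushing,false
2nd,Cefotiam,fever,false
2nd,Cefprozil,nausea,false
2nd,Cefprozil,vomiting,false
2nd,Cefprozil,diarrhoea,false
2nd,Cefuroxime axetil,vomiting,false
3rd,Cefoperazone/Sulbactam,flushing,true
3rd,Cefoperazone/Sulbactam,dyspnoea,true
3rd,Cefoperazone/Sulbactam,agitation,true
3rd,Cefoperazone/Sulbactam,dermatitis,true
3rd,Cefoperazone/Sulbactam,dizziness,true
3rd,Cefoperazone/Sulbactam,palpitation,true
3rd,Cefoperazone/Sulbactam,back pain,true
3rd,Cefoperazone/Sulbactam,cyanosis,true
3rd,Cefoperazone/Sulbactam,rash,false
3rd,Cefoperazone/Sulbactam,pruritus,false
3rd,Cefoperazone/Sulbactam,rash maculo-papular,false
3rd,Cefoperazone/Sulbactam,urticaria acute,false
3rd,Cefoperazone/Sulbactam,nausea,false
3rd,Cefoperazone/Sulbactam,vomiting,false
3rd,Cefoperazone/Sulbactam,abdominal pain,false
3rd,Cefoperazone/Sulbactam,allergic reaction,false
3rd,Cefoperazone/Sulbactam,anaphylactic shock,false
3rd,Ceftazidime,pallor,true
3rd,Ceftazidime,flushing,true
3rd,Ceftazidime,cyanosis,true
3rd,Ceftazidime,rigors,true
3rd,Ceftazidime,increased stool frequency,true
3rd,Ceftazidime,rash,false
3rd,Ceftazidime,pruritus,false
3rd,Ceftazidime,rash maculo-papular,false
3rd,Ceftazidime,rash erythematous,false
3rd,Ceftazidime,urticaria,false
3rd,Ceftazidime,urticaria acute,false
3rd,Ceftazidime,nausea,false
3rd,Ceftazidime,vomiting,false
3rd,Ceftazidime,abdominal pain,false
3rd,Ceftazidime,allergic reaction,false
3rd,Cefotaxime,rash maculo-papular,true
3rd,Cefotaxime,dermatitis,true
3rd,Cefotaxime,vesicular rash,true
3rd,Cefotaxime,palpitation,true
3rd,Cefotaxime,larynx oedema,true
3rd,Cefotaxime,lip disorder,true
3rd,Cefotaxime,rash,false
3rd,Cefotaxime,pruritus,false
3rd,Cefotaxime,nausea,false
3rd,Cefotaxime,vomiting,false
3rd,Cefotaxime,headache,false
3rd,Cefotaxime,allergic reaction,false
3rd,Cefotaxime,anaphylactic shock,false
3rd,Cefotaxime,dyspnoea,false
3rd,Cefoperazone/Tazobactam,vesicular rash,true
3rd,Cefoperazone/Tazobactam,coughing,true
3rd,Cefoperazone/Tazobactam,pneumonia,true
3rd,Cefoperazone/Tazobactam,face oedema,true
3rd,Cefoperazone/Tazobactam,eye pain,true
3rd,Cefoperazone/Tazobactam,eye abnormality,true
3rd,Cefoperazone/Tazobactam,agitation,true
3rd,Cefoperazone/Tazobactam,rash,false
3rd,Cefoperazone/Tazobactam,pruritus,false
3rd,Cefoperazone/Tazobactam,urticaria,false
3rd,Ceftriaxone,dyspnoea,true
3rd,Ceftriaxone,anaesthesia local,true
3rd,Ceftriaxone,pain,true
3rd,Ceftriaxone,pruritus,false
3rd,Ceftriaxone,rash erythematous,false
3rd,Ceftriaxone,abdominal pain,false
3rd,Ceftriaxone,anaphylactoid reaction,false
3rd,Ceftriaxone,allergic reaction,false
3rd,Ceftriaxone,anaphylactic shock,false
3rd,Ceftizoxime,rash maculo-papular,true
3rd,Ceftizoxime,flushing,true
3rd,Ceftizoxime,pallor,true
3rd,Ceftizoxime,rigors,true
3rd,Ceftizoxime,cyanosis,true
3rd,Ceftizoxime,oedema periorbital,true
3rd,Ceftizoxime,rash,false
3rd,Ceftizoxime,diarrhoea,false
3rd,Ceftizoxime,allergic reaction,false
3rd,Cefixime,rash,false
3rd,Cefixime,rash erythematous,false
3rd,Cefixime,urticaria,false
3rd,Cefixime,nausea,false
3rd,Cefixime,diarrhoea,false
3rd,Cefixime,flushing,false
3rd,Cefixime,sweating increased,false
3rd,Cefotaxime/Sulbactam,anaphylactoid reaction,true
3rd,Cefotaxime/Sulbactam,face oedema,true
3rd,Cefotaxime/Sulbactam,oedema,true
3rd,Cefotaxime/Sulbactam,eye abnormality,true
3rd,Cefotaxime/Sulbactam,rash,false
3rd,Cefotaxime/Sulbactam,pruritus,false
3rd,Ceftriaxone/Tazobactam,coughing,true
3rd,Ceftriaxone/Tazobactam,eye abnormality,true
3rd,Ceftriaxone/Tazobactam,rash,false
3rd,Ceftriaxone/Tazobactam,pruritus,false
3rd,Ceftriaxone/Tazobactam,urticaria,false
3rd,Cefodizime,rash,false
3rd,Cefodizime,pruritus,false
3rd,Cefodizime,rash maculo-papular,false
3rd,Cefodizime,allergic reaction,false
3rd,Cefmenoxime,rash maculo-papular,true
3rd,Cefmenoxime,rash erythematous,false
3rd,Cefmenoxime,allergic reaction,false
3rd,Cefoperazone,rash,false
3rd,Cefoperazone,rash erythematous,true
3rd,Cefoperazone,diarrhoea,false
3rd,Cefpiramide,rash,false
3rd,Cefpiramide,allergic reaction,false
3rd,Cefdinir,rash,false
3rd,Cefdinir,diarrhoea,false
4th,Cefepime,diarrhoea,false
4th,Cefepime,allergic reaction,false
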