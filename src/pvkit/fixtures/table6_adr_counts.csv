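adr,n
rash,7482
pruritus,3919
allergic reaction,3293
urticaria,1160
vomiting,703
nausea,390
flushing,333
maculo-papular rash,329
abdominal pain,287
diarrhoea,284
dyspnoea,195
coughing,182
erythematous rash,171
face oedema,142
fever,142
rigors,109
anaphylactoid reaction,108
cyanosis,108
dizziness,103
palpitation,101
dermatitis,101
agitation,86
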