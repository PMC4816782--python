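fve_name,markov_names
V1,V1
V2,V2
V3,V3
V3a,V3a
V4,V4
V4t,V4t
VP,V3
MT,MT
LIP,LIP
MIP,MIP
VIP,VIP
PIP,PIP
PO,V6|V6a
MSTd,MSTl|MSTd
MSTl,MSTl|MSTd
PITv,TEO
PITd,TEOm
CITv,TEpd
CITd,TEpd
AITv,TEav
AITd,TEad
VOT,
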