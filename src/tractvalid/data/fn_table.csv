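region_a,region_b,list,confident,markov_status
V1,V4t,apparent_fn,true,weak
V3,MT,apparent_fn,true,strong
V3,V4t,apparent_fn,true,untested
VOT,V3a,apparent_fn,false,untested
V4t,AITd,apparent_fn,false,untested
V4t,AITv,apparent_fn,false,untested
V4t,CITd,apparent_fn,false,weak
V3,LIP,apparent_fn,true,untested
V3a,LIP,apparent_fn,true,untested
VP,LIP,apparent_fn,true,untested
V2,MSTi,apparent_fn,true,strong
V3a,MSTi,apparent_fn,true,untested
VP,PIP,apparent_fn,true,untested
MT,PO,apparent_fn,true,absent
V4t,PO,apparent_fn,true,untested
VP,PO,apparent_fn,true,untested
VP,VIP,apparent_fn,true,untested
V4t,LIP,apparent_fn,false,untested
V4t,MIP,apparent_fn,false,untested
V4t,PIP,apparent_fn,false,untested
V4t,VIP,apparent_fn,false,untested
VOT,MIP,apparent_fn,false,untested
VOT,LIP,apparent_fn,false,untested
VOT,PIP,apparent_fn,false,untested
VOT,VIP,apparent_fn,false,untested
VOT,PO,apparent_fn,false,untested
PITv,AITd,apparent_fn,true,strong
PITv,LIP,apparent_fn,true,strong
CITd,MIP,apparent_fn,false,absent
MSTi,LIP,apparent_fn,true,untested
PO,LIP,apparent_fn,true,untested
PO,MSTd,apparent_fn,true,untested
PO,MSTi,apparent_fn,true,untested
VIP,MSTi,apparent_fn,true,untested
MSTi,MIP,apparent_fn,false,untested
PITd,MIP,apparent_fn,false,untested
PITv,MIP,apparent_fn,false,weak
PITv,MSTd,apparent_fn,false,strong
PIP,MSTd,apparent_fn,false,untested
PIP,MSTi,apparent_fn,false,untested
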