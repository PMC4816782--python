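region_a,region_b,list,confident,markov_status
V1,VP,apparent_fp,true,strong
V2,PITv,apparent_fp,true,weak
VP,PITv,apparent_fp,true,strong
MT,PITd,apparent_fp,true,strong
V4t,PITd,apparent_fp,false,untested
VOT,CITv,apparent_fp,false,untested
V2,MIP,apparent_fp,true,absent
V3,MIP,apparent_fp,true,untested
V4,MSTi,apparent_fp,true,weak
AITv,AITd,apparent_fp,false,untested
CITv,CITd,apparent_fp,false,strong
PITd,CITd,apparent_fp,false,strong
PITd,PITv,apparent_fp,false,strong
PITd,MSTi,apparent_fp,true,untested
PIP,LIP,apparent_fp,false,untested
PIP,VIP,apparent_fp,false,untested
PIP,MIP,apparent_fp,false,untested
VIP,MIP,apparent_fp,false,untested
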