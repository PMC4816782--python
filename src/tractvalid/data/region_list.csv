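name,description
AITd,"anterior inferotemporal, dorsal"
AITv,"anterior inferotemporal, ventral"
CITd,"central inferotemporal, dorsal"
CITv,"central inferotemporal, ventral"
LIP,lateral intraparietal
MIP,medial intraparietal
MSTd,"medial superior temporal, dorsal"
MSTl,"medial superior temporal, lateral"
MT,middle temporal
PIP,posterior intraparietal
PITd,"posterior inferotemporal, dorsal"
PITv,"posterior inferotemporal, ventral"
PO,parieto-occipital
V1,visual area 1
V2,visual area 2
V3,visual area 3
V3a,visual area V3a
V4,visual area 4
V4t,V4 transitional
VIP,ventral intraparietal
VOT,ventral occipitotemporal
VP,ventral posterior
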