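element	region	limb_portion	is_long_bone	paired
horn	cranial	n/a	0	1
cranium	cranial	n/a	0	0
mandible	cranial	n/a	0	1
tooth	cranial	n/a	0	0
vertebra	axial	n/a	0	0
rib	axial	n/a	0	0
pelvis	axial	posterior	0	1
scapula	axial	anterior	0	1
humerus	upper appendicular	anterior	1	1
femur	upper appendicular	posterior	1	1
radius	intermediate appendicular	anterior	1	1
ulna	intermediate appendicular	anterior	1	1
tibia	intermediate appendicular	posterior	1	1
patella	intermediate appendicular	posterior	0	1
metacarpal	lower appendicular	anterior	1	1
metatarsal	lower appendicular	posterior	1	1
metapodial	lower appendicular	n/a	1	0
carpal	lower appendicular	anterior	0	1
tarsal	lower appendicular	posterior	0	1
calcaneus	lower appendicular	posterior	0	1
astragalus	lower appendicular	posterior	0	1
phalanx	lower appendicular	n/a	0	0
sesamoid	lower appendicular	n/a	0	0
long_bone	unclassified	n/a	1	0
indeterminate	unclassified	n/a	0	0
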