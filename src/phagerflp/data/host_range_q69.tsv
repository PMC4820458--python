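strain	origin	susceptible
CECT481T	type_strain	true
15a	dairy	false
18a	dairy	true
19a	dairy	true
23a	dairy	true
28a	dairy	false
52c	dairy	true
54c	dairy	false
57c	dairy	true
63c	dairy	true
CECT4039	dairy	false
BA62	dairy	false
BA64	dairy	false
V61	dairy	false
V63	dairy	false
LMG20645	meat	false
LMG12161	meat	false
CECT795	human	true
CECT4176	human	false
HFS25	human	false
HFS57	human	true
HFS59	human	true
HFS62	human	false
HFS66	human	false
HFS69	human	false
JH2-2	clinical	false
V583	clinical	false
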