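#name=dTCT anchor_offset=2 cutoff=0 category=initiator window=-5:2
#citation=Parry et al. 2010 (Drosophila)
pos	1	2	3	4	5	6	7	8
A	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
C	0.450000	0.450000	0.850000	0.050000	0.050000	0.050000	0.450000	0.450000
G	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
T	0.450000	0.450000	0.050000	0.850000	0.850000	0.850000	0.450000	0.450000
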