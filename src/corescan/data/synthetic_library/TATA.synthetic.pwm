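#name=TATA anchor_offset=0 cutoff=0.9 category=upstream window=-33:-23
#citation=Bucher 1990 (J Mol Biol 212:563)
pos	1	2	3	4	5	6	7	8
A	0.050000	0.850000	0.050000	0.850000	0.450000	0.850000	0.850000	0.450000
C	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
G	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.450000
T	0.850000	0.050000	0.850000	0.050000	0.450000	0.050000	0.050000	0.050000
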