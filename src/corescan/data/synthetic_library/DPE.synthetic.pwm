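#name=DPE anchor_offset=0 cutoff=0 category=downstream window=26:34
#citation=Burke & Kadonaga 1996; Kutach & Kadonaga 2000
pos	1	2	3	4	5	6
A	0.450000	0.050000	0.450000	0.050000	0.300000	0.050000
C	0.050000	0.050000	0.050000	0.450000	0.300000	0.050000
G	0.450000	0.850000	0.050000	0.050000	0.300000	0.050000
T	0.050000	0.050000	0.450000	0.450000	0.100000	0.850000
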