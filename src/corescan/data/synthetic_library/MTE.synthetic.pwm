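#name=MTE anchor_offset=0 cutoff=0.8 category=downstream window=16:24
#citation=Lim et al. 2004
pos	1	2	3	4	5	6	7	8	9	10	11	12
A	0.050000	0.050000	0.850000	0.450000	0.050000	0.050000	0.050000	0.850000	0.850000	0.050000	0.050000	0.050000
C	0.850000	0.450000	0.050000	0.050000	0.850000	0.450000	0.450000	0.050000	0.050000	0.850000	0.050000	0.450000
G	0.050000	0.450000	0.050000	0.450000	0.050000	0.450000	0.450000	0.050000	0.050000	0.050000	0.850000	0.450000
T	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
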