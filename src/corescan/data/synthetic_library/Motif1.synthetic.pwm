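#name=Motif1 anchor_offset=0 cutoff=1.2 category=pausing window=-12:4
#citation=Ohler et al. 2002 motif 1; Li & Gilmour 2013 (M1BP)
pos	1	2	3	4	5	6	7	8	9	10	11
A	0.050000	0.050000	0.050000	0.050000	0.050000	0.850000	0.050000	0.850000	0.050000	0.050000	0.450000
C	0.450000	0.050000	0.050000	0.050000	0.850000	0.050000	0.850000	0.050000	0.850000	0.050000	0.050000
G	0.050000	0.850000	0.850000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.450000
T	0.450000	0.050000	0.050000	0.850000	0.050000	0.050000	0.050000	0.050000	0.050000	0.850000	0.050000
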