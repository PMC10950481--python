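#name=BREu anchor_offset=0 cutoff=1.4 category=upstream window=-40:-30
#citation=Lagrange et al. 1998
pos	1	2	3	4	5	6	7
A	0.050000	0.050000	0.450000	0.050000	0.050000	0.050000	0.050000
C	0.450000	0.450000	0.050000	0.850000	0.050000	0.850000	0.850000
G	0.450000	0.450000	0.450000	0.050000	0.850000	0.050000	0.050000
T	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
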