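#name=BREd anchor_offset=0 cutoff=-0.1 category=upstream window=-26:-16
#citation=Deng & Roberts 2005
pos	1	2	3	4	5	6	7
A	0.450000	0.050000	0.300000	0.050000	0.050000	0.050000	0.050000
C	0.050000	0.050000	0.100000	0.050000	0.050000	0.050000	0.050000
G	0.450000	0.050000	0.300000	0.450000	0.450000	0.450000	0.450000
T	0.050000	0.850000	0.300000	0.450000	0.450000	0.450000	0.450000
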