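#name=Bridge anchor_offset=0 cutoff=0.4 category=downstream window=16:22
#citation=Theisen et al. 2010 (MTE/DPE bridge)
pos	1	2	3	4	5	6	7	8	9	10	11	12	13	14	15	16
A	0.050000	0.050000	0.850000	0.450000	0.050000	0.250000	0.250000	0.250000	0.250000	0.250000	0.450000	0.050000	0.450000	0.050000	0.300000	0.050000
C	0.850000	0.450000	0.050000	0.050000	0.850000	0.250000	0.250000	0.250000	0.250000	0.250000	0.050000	0.050000	0.050000	0.450000	0.300000	0.050000
G	0.050000	0.450000	0.050000	0.450000	0.050000	0.250000	0.250000	0.250000	0.250000	0.250000	0.450000	0.850000	0.050000	0.050000	0.300000	0.050000
T	0.050000	0.050000	0.050000	0.050000	0.050000	0.250000	0.250000	0.250000	0.250000	0.250000	0.050000	0.050000	0.450000	0.450000	0.100000	0.850000
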