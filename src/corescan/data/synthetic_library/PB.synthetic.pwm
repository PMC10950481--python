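#name=PB anchor_offset=0 cutoff=1.4 category=pausing window=18:34
#citation=Hendrix et al. 2008 (pause button)
pos	1	2	3	4	5	6	7
A	0.050000	0.050000	0.050000	0.450000	0.450000	0.050000	0.050000
C	0.050000	0.850000	0.050000	0.050000	0.050000	0.850000	0.050000
G	0.450000	0.050000	0.850000	0.450000	0.050000	0.050000	0.850000
T	0.450000	0.050000	0.050000	0.050000	0.450000	0.050000	0.050000
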