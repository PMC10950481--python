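#name=BBCA+1BW anchor_offset=3 cutoff=1 category=initiator window=-6:1
#citation=Vo ngoc et al. 2017 (human Inr consensus)
pos	1	2	3	4	5	6
A	0.100000	0.100000	0.050000	0.850000	0.100000	0.450000
C	0.300000	0.300000	0.850000	0.050000	0.300000	0.050000
G	0.300000	0.300000	0.050000	0.050000	0.300000	0.050000
T	0.300000	0.300000	0.050000	0.050000	0.300000	0.450000
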