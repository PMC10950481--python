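#name=dInr anchor_offset=2 cutoff=1.5 category=initiator window=-5:2
#citation=Hultmark et al. 1986; Purnell et al. 1994
pos	1	2	3	4	5	6
A	0.050000	0.050000	0.850000	0.050000	0.050000	0.050000
C	0.050000	0.850000	0.050000	0.050000	0.050000	0.450000
G	0.050000	0.050000	0.050000	0.850000	0.050000	0.050000
T	0.850000	0.050000	0.050000	0.050000	0.850000	0.450000
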