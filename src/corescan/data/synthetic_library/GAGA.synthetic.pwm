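#name=GAGA anchor_offset=0 cutoff=0.1 category=pausing
#citation=GAGA factor binding site, after CIS-BP M5247 v1.02
pos	1	2	3	4	5	6	7
A	0.050000	0.850000	0.050000	0.850000	0.050000	0.850000	0.050000
C	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
G	0.850000	0.050000	0.850000	0.050000	0.850000	0.050000	0.850000
T	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000	0.050000
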