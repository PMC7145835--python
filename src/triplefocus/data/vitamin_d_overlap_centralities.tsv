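gene	degree_centrality	betweenness_centrality
CACNA1C	0.0461	0.0245
COMT	0.0454	0.0125
NOTCH4	0.020	0.0072
DRD3	0.0482	0.0043
CD36	0.022	0.0024
EGR1	0.0619	0.0022
CCL2	0.0867	0.0018
DLX5	0.0062	0.0010
CYP1A1	0.0227	0.0008
A2M	0.0358	0.0006
VDR	0.0282	0.0006
TGFB2	0.0296	0.0006
TIMP3	0.0268	0.0006
CD14	0.0227	0.0006
CYP19A1	0.0296	0.0004
NME1	0.0227	0.0003
HSD11B1	0.0131	0.0002
MMP12	0.0227	0.0002
AMBRA1	0.0055	0.0002
ALOX15	0.0117	0.0001
GIG25	0.0145	0.0001
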