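gene	z
GSTT1	4.556
ENTPD6	3.931
KMO	3.67
GRIA4	3.312
PTPN11	3.097
ADORA2A	2.88
TACR1	2.879
ATP2B3	2.816
DDC	2.768
SYNJ2	2.762
PLCG1	2.643
PDE4D	2.62
NFE2L2	2.596
SORT1	2.497
C1GALT1	2.463
PNLIP	2.361
ALAS1	2.271
CDK4	2.254
CYCTP	2.215
PFKFB2	2.21
GAB2	2.144
CAMK4	2.128
HAL	2.11
CACNA1E	2.107
CYP7A1	2.019
GLS	-2.017
PLA2G2A	-2.018
SARDH	-2.032
PRKCH	-2.049
SMARCD2	-2.083
ATP1A2	-2.133
SHH	-2.137
GABRR1	-2.139
FZD9	-2.141
ACADM	-2.2
TRH	-2.206
RALA	-2.215
AP2S1	-2.235
CHRNE	-2.236
ADORA1	-2.301
PRKCZ	-2.307
RASGRP4	-2.314
NPPB	-2.337
PAH	-2.349
PLCB4	-2.352
EDN2	-2.412
RPS6KB1	-2.473
FGF10	-2.551
PDE7A	-2.689
PDE1C	-2.772
ODC1	-2.864
XDH	-2.948
RLN1	-3.042
MVD	-3.1
GRPR	-3.15
HMBS	-3.406
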