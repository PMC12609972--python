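# Partly synthetic reconstruction of a curated cisplatin literature database.
# Rows with provenance "reported" carry labels stated in published comparative
# analyses of cisplatin-regulated brain genes; rows with provenance
# "synthetic-fill" pad the stably-expressed (SEG) category to its reported
# size of 12 with common housekeeping symbols and are NOT literature claims.
# CDK4 is deliberately absent: it is reported with context-dependent
# direction and this table allows one label per symbol.
symbol	label	provenance
PRKCZ	UP	reported
GRPR	UP	reported
PLA2G2A	UP	reported
PLCB4	UP	reported
SARDH	UP	reported
GABRR1	UP	reported
CAMK4	UP	reported
FANCC	UP	reported
GRIA4	UP	reported
HOXA5	DOWN	reported
NFE2L2	DOWN	reported
ABCC2	DOWN	reported
UBB	SEG	reported
BCL2	SEG	reported
FAS	SEG	reported
ACTB	SEG	synthetic-fill
GAPDH	SEG	synthetic-fill
TUBB5	SEG	synthetic-fill
RPL13A	SEG	synthetic-fill
PPIA	SEG	synthetic-fill
PGK1	SEG	synthetic-fill
HPRT1	SEG	synthetic-fill
SDHA	SEG	synthetic-fill
YWHAZ	SEG	synthetic-fill
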