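# Minimal offline alias -> canonical symbol table (NCBI Gene conventions).
alias	canonical
NRF2	NFE2L2
NFEL2	NFE2L2
P53	TP53
HSP27	HSPB1
CY5	CYCTP
GLUR4	GRIA4
PKCZ	PRKCZ
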