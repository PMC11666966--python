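# Published top-10 hub list under maximum neighborhood component (HGNC symbols).
AKT1
TNF
TP53
IL6
SRC
EGFR
IL1B
ESR1
CASP3
JUN
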