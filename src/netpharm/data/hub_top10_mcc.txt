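# Published top-10 hub list under maximal clique centrality (HGNC symbols).
IL6
AKT1
JUN
BCL2
CASP3
TNF
TP53
PTGS2
HIF1A
IFNG
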