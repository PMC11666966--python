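# Published per-target best docking energies (AutoDock Vina, kcal/mol)
# between central targets and their best-binding screened compounds.
# IL6 has a reported two-way tie at -6.5 kcal/mol.
compound	target	energy
Tamarixetin	IL6	−6.5
Naringenin	IL6	−6.5
Quercetin	AKT1	−8.7
Patuletin	JUN	−7.9
Naringenin	CASP3	−7.2
Quercetin	TNF	−6.3
Luteolin	TP53	−7.0
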