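# Published 24-compound ADME-screened panel of Hemerocallis citrina edible flower.
# Columns: PubChem CID, compound name, oral bioavailability (%), drug-likeness,
# number of predicted depression-relevant targets.
pubchem_id	name	ob	dl	target_count
439533	Taxifolin	57.84	0.27	40
5280863	Kaempferol	41.88	0.24	180
5280445	Luteolin	36.16	0.25	173
440735	Eriodictyol	71.79	0.24	102
5281670	Morin	46.23	0.27	146
5280343	Quercetin	46.43	0.28	230
5489605	Demethylwedelolactone	72.13	0.43	99
5379033	Dehydrodiisoeugenol	56.84	0.29	201
5280544	Herbacetin	36.07	0.27	140
72281	Hesperetin	70.31	0.27	116
439246	Naringenin	59.29	0.21	136
5281654	Isorhamnetin	49.6	0.31	169
5281612	Diosmetin	31.14	0.27	146
9945785	3-p-Coumaroylquinic acid	37.63	0.29	52
25175592	3-O-Feruloylquinic acid	25.51	0.36	106
64971	Betulinic acid	55.38	0.78	59
6474640	Cynarine	31.76	0.68	47
28125525	Butin	69.94	0.21	112
5281628	Hispidulin	30.97	0.27	142
5281699	Tamarixetin	32.86	0.31	149
5281678	Patuletin	53.11	0.34	139
72344	Nobiletin	61.67	0.52	73
67128659	Luteolin-4'-O-glucoside	35.94	0.79	77
5351516	Ergosterol peroxide	42.84	0.74	51
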