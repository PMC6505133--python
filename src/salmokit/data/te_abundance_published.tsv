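# Published transposable-element classification and abundances for the
# European grayling and Atlantic salmon chromosome-level genome assemblies.
# bp = RepeatMasker-annotated base pairs; pct = percent of assembly length.
# The final class "Unknown" row holds unclassified repeats (neither class I
# nor class II).
te_class	order	superfamily	grayling_bp	grayling_pct	salmon_bp	salmon_pct
I	LINE	Jockey	133311368	9.0	228445871	10.2
I	LINE	RTE	10629973	0.7	12021858	0.5
I	LINE	L1	6987652	0.5	15019466	0.7
I	LINE	I	1925092	0.1	2994056	0.1
I	LTR	Gypsy	88958008	6.0	120880877	5.4
I	LTR	ERV	23336303	1.6	29951691	1.3
I	LTR	Bel-Pao	4559403	0.3	5228163	0.2
I	LTR	Copia	1009467	0.1	3887925	0.2
I	SINE	tRNA	6099534	0.4	12208774	0.5
I	SINE	Unknown	439123	0.0	1325090	0.1
I	DIRS	DIRS	6352447	0.4	13786775	0.6
I	PLE	Penelope	1392065	0.1	1728304	0.1
I	Unknown	Unknown	102556	0.0	157518	0.0
II	TIR	Tc1-Mariner	143125085	9.6	226246051	10.1
II	TIR	hAT	18745228	1.3	26354108	1.2
II	TIR	CACTA	1063048	0.1	1575430	0.1
II	TIR	PIF-Harbinger	606932	0.0	788870	0.0
II	TIR	PiggyBac	237022	0.0	555705	0.0
II	TIR	Unknown	5627491	0.4	90211317	4.0
II	TIR	Sola	148327	0.0	373468	0.0
II	TIR	Ginger1	59568	0.0	66177	0.0
II	TIR	ISL2EU	37185	0.0	0	0.0
II	Crypton	Crypton	1763736	0.1	2838181	0.1
II	Maverick	Maverick	4732	0.0	147407	0.0
Unknown	Unknown	Unknown	247405186	16.7	374107217	16.7
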