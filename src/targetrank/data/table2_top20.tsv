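gene_id	annotation	n_isoforms	family	tissue_expression	drug_score	essential	chembl_hit	lead_compound	expected_total	expected_rank
XLOC_015532	FGFR2	2	kinase	L,B,K	4.22	1	1	1	4.62	1
XLOC_082803	PPARA	2	nuclear_receptor	H,L,K	4.12	1	1	1	4.52	2
XLOC_015530	FGFR2	6	kinase	B,K	4.20	1	1	1	4.50	3
XLOC_087227	FLT1	2	kinase	H,L,K	4.08	1	1	1	4.48	4
XLOC_014821	VEGFR2	7	kinase	H,L,K	4.08	1	1	1	4.48	5
XLOC_017786	NR3C1	4	nuclear_receptor	H,L,K	4.07	1	1	1	4.47	6
XLOC_015794	I79_002622	2	kinase	B	4.25	1	1	1	4.45	7
XLOC_080516	IGF1R	1	kinase	P	4.25	1	1	1	4.45	8
XLOC_055323	FYN	6	kinase	B	4.24	1	1	1	4.44	9
XLOC_084356	ADRA1B	4	gpcr	K	4.23	1	1	1	4.43	10
XLOC_067939	EGM_10463	2	other	K	4.21	1	1	1	4.41	11
XLOC_018597	CHRM2	2	gpcr	H	4.20	1	1	1	4.40	12
XLOC_033229	MME	3	protease	L,K,T	4.09	0	1	1	4.39	13
XLOC_076965	ADRB1	1	gpcr	H	4.19	1	1	1	4.39	14
XLOC_039195	YES	4	kinase	L,K	4.08	1	1	1	4.38	15
XLOC_021221	SSTR2	2	gpcr	B	4.15	1	1	1	4.35	16
XLOC_051598	ARRAY	3	other	B	4.15	1	1	1	4.35	17
XLOC_050569	LOC100385676	3	other		4.23	1	1	1	4.33	18
XLOC_001891	GRIK2	4	ion_channel	B	4.13	1	1	1	4.33	19
XLOC_075660	CASR	2	gpcr	K	4.13	1	1	1	4.33	20
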