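gene_id	species	chromosome	position	intron_count	pI	mw	signal_peptide	signal_peptide_length	domain_coverage	pattern4	n_amino_acids
FvH4_4g31300.1	F. vesca	Chr4	30502482	7	5.38	102.0	N	—	>60%	CPSSNG	916
FvH4_4g31290.1	F. vesca	Chr4	30499449	3	5.23	25.7	Y	23	>60%	CPSSNG	229
FvH4_2g17310.1	F. vesca	Chr2	14946893	7	8.17	27.6	Y	28	>60%	—	245
FvH4_5g24800.1	F. vesca	Chr5	16134164	3	9.37	26.6	Y	26	>60%	—	239
FvH4_1g10040.1	F. vesca	Chr1	5448902	1	8.08	26.0	Y	19	>60%	—	230
FvH4_6g07740.1	F. vesca	Chr6	4649328	1	6.21	25.2	Y	21	>60%	—	220
FvH4_6g07690.1	F. vesca	Chr6	4634036	1	6.28	26.2	Y	15	>60%	—	226
FvH4_5g33850.1	F. vesca	Chr5	24565949	1	8.07	31.3	Y	43	>60%	—	270
FvH4_1g19170.1	F. vesca	Chr1	11366424	1	8.95	22.7	Y	23	>60%	—	198
FvH4_4g18130.1	F. vesca	Chr4	22047584	1	8.09	27.7	Y	19	>60%	—	241
FvH4_2g25650.1	F. vesca	Chr2	20739797	3	9.39	25.6	N	—	<60%	—	223
FvH4_6g22290.1	F. vesca	Chr6	15948673	1	7.66	27.4	Y	17	<60%	—	238
FvH4_2g25620.1	F. vesca	Chr2	20733334	2	9.81	15.5	Y	20	<60%	—	133
FvH4_5g24550.1	F. vesca	Chr5	15908338	2	8.55	12.3	Y	26	<60%	—	109
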