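gene_id	species	chromosome	position	intron_count	pI	mw	signal_peptide	signal_peptide_length	domain_coverage	pattern4	n_amino_acids
Unigene18150.1	F. viridis	Chr4	30504261	2	4.58	25.2	Y	27	>60%	CPSSSG	231
Unigene13465.1	F. viridis	Chr4	30500729	3	5.35	25.8	Y	23	>60%	CPSSNG	229
Unigene11523.1	F. viridis	Chr2	14950589	6	5.76	30.5	Y	29	>60%	—	278
Unigene23139.1	F. viridis	Chr6	5067585	1	8.53	26.2	Y	26	>60%	—	228
CL6424.Contig1.1	F. viridis	Chr1	5449834	1	8.57	25.8	Y	19	>60%	—	229
Unigene10929.1	F. viridis	—	—	2	8.68	25.2	Y	23	>60%	—	218
Unigene7320.1	F. viridis	—	—	2	8.55	25.6	Y	24	>60%	—	221
Unigene9248.2	F. viridis	Chr5	24566583	0	5.47	12.4	N	—	<60%	—	104
Unigene638.1	F. viridis	Chr6	4649354	1	5.26	12.4	Y	19	<60%	—	109
Unigene31475.1	F. viridis	Chr6	4634931	1	6.88	8.8	N	—	<60%	—	79
Unigene23536.2	F. viridis	Chr1	4771772	0	6.52	5.6	N	—	<60%	—	50
Unigene27236.1	F. viridis	Chr2	14949271	0	5.86	9.1	N	—	<60%	—	79
CL6424.Contig2.2	F. viridis	Chr1	5449478	1	8.94	8.5	N	—	<60%	—	75
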