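# Pairwise percent identity among intron-filter survivors.
# The two F. viridis values 56.48 and 30.88 are measured; every other
# entry is a synthetic placeholder standing in for unpublished values,
# chosen below the 30% window floor as reported qualitatively
# ("very low, <30%").
id_a	id_b	identity
Unigene10929.1	Unigene7320.1	56.48
Unigene23139.1	Unigene7320.1	30.88
Unigene23139.1	Unigene10929.1	24.5
Unigene23139.1	CL6424.Contig1.1	22.1
CL6424.Contig1.1	Unigene10929.1	25.7
CL6424.Contig1.1	Unigene7320.1	23.9
FvH4_1g10040.1	FvH4_5g33850.1	26.4
FvH4_1g10040.1	FvH4_1g19170.1	24.8
FvH4_1g10040.1	FvH4_4g18130.1	22.9
FvH4_5g33850.1	FvH4_1g19170.1	21.6
FvH4_5g33850.1	FvH4_4g18130.1	25.1
FvH4_1g19170.1	FvH4_4g18130.1	23.3
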