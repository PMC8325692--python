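# F. vesca chromosome-6 blocks collinear with the S-locus regions of
# two rose genomes and the almond genome.
source_genome	source_chrom	source_start	source_end	target_chrom	target_start	target_end
Rosa_v1	3	38160380	43142292	Chr6	2792689	6206471
Rosa_v2	3	3037968	7988569	Chr6	2072839	5489398
Prunus_v2	6	24640828	29556668	Chr6	3802	7052976
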