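# Synthetic cross-tribe reference identities for the within-genus >
# cross-tribe allele-pairing rule.  The reference stands in for an
# Amygdaleae (Prunus-type) S-RNase; the values are placeholders shaped
# so the qualitative outcome holds: candidate identities to cross-tribe
# S-RNases exceed the 30.88% within-genus value of the rejected pair
# but stay below the 56.48% of the accepted allele pair.
id_a	id_b	identity
Unigene10929.1	crosstribe_SRNase_ref	42.0
Unigene7320.1	crosstribe_SRNase_ref	40.0
Unigene23139.1	crosstribe_SRNase_ref	38.0
CL6424.Contig1.1	crosstribe_SRNase_ref	35.0
FvH4_1g10040.1	crosstribe_SRNase_ref	36.0
FvH4_5g33850.1	crosstribe_SRNase_ref	34.0
FvH4_1g19170.1	crosstribe_SRNase_ref	35.5
FvH4_4g18130.1	crosstribe_SRNase_ref	33.0
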