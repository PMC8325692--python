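line_id	genotype
S0	SaSb
S1-01	SbSb
S1-02	SaSb
S1-03	SbSb
S1-04	SaSb
S1-05	SaSa
S1-02-S2-02	SaSb
S1-02-S2-11	SaSa
S1-02-S2-28	SbSb
S1-02-S2-30	SaSb
S1-02-S2-35	SbSb
S1-02-S2-37	SbSb
S1-02-S2-49	SaSa
S1-02-S2-53	SaSb
S1-02-S2-57	SbSb
S1-02-S2-61	SbSb
S1-02-S2-63	SaSb
S1-02-S2-76	SaSb
S1-03-S2-01	SbSb
S1-05-S2-02	SaSa
S1-02-S2-11-S3-06	SaSa
S1-02-S2-30-S3-03	SbSb
S1-02-S2-30-S3-05	SbSb
S1-02-S2-30-S3-09	SaSa
S1-02-S2-37-S3-01	SbSb
S1-02-S2-76-S3-01	SbSb
S1-02-S2-76-S3-02	SaSb
S1-02-S2-76-S3-09	SaSb
S1-02-S2-76-S3-11	SbSb
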