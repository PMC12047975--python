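gene	coding_variant	gwas_hf	gwas_cvd	cis_regulated	deg	functional_relevance	expression_tpm	mr_significant
Mycbp2	0	0	1	0	0	1	2.79	0
Abcc4	1	0	1	0	1	0	3.39	0
Slain1	1	0	0	0	0	0	0.14	1
Ednrb	1	0	0	0	1	0	3.75	0
Gpc6	0	0	0	0	0	0	3.10	1
Tgds	0	0	0	0	0	1	2.29	0
Gpr180	0	0	0	1	1	0	4.95	0
Uggt2	1	0	0	0	0	0	1.40	1
Mbnl2	0	0	0	0	0	0	5.18	1
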