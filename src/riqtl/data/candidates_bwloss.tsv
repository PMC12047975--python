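gene	coding_variant	gwas_hf	gwas_cvd	cis_regulated	deg	functional_relevance	expression_tpm	mr_significant
Hspa12a	1	1	1	1	0	0	3.35	1
Rbm20	1	0	1	0	1	1	6.92	0
Adrb1	0	0	1	0	1	1	4.32	0
Pdzd8	0	0	1	0	1	0	3.62	1
Pdcd4	0	0	0	0	1	1	4.49	0
Shoc2	0	0	0	0	1	1	3.57	0
Afap1l2	1	0	1	0	0	1	1.86	0
Ablim1	1	0	0	1	1	0	6.88	0
Slc18a2	1	0	0	1	0	0	1.26	1
Add3	0	0	0	0	0	0	4.94	1
Dusp5	0	0	0	0	0	0	2.89	1
Bbip1	0	0	0	0	0	1	3.59	0
Adra2a	0	0	1	0	0	1	0.06	0
Acsl5	0	0	0	1	0	1	1.62	0
Vti1a	0	0	1	0	1	0	2.76	0
Tcf7l2	0	1	1	0	0	0	3.23	0
Nrap	1	0	1	0	0	0	8.40	0
Casp7	0	0	0	0	0	0	3.68	1
Nhlrc2	0	0	1	1	0	0	3.83	0
Gfra1	1	0	1	0	0	0	2.63	0
Pnliprp2	1	0	1	1	0	0	0.01	0
Rab11fip2	0	0	0	1	1	0	2.30	0
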