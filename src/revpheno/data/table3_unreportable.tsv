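research_id	sex	recruitment_category	gene	zygosity	consequence	hgvs_c	hgvs_p	gnomad_af	cohort_maf	sift	polyphen	cadd	clinvar	segregation	n_major	n_minor
52	unknown	Intellectual disability	ALMS1	het	missense_variant	NM_015120.4:c.7738A>T	NP_055935.4:p.Ile2580Phe	4.01E-06	0.00009997	deleterious	benign	22.5	absent	maternal	0	2
52	unknown	Intellectual disability	ALMS1	het	missense_variant	NM_015120.4:c.346C>T	NP_055935.4:p.His116Tyr	2.41E-05	0.00019994	deleterious	benign	16.05	absent	paternal	0	2
59	unknown	Hereditary spastic paraplegia	BBS1	het	missense_variant	NM_024649.5:c.235G>A	NP_078925.3:p.Glu79Lys	0.000756	0.00120728	deleterious	possibly_damaging	23.8	vus	unknown	0	0
59	unknown	Hereditary spastic paraplegia	BBS1	het	missense_variant	NM_024649.5:c.1714G>T	NP_078925.3:p.Gly572Cys	.	1.27E-05	deleterious	probably_damaging	32	absent	unknown	0	0
60	unknown	Primary immunodeficiency	CEP290	het	frameshift_variant	NM_025114.4:c.6154_6161del	NP_079390.3:p.Asp2052LeufsTer17	0	1.27E-05	.	.	.	absent	unknown	0	0
60	unknown	Primary immunodeficiency	CEP290	het	frameshift_variant	NM_025114.4:c.7412_7415del	NP_079390.3:p.Glu2471ValfsTer13	0	1.91E-05	.	.	.	absent	unknown	0	0
61	unknown	Primary lymphoedema	CEP290	het	stop_gained	NM_025114.4:c.7048C>T	NP_079390.3:p.Gln2350Ter	1.90E-05	1.91E-05	.	.	.	likely_pathogenic	unknown	0	0
61	unknown	Primary lymphoedema	CEP290	het	missense_variant	NM_025114.4:c.4063C>T	NP_079390.3:p.Arg1355Cys	4.97E-05	9.53E-05	deleterious	probably_damaging	32	vus	unknown	0	0
64	unknown	Limb-girdle muscular dystrophy	CEP290	hom	missense_variant	NM_025114.4:c.4805C>T	NP_079390.3:p.Thr1602Met	0.000226	0.00027958	deleterious	possibly_damaging	27.7	conflicting	unknown	0	0
65	unknown	Undiagnosed monogenic disorders	CEP290	het	missense_variant	NM_025114.4:c.5909C>A	NP_079390.3:p.Thr1970Asn	0	1.27E-05	deleterious	probably_damaging	25.6	absent	unknown	0	0
65	unknown	Undiagnosed monogenic disorders	CEP290	het	frameshift_variant	NM_025114.4:c.7283_7286dup	NP_079390.3:p.Tyr2429Ter	2.11E-05	2.54E-05	.	.	.	absent	unknown	0	0
68	unknown	Early onset dementia	CEP290	het	missense_variant	NM_025114.4:c.31A>G	NP_079390.3:p.Met11Val	7.72E-05	6.35E-06	deleterious	benign	23.2	vus	unknown	0	0
68	unknown	Early onset dementia	CEP290	het	missense_variant	NM_025114.4:c.2447G>A	NP_079390.3:p.Arg816His	3.13E-05	6.35E-05	deleterious	probably_damaging	26.4	vus	unknown	0	0
69	unknown	Epilepsy plus other features	CEP290	het	missense_variant	NM_025114.4:c.2446C>T	NP_079390.3:p.Arg816Cys	5.00E-05	2.54E-05	deleterious	probably_damaging	32	vus	unknown	0	0
69	unknown	Epilepsy plus other features	CEP290	het	missense_variant	NM_025114.4:c.4741C>T	NP_079390.3:p.Leu1581Phe	1.32E-05	1.27E-05	deleterious	possibly_damaging	25.1	vus	unknown	0	0
71	unknown	Hereditary ataxia	DYNC2H1	het	missense_variant	NM_001377.3:c.10142C>T	NP_001368.2:p.Pro3381Leu	3.62E-05	1.00E-04	deleterious	probably_damaging	31	conflicting	unknown	0	0
71	unknown	Hereditary ataxia	DYNC2H1	het	missense_variant	NM_001377.3:c.3419G>T	NP_001368.2:p.Gly1140Val	0.0003938	0.00044987	deleterious	benign	23.2	vus	unknown	0	0
72	female	Early onset dementia	OFD1	het	splice_acceptor_variant	NM_003611.3:c.936-1G>A	.	0	6.35E-06	.	.	.	absent	unknown	0	0
73	female	Early onset dystonia	OFD1	het	frameshift_variant	NM_003611.3:c.1911del	NP_003602.1:p.Glu637AspfsTer29	0	6.35E-06	.	.	.	absent	unknown	0	0
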