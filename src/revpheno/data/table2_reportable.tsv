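research_id	printed_confidence	sex	recruitment_category	gene	zygosity	consequence	hgvs_c	hgvs_p	gnomad_af	cohort_maf	sift	polyphen	cadd	clinvar	segregation	acmg_class	splice_delta_max	n_major	n_minor	systems	excluded
45	confident	male	Cone dysfunction syndrome	ALMS1	het	frameshift_variant	NM_015120.4:c.10775del	NP_055935.4:p.Thr3592LysfsTer6	5.23E-05	4.77E-04	.	.	.	pathogenic	paternal	pathogenic	.	1	0	Ophthalmic	1
45	confident	male	Cone dysfunction syndrome	ALMS1	het	structural_variant	NC_000002.12:g.(73424245_73544334inv;73424245_73427355dup;73484777_73544334dup)	.	.	.	.	.	.	absent	maternal	likely_pathogenic	.	1	0	Ophthalmic	1
47	possible	female	Bardet-Biedl syndrome	BBS10	hom	missense_variant	NM_024685.4:c.1790G>A	NP_078961.3:p.Gly597Asp	0	2.54E-05	deleterious	probably_damaging	.	absent	biparental	vus	.	4	0	Renal|Ophthalmic|Skeletal|Endocrine/Metabolic	1
48	confident	male	Rod dysfunction syndrome	NPHP1	hom	missense_variant	NM_001128178.3:c.1027G>A	NP_000263.2:p.Gly343Arg	0.0001155	0.00034312	deleterious	probably_damaging	35	pathogenic	one_parent	pathogenic	.	1	1	Renal|Ophthalmic	1
49	possible	female	Cystic kidney disease	CEP290	hom	intron_variant	NM_025114.4:c.6011+874G>T	.	0	3.81E-05	.	.	.	absent	one_parent	vus	0.64	1	1	Renal|Cardiovascular	0
50	possible	female	Syndromic cleft lip and/or cleft palate	OFD1	het	missense_variant	NM_003611.3:c.635G>C	NP_003602.1:p.Arg212Pro	0	1.27E-05	deleterious	possibly_damaging	21.2	absent	de_novo	vus	.	3	0	Facial/Oral|Skeletal	1
51	probable	male	Joubert syndrome	CEP290	het	missense_variant	NM_025114.4:c.104T>G	NP_079390.3:p.Val35Gly	0	1.00E-04	deleterious	probably_damaging	33	absent	maternal	vus	.	4	0	Ophthalmic|Neurological	1
51	probable	male	Joubert syndrome	CEP290	het	stop_gained	NM_025114.4:c.5668G>T	NP_079390.3:p.Gly1890Ter	9.49E-05	2.50E-04	.	.	.	pathogenic	paternal	vus	.	4	0	Ophthalmic|Neurological	1
53	possible	male	Cystic kidney disease	ALMS1	het	missense_variant	NM_015120.4:c.8735A>G	NP_055935.4:p.Gln2912Arg	0	5.00E-05	deleterious	possibly_damaging	19.03	absent	unknown	vus	.	2	2	Renal|Endocrine/Metabolic|Gastrointestinal|Cardiovascular	0
53	possible	male	Cystic kidney disease	ALMS1	het	missense_variant	NM_015120.4:c.7412A>G	NP_055935.4:p.Asp2471Gly	0	5.00E-05	deleterious	probably_damaging	25.9	absent	unknown	vus	.	2	2	Renal|Endocrine/Metabolic|Gastrointestinal|Cardiovascular	0
54	possible	female	Rod-cone dystrophy	ALMS1	het	missense_variant	NM_015120.4:c.10831A>G	NP_055935.4:p.Arg3611Gly	3.22E-05	5.00E-05	deleterious	possibly_damaging	23.5	absent	unknown	vus	.	2	1	Ophthalmic|Renal|Respiratory	0
54	possible	female	Rod-cone dystrophy	ALMS1	het	missense_variant	NM_015120.4:c.10377C>G	NP_055935.4:p.Ile3459Met	3.63E-05	5.00E-05	deleterious	possibly_damaging	23.1	vus	unknown	vus	.	2	1	Ophthalmic|Renal|Respiratory	0
55	confident	female	Single autosomal recessive mutation in rare disease	ALMS1	het	frameshift_variant	NM_015120.4:c.11794del	NP_055935.4:p.Glu3932LysfsTer18	3.99E-06	1.27E-05	.	.	.	absent	unknown	pathogenic	.	4	0	Ophthalmic|Endocrine/Metabolic|Cardiovascular	0
55	confident	female	Single autosomal recessive mutation in rare disease	ALMS1	het	frameshift_variant	NM_015120.4:c.1735del	NP_055935.4:p.Arg579GlyfsTer17	1.61E-05	3.18E-05	.	.	.	pathogenic	unknown	pathogenic	.	4	0	Ophthalmic|Endocrine/Metabolic|Cardiovascular	0
56	probable	male	Intellectual disability	ALMS1	het	frameshift_variant	NM_015120.4:c.10775del	NP_055935.4:p.Thr3592LysfsTer6	5.23E-05	0.00047656	.	.	.	pathogenic	unknown	pathogenic	.	1	2	Sensory|Cardiovascular|Neurological	0
56	probable	male	Intellectual disability	ALMS1	het	missense_variant	NM_015120.4:c.7510G>T	NP_055935.4:p.Ala2504Ser	8.93E-05	0.00019062	deleterious	probably_damaging	25	vus	unknown	vus	.	1	2	Sensory|Cardiovascular|Neurological	0
57	possible	male	Congenital hearing impairment	ALMS1	het	missense_variant	NM_015120.4:c.11429A>G	NP_055935.4:p.Tyr3810Cys	.	1.27E-05	deleterious	probably_damaging	27.5	absent	maternal	vus	.	1	0	Sensory	0
57	possible	male	Congenital hearing impairment	ALMS1	het	missense_variant	NM_015120.4:c.9148A>G	NP_055935.4:p.Ile3050Val	0.0002007	0.00012708	deleterious	possibly_damaging	24.2	vus	paternal	vus	.	1	0	Sensory	0
58	possible	female	Syndromic congenital heart disease	BBS1	het	missense_variant	NM_024649.5:c.734C>T	NP_078925.3:p.Pro245Leu	7.16E-05	6.35E-06	deleterious	benign	23.4	vus	unknown	vus	.	1	1	Neurological|Cardiovascular	0
58	possible	female	Syndromic congenital heart disease	BBS1	het	missense_variant	NM_024649.5:c.1313C>G	NP_078925.3:p.Thr438Arg	7.96E-05	4.45E-05	deleterious	probably_damaging	25.3	vus	maternal	vus	.	1	1	Neurological|Cardiovascular	0
62	confident	female	Epilepsy plus other features	CEP290	het	frameshift_variant	NM_025114.4:c.5434_5435del	NP_079390.3:p.Glu1812LysfsTer5	1.14E-05	4.45E-05	.	.	.	pathogenic	unknown	pathogenic	.	2	0	Ophthalmic|Neurological	0
62	confident	female	Epilepsy plus other features	CEP290	het	intron_variant	NM_025114.4:c.2991+1655A>G	.	0	0.00040031	.	.	.	pathogenic	unknown	pathogenic	.	2	0	Ophthalmic|Neurological	0
63	confident	female	Cystic kidney disease	CEP290	het	start_lost	NM_025114.4:c.2T>A	NP_079390.3:p.Met1?	4.07E-06	2.54E-05	.	.	.	absent	paternal	pathogenic	.	2	0	Renal|Ophthalmic	0
63	confident	female	Cystic kidney disease	CEP290	het	stop_gained	NM_025114.4:c.4966G>T	NP_079390.3:p.Glu1656Ter	3.60E-05	1.59E-04	.	.	.	pathogenic	maternal	pathogenic	.	2	0	Renal|Ophthalmic	0
66	possible	male	Leber congenital amaurosis or early onset severe retinal dystrophy	CEP290	hom	missense_variant	NM_025114.4:c.182T>C	NP_079390.3:p.Met61Thr	.	2.54E-05	deleterious	possibly_damaging	25.6	absent	biparental	vus	.	3	0	Ophthalmic|Neurological	0
67	possible	female	Ultra-rare undescribed monogenic disorders	CEP290	hom	missense_variant	NM_025114.4:c.5284C>T	NP_079390.3:p.Arg1762Cys	3.78E-05	9.53E-05	deleterious	possibly_damaging	29.6	vus	unknown	vus	.	2	1	Ophthalmic|Neurological|Gastrointestinal	0
70	confident	female	Proteinuric renal disease	DYNC2H1	het	synonymous_variant	NM_001377.3:c.11049G>A	NP_001368.2:p.Pro3683=	1.21E-05	0.00014996	.	.	.	likely_pathogenic	paternal	likely_pathogenic	0.51	2	0	Renal|Skeletal	0
70	confident	female	Proteinuric renal disease	DYNC2H1	het	structural_variant	NC_000011.9:g.103445518_10350188del	.	.	.	.	.	.	absent	maternal	likely_pathogenic	.	2	0	Renal|Skeletal	0
75	possible	male	Distal myopathies	TMEM67	het	missense_variant	NM_153704.6:c.2035G>C	NP_714915.3:p.Glu679Gln	0	5.00E-05	deleterious	probably_damaging	26.5	absent	unknown	vus	.	1	0	Renal	0
75	possible	male	Distal myopathies	TMEM67	het	missense_variant	NM_153704.6:c.755T>C	NP_714915.3:p.Met252Thr	8.36E-05	2.00E-04	deleterious	benign	23.7	pathogenic	unknown	pathogenic	.	1	0	Renal	0
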