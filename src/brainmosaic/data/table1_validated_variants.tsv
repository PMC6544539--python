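chrom	pos	ref	alt	consequence	gene	aa_change	exac_maf	sift_score	sift_class	expression_class	constraint_quartile	methylated_icm	exome_vaf	context_synthetic	sample_id	sex	brain_region	disease_group
chr1	248224344	C	T	nonsynonymous	OR2L3	p.R121C	4.94E-05	0.02	deleterious	not_detected	2	N	0.152	ACG	1	M	Cerebellum	Control
chr7	150815676	C	T	nonsynonymous	AGAP3	p.S81L		0.02	deleterious	expressed_all	4	N	0.223	ACA	2	M	Temporal cortex	Control
chr11	104905100	T	G	nonsynonymous	CASP1	p.K37Q	4.10E-03	0.59	tolerated	expressed_all	2	N	0.169	ATA	3	M	Cerebellum	Control
chr17	39502849	T	G	nonsynonymous	KRT33A	p.R316S	1.10E-03	0.67	tolerated	not_in_brain	2	N	0.221	CTC	4	M	Cerebellum	CJD
chr3	45837911	T	C	start_loss	SLC6A20	p.M1V	8.77E-05	0.43	tolerated	not_in_brain	3	N	0.203	ATG	5	M	Cerebellum	Alzheimer disease
chr3	122629742	T	C	nonsynonymous	SEMA5B	p.H59R		0.02	deleterious	elevated_brain	4	N	0.193	TTA	5	M	Cerebellum	Alzheimer disease
chr19	36275201	G	A	nonsynonymous	ARHGAP33	p.A517T		0.13	tolerated	mixed	3	N	0.260	CGA	6	M	Cerebellum	Other (PSP)
chr12	6138596	C	T	nonsynonymous	VWF	p.R960P	8.24E-06	0.26	tolerated	mixed	3	N	0.195	TCT	7	F	Cerebellum	Control
chr11	56344581	G	T	nonsynonymous	OR5M10	p.T206N	1.20E-03	1	tolerated	not_detected	2	N	0.130	AGA	8	F	Cerebellum	Other (epilepsy)
chr16	4833750	A	G	nonsynonymous	SETP12	p.I131T	1.68E-05	0.01	deleterious	not_in_brain	1	N	0.228	CAT	9	M	Frontal cortex	Control
chr7	1535876	C	T	nonsynonymous	INTS1	p.D671N	8.26E-06	0	deleterious	expressed_all	3	N	0.147	GCA	9	M	Frontal cortex	Control
chr8	144921555	T	C	nonsynonymous	NRBP2	p.I171V	3.32E-04	0.15	tolerated	expressed_all	2	N	0.304	GTG	9	M	Frontal cortex	Control
chr2	85991195	C	T	nonsynonymous	ATOH8	p.R284W	8.30E-06	0	deleterious	mixed	4	Y	0.283	TCG	10	F	Temporal cortex	Control
chr1	24125194	G	A	nonsynonymous	GALE	p.R50W	1.66E-05	0.02	deleterious	expressed_all	2	Y	0.217	CGT	11	F	Cerebellum	Control
chr1	17570577	T	C	nonsynonymous	PADI1	p.C126R		0.01	deleterious	not_in_brain	1	N	0.253	ATT	12	M	Cerebellum	Other (dementia)
chr17	76499013	G	A	synonymous	DNAH17		4.05E-03			not_in_brain		Y	0.282	CGC	12	M	Cerebellum	Other (dementia)
chr11	1718844	T	C	synonymous	KRTAP5-6		1.65E-05			not_detected		N	0.149	CTA	13	F	Cerebellum	FTD-ALS
chr19	9361855	G	A	nonsynonymous	OR7E24	p.A46T	2.50E-05	0	deleterious	not_in_brain	1	Y	0.302	CGG	13	F	Cerebellum	FTD-ALS
chr20	60888258	G	A	synonymous	LAMA5					expressed_all		N	0.230	TGA	13	F	Cerebellum	FTD-ALS
chr16	88712548	G	A	synonymous	CYBA					expressed_all	2	Y	0.235	CGA	14	F	Cerebellum	Control
chr22	50752254	G	A	nonsynonymous	DENND6B	p.R398W	1.66E-05	0	deleterious	mixed	1	Y	0.202	CGT	15	M	Cerebellum	FTD-ALS
chr6	5004177	G	A	synonymous	RPP40		4.12E-05			expressed_all		N	0.229	AGT	15	M	Cerebellum	FTD-ALS
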