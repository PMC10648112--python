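cancer_type	patient_id	gene	protein_change	classification	filter_note	pre_vaf_percent	post_vaf_percent	post_detected
NSCLC	CH-067	TP53	G245V	Path.		0.95	0.32	1
NSCLC	HN-008	EGFR	E746_750del	Path.		38	0	0
NSCLC	HN-008	TP53	N239D	Path.		33	0	0
NSCLC	LTW-047	BRAF	G265R	Lik. Path.		14.3	22.57	1
Colon	RA-027	KRAS	A146T	Path.		4.58	5.33	1
Colon	RA-027	PIK3CA	E545K	Path.		5.10	7.18	1
Colon	RA-027	TP53	R282W	Path.		5.17	7.61	1
Colon	RA-027	RAF1	R191I	Unc. Sig.		6.24	7.92	1
Colon	EW-034	KRAS	G12C	Path.		1.62	5.52	1
Colon	EW-034	TP53	R273H	Path.		47.39	4.47	1
Colon	EW-034	APC	S1407fs*3	Lik. Path.	G	51	12.60	1
Colon	MM-015	APC	P1443Lfs*30	Path.		73.48	0.94	1
Colon	MM-015	BRAF	K483E	Lik. Path.	G	69	2.19	1
Colon	MM-015	KRAS	A146V	Path.		39.4	1.99	1
Colon	MM-015	TP53	R275H	Path.		71.44	0.83	1
Colon	MB-051	KRAS	G12S	Path.		10.82	2.01	1
Colon	MB-051	TP53	R273H	Path.		11	1.86	1
Colon	MB-051	APC	P1319fs*2	Path.		14	2.68	1
Colon	SVO-002	APC	Y935*	Path.		3	0.54	1
Colon	SVO-002	APC	P1440fs*33	Path.		3.72	0.31	1
Colon	SVO-002	KRAS	A146T	Path.		7.65	1.65	1
Colon	SVO-002	TP53	E51*	Path.	R	5.85	1.63	1
Colon	KRS-014	APC	R564*	Path.		30.09	4.44	1
Colon	KRS-014	NRAS	Q61K	Path.		0.28	0	0
Colon	KRS-014	TP53	D259Y	Path.		19.28	3.25	1
Breast	CA-062	PIK3CA	I69N	Unc. Sig.		29.34	20.67	1
Breast	CA-062	PIK3CA	H1047R	Path.		27.46	22.23	1
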