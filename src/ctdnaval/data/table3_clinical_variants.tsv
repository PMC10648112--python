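gene	cdna_change	protein_change	ortho_vaf_percent	test_vaf_reported_percent	test_vaf_unfiltered_percent	filter_reason	below_ldt_cutoff	ortho_false_negative	classification	tumor_type	patient_id	clinical_in_ppa
AKT1	49G>A	E17K	39.1	43.35			0	0	Path.	Breast	MF-053	1
ALK	1108G>A	E370K	35.7	38.88			0	0	Unc. Sig.	Colon	EW-034	0
ALK	3599C>T	A1200V	40.8	36.16			0	0	Unc. Sig.	Mel.	SH-041	0
ALK	3885G>A	W1295*	3.7	4.55			0	0	Unc. Sig.	Lung	JS-040	0
ALK	3931G>C	D1311H	3.3	4.66			0	0	Unc. Sig.	Lung	JS-040	0
APC	734C>A	S245*	14	12.85			0	0	Path.	Colon	HM-059	1
APC	4349G>A	R1450Q	48.8	0	48.9	G	0	0	Unc. Sig.	Lung	GP-051	0
ARID1A	947A>T	Y316F	0.6	0			0	0	Unc. Sig.	Lung	DK-055	0
ARID1A	1978G>A	G660R	1.7	1.32			0	0	Unc. Sig.	Lung	CK-027	0
ARID1A	5965C>T	R1989*	0.3	0			0	0	Path.	Lung	AS-012	1
ATM	1339C>T	R447*	51.6	0	53.4	G	0	0	Path.	Lung	RC-055	1
ATM	6188G>A	G2063E	17.1	21			0	0	Lik. Path.	Colon	AD-050	1
ATM	8165T>G	L2722R	5.4	5.54			0	0	Unc. Sig.	Lung	JR-010	0
ATM	9023G>A	R3008H	18.3	20.81			0	0	Path.	Colon	AD-050	1
ATM	9101T>G	L3034W	50.4	0	50	G	0	0	Unc. Sig.	Lung	LTW-047	0
BRAF	793G>C	G265R	0	14.3			0	1	Lik. Path.	Lung	LTW-047	1
BRAF	1447A>G	K483E	68.5	0	69	G	0	0	Lik. Path.	Colon	MM-015	1
BRAF	1799T>A	V600E	0.6	0.69			0	0	Path.	Mel.	LH-070	1
BRAF	1799T>A	V600E	1.6	1.94			0	0	Path.	Mel.	JB-086	1
BRAF	1799T>A	V600E	19.8	17.07			0	0	Path.	Mel.	SH-041	1
BRCA1	3599A>C	Q1200P	0.6	0			0	0	Unc. Sig.	Lung	CL-080	0
BRCA2	7903G>A	E2635K	10.2	9.83			0	0	Unc. Sig.	Colon	HM-059	0
BRCA2	3568C>T	R1190W	52	52.11			0	0	Benign	Lung	JS-040	0
CCND1	835G>T	E279*	1.3	0			0	0	Unc. Sig.	Lung	AS-012	1
CDH1	817G>A	E273K	0.3	0			0	0	Unc. Sig.	Lung	DK-055	0
CDH1	2199G>T	R733S	0.3	0			0	0	Unc. Sig.	Lung	LTW-047	0
EGFR	2255C>T	S752F	0	1.16			0	0	Lik. Path.	Lung	AS-012	1
EGFR	2918G>A	R973Q	0.9	1.07			0	0	Unc. Sig.	Lung	JR-010	0
EGFR	3055C>T	P1019S	0.8	0.56			0	0	Unc. Sig.	Lung	RC-055	0
KIT	497C>G	P166R	0.6	0.78			0	0	Unc. Sig.	Lung	JK-049	0
KIT	1588G>A	V530I	0.8	0			0	0	Unc. Sig.	Lung	PC-075	0
KRAS	34G>T	G12C	0.5	1.62			0	0	Path.	Colon	EW-034	1
KRAS	35G>A	G12D	9.6	9.88			0	0	Path.	Lung	MS-072	1
KRAS	35G>A	G12D	22.5	21.85			0	0	Path.	Colon	HM-059	1
KRAS	35G>A	G12D	34.5	33.28			0	0	Path.	Colon	AD-050	1
KRAS	35G>T	G12V	14.4	11.13			0	0	Path.	Lung	CL-080	1
KRAS	35G>C	G12A	25.5	25.08			0	0	Path.	Lung	JS-040	1
KRAS	437C>T	A146V	35.1	34.9			0	0	Path.	Colon	MM-015	1
MET	3637C>A	L1213I	8.9	7.9			0	0	Lik. Path.	Lung	LD-030	1
MET	3937T>A	Y1331N	6.7	8.25			0	0	Unc. Sig.	Lung	MS-072	0
MYC	138C>G	F46L	23.6	22.21			0	0	Unc. Sig.	Breast	CM-029	0
MYC	1307G>A	R436Q	49.4	0	49	G	0	0	Unc. Sig.	Esoph.	AG-042	0
NTRK1	2350C>G	L784V	0.6	0			0	0	Unc. Sig.	Lung	LTW-047	0
PIK3CA	1624G>A	E542K	0	0.31			0	0	Path.	Colon	HM-059	1
PIK3CA	1624G>A	E542K	0.3	0.13			1	0	Path.	Lung	JK-049	1
PIK3CA	1624G>A	E542K	81	83.73			0	0	Path.	Breast	CM-029	1
PIK3CA	1633G>A	E545K	0.3	0.26			0	0	Path.	Colon	HM-059	1
PIK3CA	1634A>G	E545G	0.3	0.16			1	0	Path.	Colon	HM-059	1
PIK3CA	2176G>A	E726K	0	0.32			0	0	Path.	Lung	AS-012	1
RET	1078C>T	R360W	0	0.9			0	0	Unc. Sig.	Mel.	JB-086	0
ROS1	5209G>T	E1737*	1.5	1.4			0	0	Unc. Sig.	Breast	MF-053	0
ROS1	6286C>T	R2096W	30.7	0	29.8	R	0	0	Unc. Sig.	Lung	DK-055	0
TP53	313G>T	G105C	19.9	23.04			0	0	Path.	Lung	LD-030	1
TP53	469G>T	V157F	2.2	1.75			0	0	Path.	Lung	PC-075	1
TP53	641A>G	H214R	0.3	0.32			0	0	Path.	Esoph.	AG-042	1
TP53	659A>G	Y220C	2.2	2.89			0	0	Path.	Lung	JK-049	1
TP53	673-1G>T	Splicing region	37.6	0	36	R	0	0	Path.	Breast	CM-029	1
TP53	715A>G	N239D	34.9	33.03			0	0	Path.	Lung	HN-008	1
TP53	733G>T	G245C	47.1	46.55			0	0	Path.	Lung	DK-055	1
TP53	743G>A	R248Q	5.7	6.56			0	0	Path.	Lung	JS-040	1
TP53	773A>G	E258G	1.1	1.43			0	0	Path.	Lung	AS-012	1
TP53	818G>A	R273H	0.4	0.39			0	0	Path.	Lung	LD-030	1
TP53	818G>A	R273H	0.8	0.6			0	0	Path.	Lung	JK-049	1
TP53	818G>A	R273H	46.7	47.39			0	0	Path.	Colon	EW-034	1
TP53	524G>A	R175H	71.9	71.44			0	0	Path.	Colon	MM-015	1
TP53	856G>A	E286K	5.9	6.18			0	0	Path.	Lung	CL-080	1
APC	3460_3462delGAA	E1154del	46.5	37.54			0	0	Lik.ben.	Lung	DH-058	0
APC	3956delC	P1319Lfs*2	11.7	12.67			0	0	Path.	Colon	HM-059	1
APC	3957_3964delTGTGAGCG	V1320fs*9	23	0	26	PHI	0	0	Lik. Path.	Colon	AD-050	1
APC	4219_4234delAGTGAACCATGCAGTT	S1407fs*3	63	0	51	PHI	0	0	Lik. Path.	Colon	EW-034	1
APC	4326delT	P1443Lfs*30	75.6	73.48			0	0	Path.	Colon	MM-015	1
ARID1A	123_128delGGC	A42_A43del	62.7	0	56	G	0	0	Unc. Sig.	Lung	GP-051	0
BRAF	1798_1799delGTinsAA	V600K	2.2	1.66			0	0	Path.	Mel.	MI-043	1
BRCA2	6284delC	S2095Yfs*24	3.2	1.78			0	0	Lik. Path.	Lung	GP-051	1
CDH1	61_86delCTCTGCCAGGAGCCGGAGCCCTGCCAinsGCT	L21fs	12.7	0	36	C	0	0	Lik. Path.	Breast	MF-053	1
EGFR	2235_2249delGGAATTA	E746_A750del	28.8	37.8			0	0	Path.	Lung	HN-008	1
EGFR	2237_2254delAATTAAGAGAAGCAACAT	E746_S752delinsA	0	1.09			0	0	Path.	Lung	AS-012	1
EGFR	2237_2255delAATTAAGAGAAGCAACATinsT	E746_S752delinsV	1.3	1.18			0	0	Path.	Lung	AS-012	1
ERBB2	2230_2231delGA	N745Cfs*128	41	0	39.8	R	0	0	Unc. Sig.	Colon	AD-050	0
TP53	773_782delAAGACTCCAG	E258Vfs*84	0.5	1.01			0	0	Path.	Colon	HM-059	1
TP53	780delC	S261Vfs*84	9.6	10.92			0	0	Path.	Lung	RW-024	1
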