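signal_rsid	gene	base_score	ub_column	published_total
rs61816761	FLG	2	0	2
rs61816761	TUFT1	0	1	2
rs61816761	SELENBP1	0	1	2
rs61816761	C1orf68	0	1	2
rs7523907	CD247	7	0	7
rs7523907	BRP44	0	1	2
rs7523907	CREG1	0	1	2
rs12479210	IL1RL1	11	1	13
rs12479210	IL1R1	0	1	2
rs12479210	IL18R1	6	0	6
rs34290285	D2HGDH	11	1	13
rs34290285	PDCD1	3	0	3
rs34290285	GAL3ST2	1	0	1
rs34290285	KIF1A	1	1	3
rs560026225	KIAA1109	4	0	4
rs1837253	TSLP	2	0	2
rs1837253	WDR36	1	0	1
rs1438673	WDR36	3	0	3
rs1438673	CAMK4	1	0	1
rs1438673	TMEM232	0	1	2
rs1438673	TSLP	1	1	3
rs1438673	STMN1	0	1	2
rs3749833	SLC22A5	8	0	8
rs3749833	SLC22A4	2	0	2
rs3749833	P4HA2	2	0	2
rs3749833	C5orf56	1	0	1
rs3749833	IRF1	3	0	3
rs3749833	LOC553103	0	1	2
rs3749833	SEPT8	0	1	2
rs3749833	ANKRD43	0	1	2
rs1986009	SLC22A5	3	0	3
rs1986009	SLC22A4	3	0	3
rs1986009	ACSL6	0	1	2
rs1986009	IL13	0	1	2
rs1986009	IL4	0	1	2
rs9273410	HLA-DQB1	2	3	8
rs9273410	HLA-DQB2	2	3	8
rs9273410	HLA-DQA1	2	0	2
rs9273410	HLA-DQA2	2	0	2
rs9273410	ATF6B	1	0	1
rs776111176	HLA-DQA1	6	2	8
rs776111176	HLA-DQA2	6	0	6
rs776111176	HLA-DQB1	6	6	12
rs776111176	HLA-DQB2	6	0	6
rs776111176	HLA-DRB3	0	2	2
rs776111176	HLA-DOB	4	0	4
rs776111176	AGER	0	2	2
rs776111176	LY6G6E	0	2	2
rs776111176	PFDN6	0	2	2
rs776111176	NEU1	0	2	2
rs776111176	DOM3Z	0	2	2
rs776111176	LY6G6D	0	2	2
rs776111176	COL11A2	0	2	2
rs367983479	BACH2	3	0	3
rs367983479	ANKRD6	0	1	2
rs367983479	MAP3K7	0	1	2
rs367983479	GABRR2	0	1	2
rs71266076	ZBTB10	1	0	1
rs144829310	IL33	2	2	6
rs144829310	ERMP1	1	0	1
rs144829310	TPD52L3	0	1	2
rs10905284	GATA3	2	0	2
rs11603634	MUC5AC	2	2	6
rs11603634	TNNT3	0	1	2
rs7936312	LRRC32	4	0	4
rs7936312	BRCA2	1	0	1
rs7305461	RPS26	4	0	4
rs7305461	SUOX	4	0	4
rs7305461	RAB5B	2	0	2
rs7305461	ERBB3	2	0	2
rs7305461	ESYT1	1	0	1
rs7305461	GDF11	1	0	1
rs7305461	RNF41	1	0	1
rs703816	STAT6	5	0	5
rs703816	NEMP1	1	0	1
rs703816	RBMS2	1	0	1
rs703816	SPRYD4	1	0	1
rs703816	EEF1AKMT3	1	0	1
rs703816	ZBTB39	0	1	2
rs703816	CDK4	0	1	2
rs703816	ESYT1	0	1	2
rs10519068	RORA	4	0	4
rs10519068	ICE2	0	1	2
rs10519068	ANXA2	0	1	2
rs10519068	FOXB1	0	1	2
rs72743461	SMAD3	4	0	4
rs72743461	AAGAB	3	0	3
rs72743461	C15orf61	0	1	2
rs72743461	BPGM	0	1	2
rs72743461	MAP2K1	0	1	2
rs7203459	CLEC16A	2	1	4
rs7203459	TEKT5	0	1	2
rs7203459	PRM1	0	1	2
rs7203459	DEXI	3	0	3
rs2941522	ORMDL3	4	0	4
rs2941522	GSDMB	5	0	5
rs2941522	GSDMA	2	0	2
rs2941522	PGAP3	3	0	3
rs2941522	MSL1	1	1	3
rs2941522	IKZF3	2	0	2
rs2941522	ARL5C	0	1	2
rs112502960	ZNF652	3	0	3
rs112502960	GNGT2	3	0	3
rs112502960	PHOSPHO1	2	0	2
rs112502960	TMEM92	0	1	2
rs112502960	HOXB4	0	1	2
rs112502960	NCRNA00253	0	1	2
rs61840192	GATA3	4	0	4
rs61840192	GATA3-AS1	2	0	2
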