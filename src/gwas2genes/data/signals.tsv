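rsid	closest_gene	risk_allele	non_risk_allele	raf_eur
rs61816761	FLG	A	G	0.0237
rs7523907	CD247	T	C	0.5408
rs12479210	IL1RL1	T	C	0.3873
rs34290285	D2HGDH	G	A	0.7426
rs560026225	KIAA1109	GATT	G	0.2360
rs1837253	TSLP	C	T	0.7416
rs1438673	WDR36	C	T	0.5078
rs3749833	C5orf56	C	T	0.2608
rs1986009	RAD50	A	C	0.1871
rs9273410	HLA-DQB1	A	C	0.5530
rs776111176	HLA-DQA1	A	AAT	0.1485
rs367983479	BACH2	CA	C	0.6150
rs71266076	MIR5708	C	CT	0.3693
rs144829310	IL33	T	G	0.1640
rs10905284	GATA3	C	A	0.4294
rs11603634	MUC5AC	G	A	0.5036
rs7936312	C11orf30	T	G	0.4742
rs7305461	RPS26	A	C	0.4461
rs703816	STAT6	C	T	0.4341
rs10519068	RORA	G	A	0.8725
rs72743461	SMAD3	A	C	0.2360
rs7203459	CLEC16A	T	C	0.7544
rs2941522	IKZF3	T	C	0.4829
rs112502960	ZNF652	A	G	0.3592
rs61840192	LOC101928272	G	A	0.5730
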