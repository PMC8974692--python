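term	genes	count	percent	fold_enrichment	p_value	fdr
Asthma	FLG,IL33,GSDMB,SLC22A5,SMAD3,TSLP,GATA3,SUOX,MUC5AC,IL1RL1,IRF1,ORMDL3,STAT6,HLA-DQA2,IL18R1,HLA-DQA1,HLA-DQB1	17	45.95	14.53	1.78e-15	1.07e-12
Diabetes mellitus, type 1	KIAA1109,GSDMB,CLEC16A,PDCD1,SUOX,HLA-DQA2,BACH2,HLA-DQA1,HLA-DQB1	9	24.32	32.76	1.58e-10	4.76e-08
Celiac disease	IL1RL1,KIAA1109,IRF1,CLEC16A,CD247,BACH2,IL18R1,HLA-DQA1,HLA-DQB1	9	24.32	22.97	2.72e-09	5.44e-07
Nasal polyposis	IL33,IL1RL1,WDR36,HLA-DQA1,HLA-DQB1	5	13.51	140.38	3.00e-08	4.30e-06
Obesity|asthma	IL33,IL1RL1,GSDMB,TSLP,ORMDL3,IL18R1	6	16.22	60.47	3.57e-08	4.30e-06
Ulcerative colitis	SLC22A4,GSDMB,SLC22A5,ORMDL3,STAT6,HLA-DQA1,HLA-DQB1	7	18.92	31.27	6.45e-08	6.46e-06
Arthritis, rheumatoid	SLC22A4,IL1RL1,KIAA1109,CD247,HLA-DQA2,HLA-DQA1,HLA-DQB1	7	18.92	19.79	9.79e-07	8.41e-05
Crohn's disease	GSDMB,SLC22A5,SMAD3,ORMDL3,BACH2,HLA-DQA1	6	16.22	23.12	4.63e-06	3.48e-04
Diabetes, type 1	SLC22A4,SLC22A5,IRF1,CLEC16A,PDCD1,HLA-DQA1,HLA-DQB1	7	18.92	14.48	6.02e-06	3.62e-04
Rheumatoid arthritis	SLC22A4,SLC22A5,CLEC16A,PDCD1,HLA-DQB2,HLA-DQA1,HLA-DQB1	7	18.92	14.48	6.02e-06	3.62e-04
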