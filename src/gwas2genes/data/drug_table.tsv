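gene	drug	interaction_type	pmids	interaction_score	trial_ids
AAGAB					
BACH2					
CD247	MUROMO-B-CD3		2503348,8861551	15.95	
CD247	BLI-TUMOMAB			3.04	
CD247	AZACITIDINE		15795105	1.25	
CD274	AVELUMAB	Antibody (inhibitory) Clinical Trials	28472902,26918451,23724846	23.92	
CD274	ATEZOLIZUMAB	Antibody (inhibitory) Clinical Trials	24403232,24829850,28472902,26970723,26918451,26952546,27412122	10.63	
CD274	DURVALUMAB	Antibody (inhibitory) Clinical Trials	28472902,29416316,28717238,28214651	7.97	
CD274	LODAPOLIMAB	Antibody (inhibitory)		5.32	
CD274	CX-072	Clinical Trials/CytomX Therapeutics/Solid tumor		5.32	NCT03993379,NCT03013491,NCT04596150
CD274	BMS-936559	Antibody (inhibitory) Clinical trials/Bristol-Myers Squibb/cancer and NIAID/HIV		5.32	NCT01452334,NCT01455103,NCT02576457,NCT02028403
CD274	ENVAFOLIMAB	Antibody (inhibitory) Clinical Trial/Tracon Pharmaceuticals Inc./Undifferentiated Pleomorphic Sarcoma|Myxofibrosarcoma		5.32	NCT04480502
CD274	PIDILIZUMAB	Antibody (inhibitory) Clinical trial/Northwestern University|Gateway for Cancer Research|National Cancer Institute (NCI)/Lymphoma		2.66	NCT02530125
CD274	NIVOLUMAB	Antibody (inhibitory) Clinical Trials	26086854,28472902,26918451	2.48	
CD274	PEMBROLIZUMAB	Antibody (inhibitory) Clinical Trials	25891174,28472902,27718847,26918451,26086854	2.17	
CD274	M-7824	Clinical Trials		1.77	
CLEC16A					
D2HGDH					
DEXI					
FLG					
GATA3	PEGASPARGASE		24141364	2.45	
GATA3	SB010	Clinical Trial/Sterna Biologicals GmbH & Co. KG/Asthma			NCT01743768
GATA3	SB011	Clinical Trial/Sterna Biologicals GmbH & Co. KG/Mild to Moderate Atopic Dermatitis			NCT02079688
GATA3	SB012	Clinical Trial/Sterna Biologicals GmbH & Co. KG/Ulcerative Colitis			NCT02129439
GNGT2					
GSDMB					
HLA-DQA1	LUMIRACOXIB		20639878	7.97	
HLA-DQA1	LAPATINIB		24687830,21245432	2.28	
HLA-DQA1	AZATHIOPRINE		25217962	1.28	
HLA-DQA2					
HLA-DQB1	LUMIRACOXIB		20639878	2.66	
HLA-DQB1	BUCILLAMINE			2.66	
HLA-DQB1	CLAVULANIC ACID		10535882,30664875	2.28	
HLA-DQB1	FLOXACILLIN		30664875	1.52	
HLA-DQB2					
IL18R1					
IL1RL1	MSTT1041A	Clinical Trial/University of Leicester/COPD			NCT03615040
IL1RL1	GSK3772847	Clinical Trial/GSK/Moderately Severe Asthma			NCT03207243
IL33	ITEPEKIMAB	Clinical Trial/Regerenron/COPD			NCT04701983
IL33	MSTT1041A	Clinical Trial/Hoffmann-La Roche/Severe Asthma			NCT02918019
IL33	MEDI3506	Clinical Trial/AstraZenica/Uncontrolled Moderate-Severe Asthma			NCT04570657
IL33	ANB020	Clinical Trial/University of Leicester/AnaptysBio/Asthma			NCT04256044
IL37					
IRAK4	PF-06650833	Inhibitory Clinical Trial/Yale University/COVID-19 Clinical Trial/Pfizer/rheumatoid arthritis		3.36	NCT04575610,NCT02996500
IRAK4	KT-474	Small molecule degrader Clinical Trial/Kymera Therapeutics Inc./Atopic Dermatitis, Hidradenitis Suppurativa			NCT04772885
IRAK4	CA-4948	Inhibitory Clinical Trial/Curis Inc./Acute Myelogenous Leukemia, Myelodysplastic Syndrome/Relapsed Hematologic Malignancy, Refractory Hematologic Malignancy			NCT04278768,NCT03328078
IRF1					
KIF1A					
KIAA1109					
LRRC32					
MSL1					
MUC5AC	ENSITUXIMAB			31.9	
ORMDL3					
PDCD1	CEMIPLIMAB	Antibody (inhibitory), inhibitor (inhibitory)	29863979,29089720	9.11	
PDCD1	SPARTALIZUMAB	Antibody (inhibitory)		9.11	
PDCD1	TISLELIZUMAB	Antibody (inhibitory)		9.11	
PDCD1	PIDILIZUMAB	Antibody (inhibitory)		6.83	
PDCD1	AMP-224	Antibody (inhibitory)		4.56	
PDCD1	MGA-012			4.56	
PDCD1	BALSTILIMAB			4.56	
PDCD1	SYM-021			4.56	
PDCD1	SASANLIMAB			4.56	
PDCD1	SINTILIMAB			4.56	
PDCD1	DOSTARLIMAB			4.56	
PDCD1	NIVOLUMAB	Inhibitor (inhibitory), antibody (inhibitory)	23289116	2.13	
PDCD1	M-7824			1.52	
PDCD1	PEMBROLIZUMAB	Antibody (inhibitory), antagonist (inhibitory), inhibitor (inhibitory)	25685857	1.04	
PDCD1	Pembrolizumab/Vibostolimab Coformulation (MK-7684A)	Clinical Trial/Merck Sharp & Dohme Corp./Metastatic Non-Small Cell Lung Cancer			NCT04725188
PDCD1LG2	AMP-224	Antibody		15.95	
PDCD1LG2	PEMBROLIZUMAB		28619999	2.9	
PGAP3					
RORA	CHOLESTEROL	Agonist (activating)	10592235,17139284,17016423	31.9	
RORA	T091317	Agonist (activating)		2.66	
RORA	MELATONIN		8702678,12595746	1.77	
RPS26					
SLC22A4	IMATINIB		23127916,22875622	2.81	
SLC22A5	CARNITINE		21422191	63.79	
SLC22A5	IMATINIB		28762371,23127916	1.41	
SMAD3	VACTOSERTIB	Clinical Trial/MedPacto, Inc./Solid state tumors			NCT02160106
STAT6	CHEMBL1374370			5.32	
STAT6	CHEMBL363332			2.66	
SUOX					
TSLP	MEDI9929	Clinical Trial/MedImmune LLC/Severe Asthma, Atopic Dermatitis			NCT02698501,NCT02054130,NCT02512900
TSLP	MRx-4DP0004	Clinical Trial/4D pharma plc/Asthma & COVID-19			NCT03851250,NCT04363372
WDR36					
ZAP70	TRIDOLGOSIR		17897956	21.26	
ZAP70	ALOISINE	Inhibitory		10.63	
ZBTB10					
ZNF652					
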