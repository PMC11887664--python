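regulator_id	cnv_class	target_id	target_type	diseases
LINC00115	FULL_DEL	ZNF596	protein_coding	Malignant glioma
LINC01128	FULL_DEL	SFN	protein_coding	Cervical cancer
LINC-PINT	FULL_DEL	PTCH1	protein_coding	Acute lymphocytic leukemia;Gastric cancer;Esophageal cancer;Non-small cell lung cancer;Osteosarcoma;Laryngeal carcinoma
LINC01189	FULL_DEL	miR-155-5p	miRNA	Hepatitis C
LINC01093	FULL_DUP	GLI1	protein_coding	Hepatocellular carcinoma
LUCAT1	FULL_DUP	NRF2	protein_coding	Hepatoblastoma;Osteosarcoma;Clear cell renal cell carcinoma;Non-small cell lung cancer;Esophagus squamous cell carcinoma;Thoracoabdominal aorta aneurysm;Breast cancer;Renal fibrosis;Chronic heart failure;Chronic obstructive pulmonary disease;Pancreatic cancer;Hepatocellular carcinoma;Pancreatic ductal adenocarcinoma;Cervical cancer;Colorectal cancer;Triple-negative breast cancer;Ovarian cancer;Gastric cancer;Papillary thyroid carcinoma
NR2F1-AS1	FULL_DUP	SIK1	protein_coding	Osteosarcoma;Endometrial cancer;Gastric cancer;Breast cancer lung metastatic dormancy;Thyroid cancer;Cervical squamous cell carcinoma
MCTP1-AS1	FULL_DUP	miR-650	miRNA	Endometrial cancer
LINC01554	FULL_DUP	PKM	protein_coding	Esophagus squamous cell carcinoma;Hepatocellular carcinoma
RGMB-AS1	FULL_DUP	NLRP3	protein_coding	Lung adenocarcinoma;Non-small cell lung cancer;Gastric cancer;Laryngeal squamous cell carcinoma
LINC00491	FULL_DUP	ROCK1	protein_coding	Hepatocellular carcinoma
EPB41L4A-AS1	FULL_DUP	MYD88	protein_coding	Cancer;Type 2 diabetes mellitus
EPB41L4A-DT	FULL_DUP	FOXL1	protein_coding	Hepatocellular carcinoma
LINC02200	FULL_DUP	NFKB1	protein_coding	Sinonasal squamous cell carcinoma
LINC01170	FULL_DUP	AKT1	protein_coding	Endometrial cancer
MIR3936HG	FULL_DUP	STMN1	protein_coding	Nasopharynx carcinoma;Gastric cancer
WSPAR	FULL_DUP	miR-200c	miRNA	Asthma;Colorectal cancer;Malignant glioma;Hepatocellular carcinoma;Non-small cell lung cancer;Kidney disease
EPIST	FULL_DUP	CYC1	protein_coding	Osteosarcoma;Hepatocellular carcinoma;Oral squamous cell carcinoma
SMAD5-AS1	FULL_DUP	SMAD5	protein_coding	Diffuse large B-cell lymphoma;Nasopharynx carcinoma
SNHG4	FULL_DUP	MET	protein_coding	Osteosarcoma;Neuroblastoma;Renal cell carcinoma;Acute myeloid leukemia;Non-small cell lung cancer;Neonatal pneumonia;Prostate cancer;Cervical cancer;Lung cancer
MALINC1	FULL_DUP	PURA	protein_coding	Cancer
CARMN	FULL_DUP	miR-21	miRNA	Urinary bladder cancer;Laryngeal squamous cell carcinoma
CLMAT3	FULL_DUP	CDH1	protein_coding	Colorectal cancer
SAP30L-AS1	FULL_DUP	SAP30L	protein_coding	Prostate cancer
FAM87A	FULL_DUP	PPM1H	protein_coding	Malignant glioma
B4GALT1-AS1	FULL_DUP	YY1AP1	protein_coding	Sepsis-induced acute kidney injury
LINC00842	FULL_DUP	PPARGC1A	protein_coding	Pancreatic ductal adenocarcinoma
FAM99A	FULL_DUP	YAP1	protein_coding	Pre-eclampsia
NRIR	PART_DEL	FUBP3	protein_coding	Colorectal cancer
PURPL	PART_DEL	TP53	protein_coding	Colorectal cancer;Liver cancer
TRG-AS1	PART_DEL	SUZ12	protein_coding	Glioblastoma
LINC01410	PART_DEL	CHD7	protein_coding	Thyroid cancer;Gallbladder cancer;Endometrial cancer
TCL6	PART_DEL	PTEN	protein_coding	Pre-eclampsia;Threatened abortion;Retinoblastoma
LINC01579	PART_DEL	EIF4G2	protein_coding	Glioblastoma
LINC00922	PART_DEL	LZTS1	protein_coding	Lung cancer;Colorectal cancer
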