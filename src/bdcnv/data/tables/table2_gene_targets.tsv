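regulator_id	cnv_class	target_id	target_type	diseases
IL6	FULL_DEL	AU021063	lncRNA	Breast cancer
TLR3	FULL_DUP	lnc-IL7R	lncRNA	Oral squamous cell carcinoma
ELL2	FULL_DUP	MAPK14	protein_coding	Malignant glioma
TSLP	FULL_DUP	HOTAIR	lncRNA	Atherosclerosis
IRF1	FULL_DUP	IRF1-AS	lncRNA	Esophageal squamous cell carcinoma
EGR1	FULL_DUP	FOXD2-AS1	lncRNA	Gastric cancer;Diabetes mellitus;Lung adenocarcinoma;Hepatocellular carcinoma
HDAC3	FULL_DUP	LOC101928316	lncRNA	Gastric cancer
G3BP1	FULL_DUP	H19	lncRNA	Hepatocellular carcinoma
BIRC7	FULL_DUP	LNCRNA-ATB	lncRNA	Kidney disease
REST	PART_DUP	ITIH4-AS1	lncRNA	Colorectal cancer
PBX3	PART_DUP	SNHG10	lncRNA	Gastric cancer
KDM4C	PART_DUP	MALAT1	lncRNA	Colorectal cancer
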