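abbreviation	cancer_type	hit_ranges
BLCA	Bladder urothelial carcinoma	4;6-7;7
BRCA	Breast invasive carcinoma	3;2-3;6-7
CESC	Cervical squamous cell carcinoma and endocervical adenocarcinoma	5;6-7
COAD	Colon adenocarcinoma	3;4;5;6
GBM	Glioblastoma multiforme	2;3
HNSC	Head and neck squamous cell carcinoma	4;5
KIRP	Kidney renal papillary cell carcinoma	8
LGG	Brain lower grade glioma	3;6
LIHC	Liver hepatocellular carcinoma	8
LUAD	Lung adenocarcinoma	3;6-7
LUSC	Lung squamous cell carcinoma	5
OV	Ovarian serous cystadenocarcinoma	2;6-7
PRAD	Prostate adenocarcinoma	6-7;7
SARC	Sarcoma	5;8
THCA	Thyroid carcinoma	5;6
UCEC	Uterine corpus endometrial carcinoma	2;6-7
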