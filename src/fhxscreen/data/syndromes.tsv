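id	parent_id	label	aliases
hboc		Hereditary breast and ovarian cancer syndrome	hereditary breast and ovarian cancer
li_fraumeni		Li-Fraumeni syndrome	lfs|li fraumeni
lynch_syndrome		Lynch syndrome	ls|hnpcc|hereditary nonpolyposis colorectal cancer
cowden		Cowden syndrome	pten hamartoma tumor syndrome|phts
peutz_jeghers		Peutz-Jeghers syndrome	pjs
familial_adenomatous_polyposis		Familial adenomatous polyposis	fap
attenuated_fap		Attenuated familial adenomatous polyposis	afap
mutyh_associated_polyposis		MUTYH-associated polyposis	map
juvenile_polyposis		Juvenile polyposis syndrome	jps
hereditary_diffuse_gastric_cancer		Hereditary diffuse gastric cancer	hdgc
von_hippel_lindau		Von Hippel-Lindau syndrome	vhl syndrome
birt_hogg_dube		Birt-Hogg-Dube syndrome	bhd
hereditary_leiomyomatosis_rcc		Hereditary leiomyomatosis and renal cell cancer	hlrcc
hereditary_papillary_rcc		Hereditary papillary renal cell carcinoma	hprcc
tuberous_sclerosis		Tuberous sclerosis complex	tsc
men1_syndrome		Multiple endocrine neoplasia type 1	men1 syndrome|multiple endocrine neoplasia 1
men2a		Multiple endocrine neoplasia type 2A	men2a syndrome
men2b		Multiple endocrine neoplasia type 2B	men2b syndrome
familial_medullary_thyroid		Familial medullary thyroid carcinoma	fmtc
hereditary_paraganglioma_pheochromocytoma		Hereditary paraganglioma-pheochromocytoma syndrome	pgl/pcc
retinoblastoma_syndrome		Hereditary retinoblastoma
neurofibromatosis_1		Neurofibromatosis type 1
neurofibromatosis_2		Neurofibromatosis type 2
fammm		Familial atypical multiple mole melanoma syndrome	melanoma-pancreatic cancer syndrome
bap1_tumor_predisposition		BAP1 tumor predisposition syndrome	bap1-tpds
gorlin_syndrome		Gorlin syndrome	nevoid basal cell carcinoma syndrome
dicer1_syndrome		DICER1 syndrome
rhabdoid_tumor_predisposition		Rhabdoid tumor predisposition syndrome
fanconi_anemia		Fanconi anemia
bloom_syndrome		Bloom syndrome
ataxia_telangiectasia		Ataxia-telangiectasia
xeroderma_pigmentosum		Xeroderma pigmentosum	xp
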