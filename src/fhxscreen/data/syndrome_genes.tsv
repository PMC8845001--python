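syndrome_id	gene_ids
hboc	brca1|brca2
li_fraumeni	tp53
lynch_syndrome	epcam|mlh1|msh2|msh6|pms2
cowden	pten
peutz_jeghers	stk11
familial_adenomatous_polyposis	apc
attenuated_fap	apc
mutyh_associated_polyposis	mutyh
juvenile_polyposis	bmpr1a|smad4
hereditary_diffuse_gastric_cancer	cdh1|ctnna1
von_hippel_lindau	vhl
birt_hogg_dube	flcn
hereditary_leiomyomatosis_rcc	fh
hereditary_papillary_rcc	met
tuberous_sclerosis	tsc1|tsc2
men1_syndrome	men1
men2a	ret
men2b	ret
familial_medullary_thyroid	ret
hereditary_paraganglioma_pheochromocytoma	sdha|sdhaf2|sdhb|sdhc|sdhd|tmem127|max
retinoblastoma_syndrome	rb1
neurofibromatosis_1	nf1
neurofibromatosis_2	nf2
fammm	cdkn2a|cdk4
bap1_tumor_predisposition	bap1
gorlin_syndrome	ptch1|sufu
dicer1_syndrome	dicer1
rhabdoid_tumor_predisposition	smarcb1|smarca4
fanconi_anemia	fanca|fancb|fancc|fancd2|fance|fancf|fancg|fanci|fancl|fancm|slx4|ercc4|brip1|palb2|rad51c
bloom_syndrome	blm
ataxia_telangiectasia	atm
xeroderma_pigmentosum	xpa|xpc|ercc2|ercc3|ercc5|ddb2|polh
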