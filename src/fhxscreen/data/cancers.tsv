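id	parent_id	label	aliases
breast		Breast cancer	breast cancer|breast carcinoma
ovarian		Ovarian cancer	ovarian cancer|ovary
fallopian_tube		Fallopian tube cancer	fallopian tube cancer
primary_peritoneal		Primary peritoneal cancer	peritoneal cancer
prostate		Prostate cancer	prostate cancer
pancreatic		Pancreatic cancer	pancreatic cancer|pancreas
colorectal		Colorectal cancer	colorectal cancer|bowel cancer
endometrial		Endometrial cancer	endometrial cancer|uterine cancer|uterine
gastric		Gastric cancer	gastric cancer|stomach cancer|stomach
melanoma		Melanoma	malignant melanoma
brain_cns		Brain/CNS tumor	brain cancer|brain tumor|cns tumor
renal		Renal cancer	kidney cancer|kidney|renal cell carcinoma
thyroid		Thyroid cancer	thyroid cancer
bladder		Bladder cancer	bladder cancer
urothelial		Urothelial cancer	urothelial carcinoma|ureter cancer|renal pelvis cancer
small_bowel		Small bowel cancer	small intestine cancer|small bowel cancer
hepatobiliary		Hepatobiliary cancer	liver cancer|bile duct cancer|cholangiocarcinoma
lung		Lung cancer	lung cancer
leukemia		Leukemia	leukaemia
lymphoma		Lymphoma
sarcoma		Sarcoma	soft tissue sarcoma
adrenocortical_carcinoma		Adrenocortical carcinoma	acc|adrenal cortical carcinoma
pheochromocytoma		Pheochromocytoma
paraganglioma		Paraganglioma
testicular		Testicular cancer	testicular cancer
cervical		Cervical cancer	cervix
vulvar		Vulvar cancer
vaginal		Vaginal cancer
esophageal		Esophageal cancer	oesophageal cancer
head_and_neck		Head and neck cancer
basal_cell_carcinoma		Basal cell carcinoma	bcc
squamous_cell_skin		Cutaneous squamous cell carcinoma	skin scc
neuroblastoma		Neuroblastoma
retinoblastoma		Retinoblastoma
wilms_tumor		Wilms tumor	nephroblastoma
mesothelioma		Mesothelioma
thymoma		Thymoma
carcinoid		Carcinoid tumor	neuroendocrine tumor
gastrointestinal_stromal_tumor		Gastrointestinal stromal tumor	gist
multiple_myeloma		Multiple myeloma
salivary_gland		Salivary gland cancer
gallbladder		Gallbladder cancer
penile		Penile cancer
sebaceous_carcinoma		Sebaceous carcinoma	sebaceous adenocarcinoma
ductal_breast	breast	Invasive ductal breast carcinoma	ductal breast cancer
lobular_breast	breast	Invasive lobular breast carcinoma	lobular breast cancer
inflammatory_breast	breast	Inflammatory breast cancer
medullary_breast	breast	Medullary breast carcinoma
metaplastic_breast	breast	Metaplastic breast carcinoma
high_grade_serous_ovarian	ovarian	High-grade serous ovarian carcinoma	hgsoc
endometrioid_ovarian	ovarian	Endometrioid ovarian carcinoma
clear_cell_ovarian	ovarian	Clear cell ovarian carcinoma
mucinous_ovarian	ovarian	Mucinous ovarian carcinoma
sex_cord_stromal	ovarian	Sex cord-stromal tumor
small_cell_carcinoma_ovary	ovarian	Small cell carcinoma of the ovary, hypercalcemic type	sccoht
colon	colorectal	Colon cancer	colon
rectal	colorectal	Rectal cancer	rectum
glioblastoma	brain_cns	Glioblastoma	gbm
astrocytoma	brain_cns	Astrocytoma
medulloblastoma	brain_cns	Medulloblastoma
choroid_plexus_carcinoma	brain_cns	Choroid plexus carcinoma	cpc
ependymoma	brain_cns	Ependymoma
meningioma	brain_cns	Meningioma
clear_cell_rcc	renal	Clear cell renal cell carcinoma	ccrcc
papillary_rcc_type1	renal	Papillary renal cell carcinoma type 1
papillary_rcc_type2	renal	Papillary renal cell carcinoma type 2
chromophobe_rcc	renal	Chromophobe renal cell carcinoma
collecting_duct_rcc	renal	Collecting duct renal cell carcinoma
renal_oncocytoma	renal	Renal oncocytoma
papillary_thyroid	thyroid	Papillary thyroid carcinoma
follicular_thyroid	thyroid	Follicular thyroid carcinoma
medullary_thyroid	thyroid	Medullary thyroid carcinoma	mtc
anaplastic_thyroid	thyroid	Anaplastic thyroid carcinoma
cribriform_morular_thyroid	thyroid	Cribriform-morular thyroid carcinoma
osteosarcoma	sarcoma	Osteosarcoma
rhabdomyosarcoma	sarcoma	Rhabdomyosarcoma
leiomyosarcoma	sarcoma	Leiomyosarcoma
liposarcoma	sarcoma	Liposarcoma
ewing_sarcoma	sarcoma	Ewing sarcoma
acute_lymphoblastic_leukemia	leukemia	Acute lymphoblastic leukemia	all
acute_myeloid_leukemia	leukemia	Acute myeloid leukemia	aml
diffuse_gastric	gastric	Diffuse gastric cancer	signet ring gastric cancer
intestinal_gastric	gastric	Intestinal-type gastric cancer
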