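category	id	parent_id	label	aliases
disease_factor	msi_high		Microsatellite instability high	msi-h|msi high|mmr deficient
disease_factor	mmr_stable		Mismatch repair stable	mss|microsatellite stable
histology	clear_cell		Clear cell	clear-cell
histology	collecting_duct		Collecting duct
histology	papillary		Papillary
histology	chromophobe		Chromophobe
histology	oncocytic		Oncocytic
histology	cribriform_morular		Cribriform-morular	cribriform morular
hormone_status	er_positive		Estrogen receptor positive	er+
hormone_status	er_negative		Estrogen receptor negative	er-
hormone_status	pr_positive		Progesterone receptor positive	pr+
hormone_status	pr_negative		Progesterone receptor negative	pr-
hormone_status	her2_positive		HER2 positive	her2+
hormone_status	her2_negative		HER2 negative	her2-
laterality	left		Left
laterality	right		Right
laterality	bilateral		Bilateral	both sides
tissue_origin	ductal		Ductal
tissue_origin	lobular		Lobular
tissue_origin	serous		Serous
tissue_origin	mucinous		Mucinous
tissue_origin	endometrioid		Endometrioid
tissue_origin	intestinal		Intestinal
tissue_origin	diffuse		Diffuse	signet ring
tissue_origin	epithelial		Epithelial
polyp_type	adenomatous		Adenomatous polyps	adenoma|adenomas
polyp_type	hamartomatous		Hamartomatous polyps	hamartoma
polyp_type	juvenile		Juvenile polyps
polyp_type	serrated		Serrated polyps
polyp_type	hyperplastic		Hyperplastic polyps
ancestry	ashkenazi_jewish		Ashkenazi Jewish	aj|ashkenazi
ancestry	european		European	caucasian|white
ancestry	african		African	african american|black
ancestry	hispanic_latino		Hispanic or Latino	hispanic|latino
ancestry	east_asian		East Asian
ancestry	south_asian		South Asian
ancestry	southeast_asian		Southeast Asian
ancestry	middle_eastern		Middle Eastern or North African	mena
ancestry	native_american		Native American	american indian
ancestry	pacific_islander		Pacific Islander
trait	macrocephaly		Macrocephaly
trait	mucocutaneous_pigmentation		Mucocutaneous pigmentation
trait	trichilemmoma		Trichilemmoma
trait	desmoid_tumor		Desmoid tumor
sex	female		Female	f|woman
sex	male		Male	m|man
sex	unknown		Unknown sex
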