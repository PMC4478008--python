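# Synthetic reference catalog of characterized type II PKS KS-alpha loci.
# Ids and product names are synthetic stand-ins; the composition matches the
# published reference set for this marker: 70 loci = 7 spore pigment + 63
# antibiotic, the latter covering 58 unique products in 20 chemotypes.
id	category	chemotype	antibiotic
R001	antibiotic	angucycline	urdamycin
R002	antibiotic	angucycline	landomycin
R003	antibiotic	angucycline	jadomycin
R004	antibiotic	angucycline	aquayamycin
R005	antibiotic	angucycline	gaudimycin
R006	antibiotic	angucycline	simocyclinone
R007	antibiotic	angucycline	oviedomycin
R008	antibiotic	angucycline	grincamycin
R009	antibiotic	angucycline	moromycin
R010	antibiotic	angucycline	saquayamycin
R011	antibiotic	angucycline	vineomycin
R012	antibiotic	angucycline	fridamycin
R013	antibiotic	angucycline	kiamycin
R014	antibiotic	angucycline	dehydrorabelomycin
R015	antibiotic	angucycline	tetrangulol
R016	antibiotic	angucycline	hatomarubigin
R017	antibiotic	angucycline	urdamycin
R018	antibiotic	anthracycline	doxorubicin
R019	antibiotic	anthracycline	daunorubicin
R020	antibiotic	anthracycline	aclacinomycin
R021	antibiotic	anthracycline	nogalamycin
R022	antibiotic	anthracycline	steffimycin
R023	antibiotic	anthracycline	cosmomycin
R024	antibiotic	anthracycline	komodoquinone
R025	antibiotic	anthracycline	daunorubicin
R026	antibiotic	benzoisochromanequinone	actinorhodin
R027	antibiotic	benzoisochromanequinone	granaticin
R028	antibiotic	benzoisochromanequinone	medermycin
R029	antibiotic	benzoisochromanequinone	actinorhodin
R030	antibiotic	tetracycline	oxytetracycline
R031	antibiotic	tetracycline	chlortetracycline
R032	antibiotic	tetracycline	dactylocycline
R033	antibiotic	tetracycline	oxytetracycline
R034	antibiotic	aureolic_acid	mithramycin
R035	antibiotic	aureolic_acid	chromomycin
R036	antibiotic	aureolic_acid	olivomycin
R037	antibiotic	aureolic_acid	mithramycin
R038	antibiotic	tetracenomycin	tetracenomycin
R039	antibiotic	tetracenomycin	elloramycin
R040	antibiotic	tetracenomycin	saintopin
R041	antibiotic	pradimicin	pradimicin
R042	antibiotic	pradimicin	benanomicin
R043	antibiotic	pradimicin	rubrofusarin
R044	antibiotic	pentangular_polyphenol	fasamycin
R045	antibiotic	pentangular_polyphenol	accramycin
R046	antibiotic	pentangular_polyphenol	naphthacemycin
R047	antibiotic	enterocin	enterocin
R048	antibiotic	enterocin	wailupemycin
R049	antibiotic	resistomycin	resistomycin
R050	antibiotic	resistomycin	resistoflavin
R051	antibiotic	fredericamycin	fredericamycin
R052	antibiotic	fredericamycin	lysolipin
R053	antibiotic	pluramycin	hedamycin
R054	antibiotic	pluramycin	pluramycin
R055	antibiotic	rubromycin	griseorhodin
R056	antibiotic	rubromycin	rubromycin
R057	antibiotic	chartreusin	chartreusin
R058	antibiotic	xantholipin	xantholipin
R059	antibiotic	lactonamycin	lactonamycin
R060	antibiotic	formicamycin	formicamycin
R061	antibiotic	arixanthomycin	arixanthomycin
R062	antibiotic	benastatin	benastatin
R063	antibiotic	oxanthromicin	oxanthromicin
R064	spore_pigment		spore_pigment_locus_1
R065	spore_pigment		spore_pigment_locus_2
R066	spore_pigment		spore_pigment_locus_3
R067	spore_pigment		spore_pigment_locus_4
R068	spore_pigment		spore_pigment_locus_5
R069	spore_pigment		spore_pigment_locus_6
R070	spore_pigment		spore_pigment_locus_7
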