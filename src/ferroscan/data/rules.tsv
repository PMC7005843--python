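rule_id	category	required_families	member_families	min_present	forbidden_families	scope
cyc2_cl1	iron_oxidation	cyc2_cluster1	-	-	-	gene
cyc2_cl2	iron_oxidation	cyc2_cluster2	-	-	-	gene
cyc1	iron_oxidation	cyc1	-	-	-	gene
sulfocyanin	iron_oxidation	sulfocyanin	-	-	-	gene
foxABC	iron_oxidation	-	foxA,foxB,foxC	2	-	neighborhood
foxEYZ	iron_oxidation	foxE	foxY,foxZ	1	-	neighborhood
pioAB	iron_oxidation	pioA,pioB	-	-	-	neighborhood
mtrCAB	iron_reduction	mtrC,mtrA,mtrB	-	-	-	neighborhood
mtrAB	probable_iron_reduction	mtrA,mtrB	-	-	mtrC	neighborhood
mtrCB	probable_iron_reduction	mtrC,mtrB	-	-	mtrA	neighborhood
mtoAB_mtrC	probable_iron_reduction	mtoA,mtrC	mtoB	0	-	neighborhood
mtoA_possible	possible_iron_oxidation_and_possible_iron_reduction	mtoA	mtoB	0	mtrC	neighborhood
cyc2_cl3	possible_iron_oxidation_and_possible_iron_reduction	cyc2_cluster3	-	-	-	gene
cymA	iron_reduction	cymA	-	-	-	gene
omcF	iron_reduction	omcF	-	-	-	gene
omcS	iron_reduction	omcS	-	-	-	gene
omcZ	iron_reduction	omcZ	-	-	-	gene
flavin	iron_reduction	-	fmnA,dmkA,fmnB,pplA,ndh2,eetA,eetB,dmkB	0.5	-	neighborhood
dfe_a	iron_reduction	-	dfe_0448,dfe_0449,dfe_0450,dfe_0451	3	-	neighborhood
dfe_b	iron_reduction	-	dfe_0461,dfe_0462,dfe_0463,dfe_0464,dfe_0465	3	-	neighborhood
slayer	iron_reduction	-	slayer_slp1,slayer_slp2	2	-	neighborhood
gpcc	iron_reduction	-	gpcc_ombB,gpcc_omaB,gpcc_omcB	2	-	neighborhood
mam	magnetosome_formation	-	mamA,mamB,mamE,mamK,mamL,mamM,mamO,mamP,mamQ,mamI	0.5	-	neighborhood
sid_operon	siderophore_synthesis	-	@category:siderophore_synthesis	2	-	neighborhood
transport_genes	iron_transport	-	@category:iron_transport	1	-	gene
heme_oxy	heme_oxygenase	-	@category:heme_oxygenase	1	-	gene
heme_trans	heme_transport	-	@category:heme_transport	1	-	gene
sid_transport	siderophore_transport	-	@category:siderophore_transport	1	-	gene
regulation	iron_gene_regulation	-	@category:iron_gene_regulation	1	-	gene
storage	iron_storage	-	@category:iron_storage	1	-	gene
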