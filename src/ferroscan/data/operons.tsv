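operon_id	members	min_fraction	anchors	partial_members	category_on_success	category_on_partial
mtrCAB	mtrC,mtrA,mtrB	1.0		mtrA+mtrB|mtrC+mtrB	iron_reduction	probable_iron_reduction
mam	mamA,mamB,mamE,mamK,mamL,mamM,mamO,mamP,mamQ,mamI	0.5			magnetosome_formation
foxABC	foxA,foxB,foxC	2/3			iron_oxidation
foxEYZ	foxE,foxY,foxZ	2/3	foxE		iron_oxidation
pioAB	pioA,pioB	1.0			iron_oxidation
flavin	fmnA,dmkA,fmnB,pplA,ndh2,eetA,eetB,dmkB	0.5			iron_reduction
dfe_0448_0451	dfe_0448,dfe_0449,dfe_0450,dfe_0451	3/4			iron_reduction
dfe_0461_0465	dfe_0461,dfe_0462,dfe_0463,dfe_0464,dfe_0465	3/5			iron_reduction
slayer	slayer_slp1,slayer_slp2	1.0			iron_reduction
gpcc	gpcc_ombB,gpcc_omaB,gpcc_omcB	2/3			iron_reduction
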