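"""Regenerates src/ferroscan/data/{manifest,operons,rules}.tsv.
Bit cutoffs for the toy skeleton models are frozen at half the model's
consensus self-score (deterministic given the family id).
"""
from ferroscan.family_db import toy_consensus
from ferroscan.profile_hmm import viterbi_bits
from ferroscan.synthetic_fixtures import make_toy_hmm
# family_id, category, method, operon_group, source, tags, min_length, min_heme
F = []
def fam(fid, cat, operon="", source="custom", tags="", min_len="", min_heme="", method="hmm"):
    F.append((fid, cat, method, operon, source, tags, min_len, min_heme))
# --- iron transport ---------------------------------------------------------
for f in ["efeUOB", "fbpABC", "sfuABC", "yfuABC", "feoA", "feoB",
          "futA1", "futA2", "futB", "futC", "yfeABCD"]:
    fam(f, "iron_transport")
# --- heme oxygenase ---------------------------------------------------------
for f in ["chuS", "chuZ", "hemO", "pigA", "hemRSTUV", "hmoB", "hmuO",
          "hugZ", "hupZ", "isd_LmHde", "isdG", "isdI", "mhuD", "phuS"]:
    fam(f, "heme_oxygenase")
# --- heme transport (incl. transferrin/lactoferrin receptors) ---------------
for f in ["hasRADEF", "hmuRSTUV", "hmuY", "hmuY_prime", "hutZ", "hxuCB", "phuRSTUVW"]:
    fam(f, "heme_transport")
for f in ["hasA", "hxuA", "isdX1", "isdX2", "rv0203"]:
    fam(f, "heme_transport", tags="hemophore")
for f in ["tbpAB", "sstABCD"]:
    fam(f, "heme_transport", tags="transferrin")
# --- siderophore synthesis --------------------------------------------------
for f in ["acsABCDEF", "amoA", "angR", "asbABCDEF", "dhbACEBF", "ent_fes",
          "iroD", "iucA", "iucC", "iutA", "mbtIJABCDEFGH", "lbtA",
          "pchABCDREFGHI", "pvdQAPMNOFEDJIHLGS", "pvsABCDE", "venB",
          "vab_system", "vib_system", "rhbABCDEF"]:
    fam(f, "siderophore_synthesis")
# --- siderophore transport --------------------------------------------------
for f in ["besA", "cbrABCD", "fatABCD", "fecIRABCDE", "feuABC_yusV",
          "fhuACDB", "fhuF", "fptABCX", "fpuAB", "fpuC", "fpuD",
          "fpvIR_fpvA", "fvtA", "hatCDB", "iroNBCDE", "lbtUABC", "pirA",
          "piuA", "pvuABCDE", "viu_system", "yfiZ_yfhA", "yfiY", "yqjH",
          "ybdA_fep"]:
    fam(f, "siderophore_transport")
for f in ["tonB", "exbB", "exbD"]:
    fam(f, "siderophore_transport", source="Pfam")
# --- regulation -------------------------------------------------------------
for f in ["dtxR", "fecR", "feoC", "ideR", "yqjI", "rhrA"]:
    fam(f, "iron_gene_regulation")
fam("fur", "iron_gene_regulation", source="Pfam")
# --- iron oxidation ---------------------------------------------------------
fam("cyc1", "iron_oxidation")
fam("cyc2_cluster1", "iron_oxidation", min_len="375", min_heme="1")
fam("cyc2_cluster2", "iron_oxidation", min_len="375", min_heme="1")
fam("sulfocyanin", "iron_oxidation")
for f in ["foxA", "foxB", "foxC"]:
    fam(f, "iron_oxidation", operon="foxABC")
for f in ["foxE", "foxY", "foxZ"]:
    fam(f, "iron_oxidation", operon="foxEYZ")
for f in ["pioA", "pioB"]:
    fam(f, "iron_oxidation", operon="pioAB")
fam("pioC", "iron_oxidation")
# --- possible oxidation / possible reduction --------------------------------
fam("mtoA", "possible_iron_oxidation_and_possible_iron_reduction", operon="mtoAB")
fam("mtoB", "possible_iron_oxidation_and_possible_iron_reduction", operon="mtoAB")
fam("cyc2_cluster3", "possible_iron_oxidation_and_possible_iron_reduction",
    min_len="375", min_heme="1")
# --- iron reduction ---------------------------------------------------------
fam("cymA", "iron_reduction")
for f in ["mtrC", "mtrA", "mtrB"]:
    fam(f, "iron_reduction", operon="mtrCAB")
for f in ["omcF", "omcS", "omcZ"]:
    fam(f, "iron_reduction")
for f in ["fmnA", "dmkA", "fmnB", "pplA", "ndh2", "eetA", "eetB", "dmkB"]:
    fam(f, "iron_reduction", operon="flavin")
for f in ["dfe_0448", "dfe_0449", "dfe_0450", "dfe_0451"]:
    fam(f, "iron_reduction", operon="dfe_0448_0451")
for f in ["dfe_0461", "dfe_0462", "dfe_0463", "dfe_0464", "dfe_0465"]:
    fam(f, "iron_reduction", operon="dfe_0461_0465")
for f in ["slayer_slp1", "slayer_slp2"]:
    fam(f, "iron_reduction", operon="slayer", method="homology")
for f in ["gpcc_ombB", "gpcc_omaB", "gpcc_omcB"]:
    fam(f, "iron_reduction", operon="gpcc", method="homology")
# --- storage ----------------------------------------------------------------
for f in ["bfr", "dpsA", "ftn"]:
    fam(f, "iron_storage", source="Pfam")
# --- magnetosome ------------------------------------------------------------
MAM = ["mamA", "mamB", "mamE", "mamK", "mamL", "mamM", "mamO", "mamP", "mamQ", "mamI"]
for f in MAM:
    fam(f, "magnetosome_formation", operon="mam")
# ---------------------------------------------------------------------------
rows = ["family_id\tcategory\tmethod\tmodel_ref\tcutoff\tmin_length\tmin_heme_motifs\toperon_group\tsource\ttags"]
for fid, cat, method, operon, source, tags, min_len, min_heme in F:
    if method == "hmm":
        cons = toy_consensus(fid, needs_heme_motif=bool(min_heme))
        hmm = make_toy_hmm(cons, match_prob=0.95)
        self_score = viterbi_bits(hmm, cons).bits
        cutoff = f"{0.5 * self_score:.1f}"
    else:
        cutoff = "1e-10"
    rows.append(f"{fid}\t{cat}\t{method}\t{fid}\t{cutoff}\t{min_len}\t{min_heme}\t{operon}\t{source}\t{tags}")
with open("src/ferroscan/data/manifest.tsv", "w") as fh:
    fh.write("\n".join(rows) + "\n")
print(f"manifest: {len(F)} families")
OPERONS = """operon_id	members	min_fraction	anchors	partial_members	category_on_success	category_on_partial
mtrCAB	mtrC,mtrA,mtrB	1.0		mtrA+mtrB|mtrC+mtrB	iron_reduction	probable_iron_reduction
mam	{mam}	0.5			magnetosome_formation
foxABC	foxA,foxB,foxC	2/3			iron_oxidation
foxEYZ	foxE,foxY,foxZ	2/3	foxE		iron_oxidation
pioAB	pioA,pioB	1.0			iron_oxidation
flavin	fmnA,dmkA,fmnB,pplA,ndh2,eetA,eetB,dmkB	0.5			iron_reduction
dfe_0448_0451	dfe_0448,dfe_0449,dfe_0450,dfe_0451	3/4			iron_reduction
dfe_0461_0465	dfe_0461,dfe_0462,dfe_0463,dfe_0464,dfe_0465	3/5			iron_reduction
slayer	slayer_slp1,slayer_slp2	1.0			iron_reduction
gpcc	gpcc_ombB,gpcc_omaB,gpcc_omcB	2/3			iron_reduction
""".format(mam=",".join(MAM))
with open("src/ferroscan/data/operons.tsv", "w") as fh:
    fh.write(OPERONS)
RULES = """rule_id	category	required_families	member_families	min_present	forbidden_families	scope
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
mam	magnetosome_formation	-	{mam}	0.5	-	neighborhood
sid_operon	siderophore_synthesis	-	@category:siderophore_synthesis	2	-	neighborhood
transport_genes	iron_transport	-	@category:iron_transport	1	-	gene
heme_oxy	heme_oxygenase	-	@category:heme_oxygenase	1	-	gene
heme_trans	heme_transport	-	@category:heme_transport	1	-	gene
sid_transport	siderophore_transport	-	@category:siderophore_transport	1	-	gene
regulation	iron_gene_regulation	-	@category:iron_gene_regulation	1	-	gene
storage	iron_storage	-	@category:iron_storage	1	-	gene
""".format(mam=",".join(MAM))
with open("src/ferroscan/data/rules.tsv", "w") as fh:
    fh.write(RULES)
print("operons + rules written")
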