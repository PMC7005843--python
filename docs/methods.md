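# Methods

## Scope and data model

`ferroscan` annotates predicted proteins from assembled genomes or
metagenomes for iron-related function. Inputs are nucleotide contigs
(ORFs then predicted by prodigal), protein FASTA in the ORF-caller
coordinate-header dialect (`>contig_N # start # end # strand # ...`), or
GenBank flat files with translated CDS features. All routes normalise to
the same objects: `GeneCall` (1-based inclusive coordinates on the forward
strand; an ordinal gene `index` per contig, assigned by start coordinate)
and `SampleInput` (ordered gene calls plus `orf_count`, the normalisation
denominator). The ordinal index — not nucleotide distance — is the unit of
all neighborhood logic, because operon context in this method is
positional. Plain protein FASTA without coordinates is accepted, but each
gene then sits on a singleton pseudo-contig, multi-gene rules cannot fire,
and a warning says so. Genes truncated at contig edges receive no special
handling. Stop-codon characters are stripped before scoring.

## Profile-HMM scoring

Family models are profile HMMs in HMMER3 ASCII (the parser covers the
header, COMPO, node lines and `//`; only the amino alphabet). Scoring is a
uni-local (Smith–Waterman-style) Viterbi in log2 space:

* entry into any match state with uniform probability 1/M (an entry cost
  of log2 M bits), free exit from any match state;
* insert and delete states interior to the alignment, with the model's
  own transition probabilities;
* flanking residues emitted by the null model, contributing 0 bits;
* no bias/composition ("null2") correction.

The reported score is the maximum alignment log-odds in bits. Acceptance
is `score ≥ τ_family`, a calibrated per-family cutoff carried by the
manifest — the method's contract is the per-family threshold, not a
universal scale, which is why a consistent in-house score with per-model
cutoffs preserves the semantics regardless of engine. Cutoffs here are
defined against this full-sequence local score. Residues outside the
20-letter alphabet (X, B, Z, U, O…) score 0 bits everywhere. An adapter
seam (any scorer producing `HmmScore`s can be substituted) allows an
external search engine with identical cutoff semantics.

The dynamic program is verified against an independent oracle that
enumerates every legal local path for small models (M ≤ 4) and short
sequences and takes the maximum log-odds directly; the two agree to
1e-9 bits over 200+ randomised cases. The inner DP loop is JIT-compiled
with numba so that scoring all genes of a sample against the full
~150-family library takes well under a second.

## Homology fallback

Families without reliable HMMs (S-layer proteins implicated in iron
reduction, Geobacter-type porin–cytochrome operon members) are detected by
local alignment against curated reference proteins: BLOSUM62, affine gap
penalties 11/1 (a gap of length k costs 11 + k), run in-process through
Biopython's `PairwiseAligner`. Raw scores scale to bits with the published
gapped Karlin–Altschul constants for BLOSUM62 11/1 (λ = 0.267, K = 0.041,
recorded in the default configuration), and

    E = m · n · 2^(−bits)

with m the query length and n the summed reference length; no edge or
length corrections, which are immaterial at the default acceptance
threshold E ≤ 1e-10. The best reference per gene is kept. The contract is
the e-value cutoff; an external aligner can stand behind the same
interface.

## Family manifest and the 12-category schema

The manifest (TSV) binds each family to: category (one of 12 fixed
labels), method (`hmm`/`homology`), model reference, cutoff (bits or
e-value — exactly one, matching the method), optional `min_length` and
`min_heme_motifs` floors, an optional operon group, source and tags.
Twelve categories: iron_transport, heme_oxygenase, heme_transport,
siderophore_synthesis, siderophore_transport, iron_gene_regulation,
iron_oxidation, possible_iron_oxidation_and_possible_iron_reduction,
iron_reduction, probable_iron_reduction, iron_storage,
magnetosome_formation. Transferrin/lactoferrin receptor families are
filed under heme_transport (tagged `transferrin`), keeping the schema at
twelve; probable_iron_reduction has no standalone families — it is
produced only by partial-operon rules.

The shipped manifest is a skeleton of the published family table:
~150 named families with the real ids, categories, operon groups, the
hemophore five (IsdX1, IsdX2, HasA, HxuA, Rv0203), the three Cyc2 cluster
models, and the Cyc2 filter encoded as data (`min_length=375,
min_heme_motifs=1`). Its models are *toy stand-ins*: for each family a
deterministic 18-residue consensus is drawn from a seed derived from the
family id (families with a heme-motif floor get exactly one CxxCH embedded
and no other cysteine), wrapped in a profile HMM with dominant match
probability 0.95, M→M transition 0.9 and uniform background; homology
families get synthetic 250-aa reference sequences the same way. Each toy
family's bit cutoff is frozen in the manifest at half its consensus
self-score (≈ 35 bits against a ≈ 70-bit self-score), far above chance
scores of unrelated sequences (≈ 10–15 bits) — so at fixture scale
separation is effectively deterministic. Real curated libraries mount via
`load_manifest(manifest, model_dir)`.

## Heme motifs and the Cyc2 filter

The canonical c-type heme-binding motif is fixed to CxxCH only; counting
is non-overlapping, scanning left to right. Variant motifs
(CxxxCH, CxxxxCH) are deliberately excluded; extending the motif set is a
configuration change, not code. Cyc2 candidates must carry ≥ 1 motif and
be ≥ 375 aa — long enough to encode the fused outer-membrane porin — and
this is enforced through the generic manifest floors, so any family can
opt into the same filters. Heme-motif floors are applied only to families
that declare them; other multiheme families (MtrA, OmcS, …) are not
filtered beyond their bit cutoffs.

## Best-hit resolution

All passing (gene, family) candidates are ranked by margin — bits above
cutoff for HMM hits, log10(cutoff/E) for homology hits; the top candidate
becomes the gene's primary annotation (ties: HMM beats homology, then
lexicographic family id). Secondary passing families are retained on the
annotation because operon rules must see co-located families even when a
gene's primary label differs.

## Neighborhoods and rules

Neighborhoods are connected components of annotated genes on one contig
linked when their ordinal indices differ by ≤ `max_gap` (default 3 — the
geometry is not specified by the method's source, and 3 tolerates small
insertions while keeping operons local; configurable). No strand or
intergenic-distance constraints are imposed.

The ruleset is a TSV (rule id, category, required families, member
families, min-present count or fraction, forbidden families, scope) and
the shipped default codifies the published main-text logic:

* iron_oxidation — cyc2_cluster1/2, sulfocyanin, cyc1 gene-level;
  foxABC at ≥ 2/3 co-located; foxE plus ≥ 1 of foxY/foxZ; pioA+pioB.
* possible oxidation/reduction — mtoA (with or without mtoB) away from
  mtrC; cyc2_cluster3.
* iron_reduction — complete mtrCAB in one neighborhood; cymA;
  omcF/omcS/omcZ; the 8-gene flavin operon at ≥ 50 %; DFE_0448–0451 at
  ≥ 3/4; DFE_0461–0465 at ≥ 3/5; S-layer or porin–cytochrome fallback
  hits with ≥ 2 operon members co-located.
* probable_iron_reduction — mtrAB without mtrC; mtrCB without mtrA;
  mtoAB with co-located mtrC.
* magnetosome_formation — ≥ 5 of the 10 mam markers
  (MamA,B,E,K,L,M,O,P,Q,I) in one neighborhood; mamL stays in the
  10-marker denominator even though it is magnetite-specific.
* siderophore_synthesis — ≥ 2 distinct synthesis families co-located is
  an operon call; singletons are gene-level calls flagged
  `low_confidence`.
* every other category — each accepted annotation yields a gene-level
  call.

Complete-operon rules shadow their partial fallbacks declaratively via
forbidden-family lists (the mtrAB rule forbids mtrC), so evaluation order
never matters and one neighborhood can never yield both the complete and
the partial verdict from the same evidence. Rule evaluation is a pure
function of (neighborhoods, ruleset). Operon rules demand co-location
within a single neighborhood, not genome-wide co-occurrence.

## Comparative summaries

The category × sample matrix counts distinct evidence genes per category
(a gene counts once per category, even when cited by several rules).
Normalisation is 100·count/orf_count. For clustering, rows of the
normalised matrix are z-scored with the sample (n−1) standard deviation
(constant rows map to zero; z-scoring normalised values rather than raw
counts is the default and configurable). Samples are clustered with
Ward's method on Euclidean distances (scipy's variance-minimising
Lance–Williams update); columns are sorted by sample id first, so the
tree is invariant to input order. Cluster uncertainty uses an *ordinary*
bootstrap over category rows (resampled with replacement, B replicates,
seeded): a node's support is the percentage of replicate trees containing
its exact leaf set. This replaces multiscale-bootstrap AU p-values — the
stated purpose is to assess clustering uncertainty, which plain support
percentages serve — and the root's support is 100 by construction.
Support is omitted with fewer than 3 samples. Exports: matrix TSV,
long-format dot-plot TSV, Newick with support as internal labels
(numeric output at 6 significant digits), optional rendered PNGs.

## Calibration utilities

The desk-scale pieces of library construction are implemented and tested:

* homolog filtering at ≥ 35 % identity over ≥ 70 % of the query length
  (inclusive boundaries);
* dereplication at 70 % global identity — greedy by descending length
  (stable for equal lengths), identity defined as matches over global
  alignment columns under the same BLOSUM62 11/1 parameters, since the
  original clustering tool's identity definition is not stated;
* per-model cutoff selection from labelled true/false-positive scores:
  the smallest true score when classes are separable, otherwise the
  observed score maximising balanced accuracy with ties resolved to the
  larger threshold (favouring precision). The original calibration was
  manual inspection; this deterministic criterion is a declared stand-in
  chosen for testability, not a claim about the original choices.

Seed-sequence gathering against public databases, multiple alignment and
`hmmbuild` remain an external recipe.

## Synthetic fixtures

`synthetic_fixtures` generates everything tests consume: toy HMMs,
emitted proteins (generative glocal walks), and whole protein samples
with planted operons plus truth labels and the exact category calls the
engine must produce. Background genes are i.i.d. draws from the
background distribution, 80–450 aa, so both sides of the 375-aa Cyc2
boundary occur. Planted genes are emissions from their family's toy
model; the generator guarantees detectability (bounded resampling until
the emission clears the family cutoff and any heme-motif floor, falling
back to the consensus core) so planted-operon recovery is exact at any
seed — this is the generator's contract, documented so that a failure is
always attributable to the pipeline, never to generator noise. Planted
blocks on one contig must be separated by more than `max_gap` indices so
truth expectations stay per-block. Fixture files use exactly the formats
the readers consume; truth sets serialise to JSON.

What passing fixture tests do *not* show: performance on real, divergent
homologs (toy models have a single dominant consensus), behaviour of the
real calibrated cutoffs, nucleotide-level gene structure, or sequencing
error. They do show that parsing, scoring, filtering, neighborhood logic,
the rule engine and the summaries compose correctly and deterministically.

## Problem sizes and numerical choices

Default test and acceptance runs use 2-contig, 10–12-gene samples against
the ~150-family library, 101-length Cyc2 sweeps, 100-replicate (tests: 20–
100) bootstraps, and 200+ oracle cases — sizes chosen so the full suite
completes in seconds while still exercising every boundary (374/375 aa,
4/5 of 10 mam markers, 2/3 operon fractions). Probability sums are
validated to 1e-6 (1e-3 for rounded file input, then renormalised);
oracle agreement to 1e-9 bits; fraction thresholds compared with a 1e-12
slack so 3/5-style fractions behave exactly. Ties everywhere resolve
lexicographically or toward precision, and every source of randomness is
an explicit seed.

## Known limitations

The shipped models are synthetic skeletons — real annotation requires
mounting the curated HMM library and reference sets. The e-value model
omits composition statistics and edge corrections. The rule engine
implements the main-text logic; the method's full supplementary rule
table may contain refinements not reproduced here, and the ruleset file
is the place to add them. Neighborhood geometry (max_gap) is a modelling
choice, not a published constant.
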