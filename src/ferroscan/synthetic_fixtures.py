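"""Deterministic synthetic fixtures: toy HMMs, emitted proteins, planted genomes.

Everything the pipeline consumes can be generated here from a seed — toy
profile HMMs standing in for the real curated family models, proteins
emitted from those models, and whole synthetic protein samples in which
iron-gene operons are planted at known positions together with the truth
labels and the category calls the rule engine must recover.

Planted genes are emissions from their family's toy model (dominant match
probability 0.95, so separation from background is near-deterministic).
The generator additionally *guarantees* detectability: each planted gene is
re-sampled (bounded retries, then the model consensus itself) until it
scores above its family's bit cutoff and satisfies the family's heme-motif
floor, so planted-operon recovery is exact at any seed.  Background genes
are i.i.d. draws from the background residue distribution.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profile_hmm import AMINO_ALPHABET, ProfileHMM, viterbi_bits
from .sequence_io import GeneCall, SampleInput

_NO_CYS = AMINO_ALPHABET.replace("C", "")
HEME_MOTIF_CORE = "CAACH"  # one concrete instance of the CxxCH motif


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string/int parts."""
    h = 0
    for p in parts:
        h = zlib.crc32(str(p).encode(), h)
    return h & 0x7FFFFFFF


def make_toy_hmm(consensus: str, match_prob: float = 0.95, seed: int = 0) -> ProfileHMM:
    """Build a toy profile HMM around a consensus sequence.

    Match state i emits ``consensus[i]`` with probability ``match_prob`` and
    every other residue uniformly; transitions strongly favour match→match
    (0.9).  Insert emissions equal the uniform background.  ``seed`` is
    accepted for interface symmetry with the other generators; the model is
    a pure function of (consensus, match_prob).
    """
    if not 0.5 < match_prob <= 1.0:
        raise ValueError(f"match_prob must be in (0.5, 1], got {match_prob}")
    if not consensus:
        raise ValueError("consensus must be non-empty")
    consensus = consensus.upper()
    M = len(consensus)
    match = np.full((M, 20), (1.0 - match_prob) / 19.0)
    for i, aa in enumerate(consensus):
        j = AMINO_ALPHABET.index(aa)
        match[i, :] = (1.0 - match_prob) / 19.0
        match[i, j] = match_prob
    insert = np.full((M, 20), 0.05)
    trans = np.tile(np.array([0.9, 0.05, 0.05, 0.9, 0.1, 0.9, 0.1]), (M, 1))
    hmm = ProfileHMM(
        name="toy",
        match_emit=match,
        insert_emit=insert,
        trans=trans,
        background=np.full(20, 0.05),
    )
    hmm.validate()
    return hmm


def emit_proteins(hmm: ProfileHMM, n: int, seed: int = 0) -> list[str]:
    """Sample ``n`` proteins from the model's generative path (glocal walk)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ALPHABET))
    out = []
    for _ in range(n):
        residues: list[str] = []
        i, state = 0, "M"
        while i < hmm.M:
            if state == "M":
                residues.append(rng.choice(aa, p=hmm.match_emit[i]))
                nxt = rng.choice(3, p=hmm.trans[i, :3])  # MM, MI, MD
                state = ("M", "I", "D")[nxt]
                if state != "I":
                    i += 1
            elif state == "I":
                residues.append(rng.choice(aa, p=hmm.insert_emit[i]))
                nxt = rng.choice(2, p=hmm.trans[i, 3:5])  # IM, II
                if nxt == 0:
                    state = "M"
                    i += 1
            else:  # D
                nxt = rng.choice(2, p=hmm.trans[i, 5:7])  # DM, DD
                state = "M" if nxt == 0 else "D"
                i += 1
        out.append("".join(residues))
    return [s if s else "".join(rng.choice(aa, size=1)) for s in out]


def background_protein(length: int, rng: np.random.Generator, background=None, no_cys: bool = False) -> str:
    alphabet = _NO_CYS if no_cys else AMINO_ALPHABET
    if background is None or no_cys:
        return "".join(rng.choice(list(alphabet), size=length))
    return "".join(rng.choice(list(AMINO_ALPHABET), p=background, size=length))


@dataclass(frozen=True)
class PlantedOperon:
    """Placement of family genes on a fixture contig.

    ``members`` are family ids planted at consecutive gene indices starting
    at ``start_index`` on contig number ``contig`` (1-based).
    """

    members: tuple[str, ...]
    contig: int = 1
    start_index: int = 1


@dataclass
class FixtureSpec:
    seed: int = 1
    n_contigs: int = 1
    genes_per_contig: int = 12
    planted: list[PlantedOperon] = field(default_factory=list)
    background_length_range: tuple[int, int] = (80, 450)

    def validate(self, max_gap: int = 3) -> None:
        by_contig: dict[int, list[tuple[int, int]]] = {}
        for p in self.planted:
            if not 1 <= p.contig <= self.n_contigs:
                raise ValueError(f"planted contig {p.contig} outside 1..{self.n_contigs}")
            if p.start_index < 1 or p.start_index + len(p.members) - 1 > self.genes_per_contig:
                raise ValueError("planted genes fall outside the contig's gene range")
            by_contig.setdefault(p.contig, []).append(
                (p.start_index, p.start_index + len(p.members) - 1)
            )
        # planted blocks on one contig must not merge into one neighborhood,
        # otherwise the per-block truth expectations would be wrong
        for spans in by_contig.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 - e1 <= max_gap:
                    raise ValueError(
                        "planted blocks on one contig are closer than max_gap; "
                        "separate them so neighborhoods stay distinct"
                    )


@dataclass
class TruthSet:
    """Ground truth for a built fixture.

    ``gene_labels`` maps gene_id -> planted family id.  ``expected_calls``
    is the exact multiset of category calls the rule engine must emit, each
    as ``(category, frozenset of evidence family ids, contig_id)``.
    """

    gene_labels: dict[str, str] = field(default_factory=dict)
    expected_calls: list[tuple[str, frozenset, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_labels": self.gene_labels,
                "expected_calls": [
                    {"category": c, "families": sorted(f), "contig": ct}
                    for c, f, ct in self.expected_calls
                ],
            },
            indent=1,
            sort_keys=True,
        )


_MAX_RESAMPLE = 20


def _planted_protein(family, db, rng: np.random.Generator) -> str:
    """Emit a detectable protein for one family (see module docstring)."""
    from .annotate import count_heme_motifs  # local import to avoid a cycle

    min_len = family.min_length or 0
    min_heme = family.min_heme_motifs or 0

    if family.method == "homology":
        refs = db.references_for(family.family_id)
        core = next(iter(refs.values()))
        seq = list(core)
        n_mut = max(1, len(seq) // 20)  # ~5% point mutations
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            seq[pos] = rng.choice(list(AMINO_ALPHABET))
        protein = "".join(seq)
    else:
        hmm = db.hmm_for(family.family_id)
        protein = None
        for attempt in range(_MAX_RESAMPLE):
            cand = emit_proteins(hmm, 1, seed=int(rng.integers(1 << 31)))[0]
            cand = _apply_family_floors(cand, family, rng, min_len, min_heme)
            if viterbi_bits(hmm, cand).bits >= family.bit_cutoff and count_heme_motifs(cand) >= min_heme:
                protein = cand
                break
        if protein is None:
            protein = _apply_family_floors(db.consensus_for(family.family_id), family, rng, min_len, min_heme)
    if min_len and len(protein) < min_len:
        protein += background_protein(min_len - len(protein), rng, no_cys=min_heme > 0)
    return protein


def _apply_family_floors(cand: str, family, rng, min_len: int, min_heme: int) -> str:
    from .annotate import count_heme_motifs

    if min_heme and count_heme_motifs(cand) < min_heme:
        # restore the motif core at its consensus position (middle of the gene)
        mid = max(0, len(cand) // 2 - 2)
        cand = cand[:mid] + HEME_MOTIF_CORE + cand[mid + 5 :]
    if min_len and len(cand) < min_len:
        cand = cand + background_protein(min_len - len(cand), rng, no_cys=min_heme > 0)
    return cand


def build_fixture(spec: FixtureSpec, db, outdir: str | Path | None = None):
    """Build one synthetic protein sample with planted iron genes.

    Returns ``(sample, truth)``; when ``outdir`` is given also writes the
    sample as coordinate-header protein FASTA plus the truth set as JSON.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plant_map: dict[tuple[int, int], str] = {}
    for op in spec.planted:
        for k, fam in enumerate(op.members):
            if fam not in db.records:
                raise ValueError(f"planted family {fam!r} not in database")
            key = (op.contig, op.start_index + k)
            if key in plant_map:
                raise ValueError(f"two families planted at contig {key[0]} index {key[1]}")
            plant_map[key] = fam

    truth = TruthSet()
    genes: list[GeneCall] = []
    lo, hi = spec.background_length_range
    for c in range(1, spec.n_contigs + 1):
        contig_id = f"c{c}"
        pos = 1
        for i in range(1, spec.genes_per_contig + 1):
            gene_id = f"{contig_id}_{i}"
            fam = plant_map.get((c, i))
            if fam is not None:
                protein = _planted_protein(db.records[fam], db, rng)
                truth.gene_labels[gene_id] = fam
            else:
                protein = background_protein(int(rng.integers(lo, hi + 1)), rng)
            start = pos
            end = start + 3 * len(protein) + 2
            pos = end + int(rng.integers(1, 200))
            genes.append(
                GeneCall(
                    gene_id=gene_id, contig_id=contig_id, index=i, protein=protein,
                    start=start, end=end, strand="+",
                )
            )
    sample = SampleInput(sample_id=f"fixture_seed{spec.seed}", genes=genes, orf_count=len(genes))
    truth.expected_calls = _expected_calls(spec, db)

    if outdir is not None:
        from .sequence_io import write_protein_calls

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_protein_calls(sample, outdir / f"{sample.sample_id}.faa")
        (outdir / f"{sample.sample_id}.truth.json").write_text(truth.to_json())
    return sample, truth


# categories whose accepted annotations each yield a gene-level call
GENE_LEVEL_CATEGORIES = frozenset(
    {
        "iron_transport",
        "heme_oxygenase",
        "heme_transport",
        "siderophore_transport",
        "iron_gene_regulation",
        "iron_storage",
    }
)
_SINGLE_GENE_REDOX = {
    "cyc2_cluster1": "iron_oxidation",
    "cyc2_cluster2": "iron_oxidation",
    "cyc1": "iron_oxidation",
    "sulfocyanin": "iron_oxidation",
    "cyc2_cluster3": "possible_iron_oxidation_and_possible_iron_reduction",
    "cymA": "iron_reduction",
    "omcF": "iron_reduction",
    "omcS": "iron_reduction",
    "omcZ": "iron_reduction",
}


def _expected_calls(spec: FixtureSpec, db) -> list[tuple[str, frozenset, str]]:
    """Independent expectation of the rule engine's output on this fixture.

    Derived from the operon definitions and category semantics directly (not
    from the ruleset file), covering the family types the fixtures plant.
    """
    calls: list[tuple[str, frozenset, str]] = []
    for op in spec.planted:
        contig_id = f"c{op.contig}"
        present = set(op.members)
        # operon-level expectations from the database's operon definitions
        for od in db.operons.values():
            inter = present & set(od.member_families)
            if not inter:
                continue
            frac = len(inter) / len(od.member_families)
            if frac >= od.min_fraction - 1e-12 and od.anchors <= inter:
                calls.append((od.category_on_success, frozenset(inter), contig_id))
            elif od.category_on_partial and od.partial_trigger(inter):
                calls.append((od.category_on_partial, frozenset(inter), contig_id))
        # mtoA: ambiguous redox alone, probable reduction when next to mtrC
        if "mtoA" in present:
            ev = present & {"mtoA", "mtoB"}
            if "mtrC" in present:
                calls.append(("probable_iron_reduction", frozenset(ev | {"mtrC"}), contig_id))
            else:
                calls.append(("possible_iron_oxidation_and_possible_iron_reduction", frozenset(ev), contig_id))
        # standalone redox markers (gene-scope rules fire unconditionally)
        for fam in sorted(present):
            if fam in _SINGLE_GENE_REDOX:
                calls.append((_SINGLE_GENE_REDOX[fam], frozenset({fam}), contig_id))
        # siderophore synthesis co-location
        synth = {f for f in present if db.records[f].category == "siderophore_synthesis"}
        if len(synth) >= 2:
            calls.append(("siderophore_synthesis", frozenset(synth), contig_id))
        elif len(synth) == 1:
            calls.append(("siderophore_synthesis", frozenset(synth), contig_id))  # low-confidence singleton
        # plain gene-level categories
        for fam in sorted(present):
            cat = db.records[fam].category
            if cat in GENE_LEVEL_CATEGORIES:
                calls.append((cat, frozenset({fam}), contig_id))
    return calls
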