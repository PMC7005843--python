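"""Per-gene detection: HMM scoring, homology fallback, motif/length filters.

Every gene is scored against every HMM family (local Viterbi bits against
the family's calibrated cutoff) and every homology family (local alignment
against reference proteins with an e-value cutoff).  Family-specific
filters from the manifest are applied next — the published Cyc2 rule
(a c-type heme-binding motif plus length ≥ 375 aa) is simply the manifest
instance ``min_heme_motifs=1, min_length=375``.  Finally the passing hits
for each gene are resolved into one primary annotation; all other passing
families are retained because the neighborhood rules need co-located
families even when a gene's primary label differs.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .config import get_default
from .family_db import FamilyDatabase, FamilyRecord
from .homology_fallback import fallback_search
from .profile_hmm import HmmScore, viterbi_bits
from .sequence_io import GeneCall, SampleInput

# canonical c-type heme-binding motif C-x-x-C-H; re.finditer scans left to
# right and never overlaps matches, which is exactly the counting rule
_HEME_RE = re.compile(r"C..CH")


def count_heme_motifs(protein: str) -> int:
    """Number of non-overlapping CxxCH motifs, scanned left to right."""
    if not protein:
        raise ValueError("empty protein sequence")
    return sum(1 for _ in _HEME_RE.finditer(protein.upper()))


def cyc2_accept(candidate: HmmScore, gene: GeneCall) -> bool:
    """The Cyc2 acceptance filter: >= 1 heme motif and length >= 375 aa.

    ``candidate`` must already have passed its bit cutoff; the filter adds
    the motif-and-length requirement that compensates for the highly
    divergent porin domain of Cyc2.
    """
    return count_heme_motifs(gene.protein) >= 1 and gene.length >= 375


@dataclass(frozen=True)
class Candidate:
    """One passing (gene, family) match before best-hit resolution."""

    family_id: str
    category: str
    method: str  # hmm | homology
    score: float  # bits (hmm) or evalue (homology)
    cutoff: float
    margin: float  # bits above cutoff, or log10(cutoff/evalue)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    contig_id: str
    index: int
    family_id: str
    category: str
    method: str
    score: float
    cutoff: float
    margin: float
    heme_motif_count: int
    length: int
    protein: str = field(repr=False, default="")
    also_passing: tuple[str, ...] = ()
    flags: frozenset = frozenset()

    @property
    def families(self) -> frozenset:
        """Primary plus secondary passing family ids at this gene."""
        return frozenset((self.family_id, *self.also_passing))


def _passes_family_filters(fam: FamilyRecord, gene: GeneCall) -> bool:
    if fam.min_length is not None and gene.length < fam.min_length:
        return False
    if fam.min_heme_motifs is not None and count_heme_motifs(gene.protein) < fam.min_heme_motifs:
        return False
    return True


def resolve_best(candidates: list[Candidate]) -> tuple[Candidate | None, list[Candidate]]:
    """Pick the primary hit; ties prefer hmm over homology, then family id."""
    if not candidates:
        return None, []
    ordered = sorted(
        candidates,
        key=lambda c: (-c.margin, 0 if c.method == "hmm" else 1, c.family_id),
    )
    return ordered[0], ordered[1:]


def annotate_sample(sample: SampleInput, db: FamilyDatabase) -> list[GeneAnnotation]:
    """Annotate every gene of a sample against the full family database.

    Output is ordered by (contig, gene index) and is invariant to the input
    order of genes and families; no annotation falls below its family
    cutoff.
    """
    if not sample.genes:
        warnings.warn(f"sample {sample.sample_id}: no genes to annotate", stacklevel=2)
        return []

    per_gene: dict[str, list[Candidate]] = {g.gene_id: [] for g in sample.genes}
    filtered_flags: dict[str, set[str]] = {g.gene_id: set() for g in sample.genes}

    hmm_fams = db.hmm_families()
    for gene in sample.genes:
        for fam in hmm_fams:
            score = viterbi_bits(db.hmm_for(fam.family_id), gene.protein)
            if not (score.cutoff is not None and score.bits >= fam.bit_cutoff):
                continue
            if not _passes_family_filters(fam, gene):
                if fam.family_id.startswith("cyc2"):
                    filtered_flags[gene.gene_id].add("cyc2_filtered")
                continue
            per_gene[gene.gene_id].append(
                Candidate(fam.family_id, fam.category, "hmm",
                          score.bits, fam.bit_cutoff, score.bits - fam.bit_cutoff)
            )

    default_ev = get_default("homology", "evalue_cutoff")
    gene_map = {g.gene_id: g for g in sample.genes}
    for fam in db.homology_families():
        cutoff = fam.evalue_cutoff if fam.evalue_cutoff is not None else default_ev
        for hit in fallback_search(sample, fam, db.references_for(fam.family_id)):
            gene = gene_map[hit.query_id]
            if not _passes_family_filters(fam, gene):
                continue
            ev = max(hit.evalue, 1e-300)
            per_gene[hit.query_id].append(
                Candidate(fam.family_id, fam.category, "homology",
                          hit.evalue, cutoff, math.log10(cutoff / ev))
            )

    annotations: list[GeneAnnotation] = []
    for gene in sorted(sample.genes, key=lambda g: (g.contig_id, g.index)):
        primary, rest = resolve_best(per_gene[gene.gene_id])
        if primary is None:
            continue
        flags = set(filtered_flags[gene.gene_id])
        if primary.method == "homology":
            flags.add("fallback_hit")
        annotations.append(
            GeneAnnotation(
                gene_id=gene.gene_id,
                contig_id=gene.contig_id,
                index=gene.index,
                family_id=primary.family_id,
                category=primary.category,
                method=primary.method,
                score=primary.score,
                cutoff=primary.cutoff,
                margin=primary.margin,
                heme_motif_count=count_heme_motifs(gene.protein),
                length=gene.length,
                protein=gene.protein,
                also_passing=tuple(sorted({c.family_id for c in rest})),
                flags=frozenset(flags),
            )
        )
    return annotations


_CSV_COLUMNS = [
    "sample", "contig", "gene_id", "index", "family_id", "category",
    "score", "cutoff", "margin", "heme_motifs", "length", "flags",
    "protein_sequence",
]


def write_annotations_csv(
    annotations: list[GeneAnnotation], sample_id: str, path: str | Path, append: bool = False
) -> None:
    """Write the per-gene annotation table (the tool's primary CSV output)."""
    mode = "a" if append else "w"
    write_header = not (append and Path(path).exists() and Path(path).stat().st_size > 0)
    with open(path, mode, newline="") as fh:
        writer = csv.writer(fh)
        if write_header:
            writer.writerow(_CSV_COLUMNS)
        for a in annotations:
            writer.writerow([
                sample_id, a.contig_id, a.gene_id, a.index, a.family_id, a.category,
                f"{a.score:.6g}", f"{a.cutoff:.6g}", f"{a.margin:.6g}",
                a.heme_motif_count, a.length, ";".join(sorted(a.flags)), a.protein,
            ])
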