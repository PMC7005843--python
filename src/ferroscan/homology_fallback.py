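"""Pairwise local-alignment fallback for families without reliable profile HMMs.

A handful of iron-reduction marker families (Thermincola-type S-layer
proteins, Geobacter porin–cytochrome operon members) are detected by direct
local alignment against curated reference proteins instead of an HMM.  The
contract is the e-value acceptance threshold (default 1e-10); alignment runs
in-process (BLOSUM62, affine gaps 11/1) through Biopython's PairwiseAligner,
with e-values from the Karlin–Altschul gapped scaling constants recorded in
the default configuration.  The search space for a query of length m against
a reference set with n total residues is m·n, with no edge corrections —
immaterial at a 1e-10 cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .config import get_default


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    reference_id: str
    raw_score: float
    bits: float
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open on the query
    reference_span: tuple[int, int]


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.mode = "local"
    # Biopython convention: opening a gap costs open+extend in total
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def smith_waterman(
    query: str,
    target: str,
    matrix: str | None = None,
    gap_open: float | None = None,
    gap_extend: float | None = None,
) -> AlignmentHit:
    """Optimal local alignment of two proteins under affine gap penalties.

    Returns the raw substitution-matrix score, the scaled bit score, and the
    aligned spans of the optimal alignment (Biopython's deterministic first
    traceback).  An all-negative scoring space yields score 0 with empty
    spans (the empty local alignment).
    """
    if not query or not target:
        raise ValueError("smith_waterman requires two non-empty sequences")
    cfg = get_default("homology")
    matrix = matrix or cfg["matrix"]
    gap_open = cfg["gap_open"] if gap_open is None else gap_open
    gap_extend = cfg["gap_extend"] if gap_extend is None else gap_extend
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = _aligner(matrix, float(gap_open), float(gap_extend))
    score = aligner.score(query, target)
    if score <= 0:
        return AlignmentHit("query", "target", 0.0, _bits_from_raw(0.0), math.inf, (0, 0), (0, 0))
    aln = next(iter(aligner.align(query, target)))
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    bits = _bits_from_raw(float(score))
    return AlignmentHit("query", "target", float(score), bits, math.inf, qspan, tspan)


def _bits_from_raw(raw: float) -> float:
    """Karlin–Altschul scaling: bits = (lambda*S - ln K) / ln 2."""
    lam = get_default("homology", "lambda")
    K = get_default("homology", "K")
    return (lam * raw - math.log(K)) / math.log(2)


def evalue_from_bits(bits: float, m: int, n: int) -> float:
    """Expected chance hits at this bit score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return m * n * 2.0 ** (-bits)


def fallback_search(sample, family, references: dict[str, str]) -> list[AlignmentHit]:
    """Search every gene of ``sample`` against a family's reference proteins.

    ``references`` maps reference id -> protein sequence.  Hits with e-value
    at or below the family cutoff (default 1e-10) are retained, keeping only
    the best reference per gene.
    """
    if not references:
        raise ValueError(f"family {family.family_id}: empty reference set")
    cutoff = family.evalue_cutoff
    if cutoff is None:
        cutoff = get_default("homology", "evalue_cutoff")
    total_ref = sum(len(s) for s in references.values())
    hits: list[AlignmentHit] = []
    for gene in sample.genes:
        best: AlignmentHit | None = None
        for ref_id, ref_seq in references.items():
            h = smith_waterman(gene.protein, ref_seq)
            ev = evalue_from_bits(h.bits, len(gene.protein), total_ref)
            h = AlignmentHit(gene.gene_id, ref_id, h.raw_score, h.bits, ev, h.query_span, h.reference_span)
            if best is None or h.evalue < best.evalue:
                best = h
        if best is not None and best.evalue <= cutoff:
            hits.append(best)
    return hits
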