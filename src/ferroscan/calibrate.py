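"""Model-library construction computations: homolog filtering, dereplication,
and per-model bit-score cutoff selection.

These are the desk-scale pieces of the database-building recipe: gathering
homologs of each curated seed sequence (kept at >= 35% identity over >= 70%
of the query length), collapsing the gathered set at 70% identity so
overrepresented sequences do not bias the model, and choosing each model's
bit-score acceptance cutoff from labelled true/false-positive scores.  The
surrounding steps — seed gathering against public databases, multiple
alignment, and model building — require external databases and an external
aligner and are documented rather than implemented.

"Optimally delineating" true from false positives is operationalised as the
threshold (among observed scores) maximising balanced accuracy, ties broken
toward the larger threshold (favouring precision); when the classes are
separable the cutoff is simply the smallest true-positive score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .config import get_default


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    percent_identity: float  # 0..100
    query_coverage: float  # 0..1

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(f"percent_identity outside [0, 100]: {self.percent_identity}")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(f"query_coverage outside [0, 1]: {self.query_coverage}")


@dataclass(frozen=True)
class LabeledScores:
    true_scores: tuple[float, ...]
    false_scores: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.true_scores:
            raise ValueError("at least one true-positive score is required")


def filter_homologs(
    hits: list[HomologHit],
    min_identity: float | None = None,
    min_coverage: float | None = None,
) -> list[HomologHit]:
    """Keep hits at or above the identity and query-coverage floors
    (defaults 35% identity, 0.7 coverage)."""
    if min_identity is None:
        min_identity = get_default("calibrate", "min_identity")
    if min_coverage is None:
        min_coverage = get_default("calibrate", "min_coverage")
    if not 0 <= min_identity <= 100 or not 0 <= min_coverage <= 1:
        raise ValueError("thresholds out of bounds")
    return [
        h for h in hits
        if h.percent_identity >= min_identity and h.query_coverage >= min_coverage
    ]


@lru_cache(maxsize=1)
def _global_aligner() -> Align.PairwiseAligner:
    cfg = get_default("homology")
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(cfg["matrix"])
    aligner.mode = "global"
    aligner.open_gap_score = -(cfg["gap_open"] + cfg["gap_extend"])
    aligner.extend_gap_score = -float(cfg["gap_extend"])
    return aligner


def global_percent_identity(a: str, b: str) -> float:
    """Identity over global alignment columns (matches / columns, in %)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = next(iter(_global_aligner().align(a, b)))
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns if columns else 0.0


def dereplicate(
    seqs: list[str], identity_threshold: float | None = None, seed: int = 0
) -> list[str]:
    """Greedy representative selection at a percent-identity threshold.

    Sequences are visited by descending length (stable, so equal-length
    sequences keep their input order; ``seed`` is accepted for interface
    stability and unused).  A sequence joins the first existing
    representative with global identity >= threshold, else it becomes a new
    representative.
    """
    if identity_threshold is None:
        identity_threshold = get_default("calibrate", "dereplication_identity")
    if not 0 < identity_threshold <= 100:
        raise ValueError("identity_threshold must be in (0, 100]")
    reps: list[str] = []
    for seq in sorted(seqs, key=lambda s: -len(s)):
        for rep in reps:
            if global_percent_identity(seq, rep) >= identity_threshold:
                break
        else:
            reps.append(seq)
    return reps


def choose_cutoff(ls: LabeledScores) -> float:
    """Pick a bit-score cutoff from labelled true/false-positive scores.

    Separable classes (or no false positives): the smallest true score.
    Otherwise: the observed score that maximises balanced accuracy of the
    classifier ``score >= cutoff``; ties resolve to the larger threshold.
    """
    true = sorted(ls.true_scores)
    false = sorted(ls.false_scores)
    if not false or true[0] > false[-1]:
        return float(true[0])
    best_t, best_ba = None, -1.0
    for t in sorted(set(true) | set(false)):
        tpr = sum(s >= t for s in true) / len(true)
        tnr = sum(s < t for s in false) / len(false)
        ba = 0.5 * (tpr + tnr)
        if ba > best_ba or (ba == best_ba and (best_t is None or t > best_t)):
            best_t, best_ba = t, ba
    return float(best_t)
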