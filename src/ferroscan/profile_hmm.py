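"""Profile hidden Markov models: HMMER3 ASCII parsing and local Viterbi bit scores.

Scoring model
-------------
Uni-local ("Smith–Waterman style") Viterbi in log2 space.  An alignment may
enter the model at any match state (uniform entry probability 1/M, i.e. an
entry cost of log2(M) bits) and exit from any match state for free.  Residues
outside the alignment are emitted by the null model and contribute 0 bits.
The reported bit score is

    max over local alignments of
        log2[ P(path, emissions | model) / P(aligned residues | background) ]
        - log2(M)

Deletions are interior only (a path never starts or ends in a delete or
insert state — flanking deletions can never raise a local score).  There is
no bias/composition ("null2") correction: acceptance is governed entirely by
each family's calibrated bit cutoff, so a consistent in-house scale is what
the per-family thresholds are defined against.

Residues outside the 20-letter amino alphabet (X, B, Z, U, O, ...) score
0 bits everywhere: they neither help nor hurt an alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ALPHABET)}

# transition order within ProfileHMM.trans rows
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

NEG_INF = float("-inf")


class HmmFormatError(ValueError):
    """Raised for malformed or unsupported HMMER3 content."""


@dataclass
class ProfileHMM:
    """A profile HMM over the 20-letter amino alphabet.

    ``match_emit``/``insert_emit`` have shape (M, 20) and each row sums to 1.
    ``trans`` has shape (M, 7) in the order (M→M, M→I, M→D, I→M, I→I, D→M, D→D);
    the row at node i describes transitions from node i's states to node i+1.
    ``bit_cutoff`` is the calibrated per-family acceptance threshold in bits
    (``None`` until assigned, e.g. by the family manifest).
    """

    name: str
    match_emit: np.ndarray
    insert_emit: np.ndarray
    trans: np.ndarray
    background: np.ndarray
    bit_cutoff: float | None = None

    # log-odds caches, built lazily
    _lo: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def M(self) -> int:
        return self.match_emit.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        M = self.M
        if M < 1:
            raise HmmFormatError(f"{self.name}: model must have at least one match state")
        for arr, what in ((self.match_emit, "match emission"), (self.insert_emit, "insert emission")):
            if arr.shape != (M, 20):
                raise HmmFormatError(f"{self.name}: bad {what} shape {arr.shape}")
            sums = arr.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > tol):
                raise HmmFormatError(f"{self.name}: {what} rows do not sum to 1")
        if self.trans.shape != (M, 7):
            raise HmmFormatError(f"{self.name}: bad transition shape {self.trans.shape}")
        groups = [(T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)]
        for idx in groups:
            sums = self.trans[:, list(idx)].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > tol):
                raise HmmFormatError(f"{self.name}: transition group {idx} does not sum to 1")
        if abs(self.background.sum() - 1.0) > tol:
            raise HmmFormatError(f"{self.name}: background does not sum to 1")

    def log_odds(self):
        """(match_lo, insert_lo, log2 trans) with -inf for zero probabilities."""
        if not self._lo:
            with np.errstate(divide="ignore"):
                bg = self.background
                self._lo["match"] = np.log2(self.match_emit) - np.log2(bg)[None, :]
                self._lo["insert"] = np.log2(self.insert_emit) - np.log2(bg)[None, :]
                self._lo["trans"] = np.log2(self.trans)
        return self._lo["match"], self._lo["insert"], self._lo["trans"]


@dataclass(frozen=True)
class HmmScore:
    """Bit score of one protein against one model."""

    model: str
    bits: float
    cutoff: float | None = None

    @property
    def passed(self) -> bool:
        return self.cutoff is not None and self.bits >= self.cutoff

    @property
    def margin(self) -> float:
        if self.cutoff is None:
            return NEG_INF
        return self.bits - self.cutoff


# ---------------------------------------------------------------------------
# HMMER3 ASCII parsing / writing (subset: header, COMPO, node lines, //)
# ---------------------------------------------------------------------------

def _prob_from_field(tok: str) -> float:
    """HMMER3 stores -ln(p); '*' means p = 0."""
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def parse_hmmer3(text: str) -> list[ProfileHMM]:
    """Parse one or more concatenated models from HMMER3 ASCII text.

    Only the amino alphabet is supported.  The COMPO line, when present,
    supplies the background distribution; otherwise the background is
    uniform 1/20.  The optional node-0 (BEGIN) insert/transition block is
    skipped: this scorer's entry distribution is uniform over match states.
    """
    lines = text.splitlines()
    pos = 0
    models: list[ProfileHMM] = []
    n = len(lines)
    while pos < n:
        # find next model header
        while pos < n and not lines[pos].startswith("HMMER3"):
            if lines[pos].strip() and models == [] and not lines[pos].startswith("HMMER3"):
                raise HmmFormatError(f"line {pos + 1}: expected 'HMMER3' format tag")
            pos += 1
        if pos >= n:
            break
        pos += 1
        name = None
        leng = None
        alpha = None
        while pos < n and not lines[pos].lstrip().startswith("HMM "):
            tok = lines[pos].split()
            if tok:
                if tok[0] == "NAME":
                    name = tok[1]
                elif tok[0] == "LENG":
                    leng = int(tok[1])
                elif tok[0] == "ALPH":
                    alpha = tok[1].lower()
            pos += 1
        if pos >= n:
            raise HmmFormatError("truncated model: no 'HMM' column-header line")
        if alpha != "amino":
            raise HmmFormatError(f"model {name!r}: unsupported alphabet {alpha!r} (amino only)")
        header_cols = lines[pos].split()[1:]
        if header_cols[:20] != list(AMINO_ALPHABET):
            raise HmmFormatError(f"model {name!r}: unexpected symbol order in HMM header")
        pos += 1  # skip the 'm->m m->i ...' transition header line
        if pos < n and "m->m" in lines[pos]:
            pos += 1

        background = np.full(20, 0.05)
        tok = lines[pos].split()
        if tok and tok[0] == "COMPO":
            background = np.array([_prob_from_field(t) for t in tok[1:21]])
            pos += 1
        # optional node-0 insert-emission + transition block
        tok = lines[pos].split()
        if tok and tok[0] != "1":
            pos += 2  # insert0 line + transition line

        if leng is None:
            raise HmmFormatError(f"model {name!r}: missing LENG")
        match_emit = np.zeros((leng, 20))
        insert_emit = np.zeros((leng, 20))
        trans = np.zeros((leng, 7))
        for k in range(1, leng + 1):
            if pos + 2 >= n:
                raise HmmFormatError(f"model {name!r}: truncated at node {k}")
            mtok = lines[pos].split()
            if not mtok or mtok[0] != str(k):
                raise HmmFormatError(
                    f"model {name!r}: expected node {k}, got {mtok[0] if mtok else 'EOF'}"
                )
            match_emit[k - 1] = [_prob_from_field(t) for t in mtok[1:21]]
            itok = lines[pos + 1].split()
            insert_emit[k - 1] = [_prob_from_field(t) for t in itok[:20]]
            ttok = lines[pos + 2].split()
            trans[k - 1] = [_prob_from_field(t) for t in ttok[:7]]
            pos += 3
        if pos >= n or lines[pos].strip() != "//":
            raise HmmFormatError(f"model {name!r}: missing terminating '//'")
        pos += 1
        hmm = ProfileHMM(
            name=name or f"model{len(models) + 1}",
            match_emit=match_emit,
            insert_emit=insert_emit,
            trans=trans,
            background=background,
        )
        hmm.validate(tol=1e-3)  # files store rounded -ln p
        # renormalise rounding error away so invariants hold exactly
        hmm.match_emit /= hmm.match_emit.sum(axis=1, keepdims=True)
        hmm.insert_emit /= hmm.insert_emit.sum(axis=1, keepdims=True)
        hmm.background = hmm.background / hmm.background.sum()
        for sl in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
            s = hmm.trans[:, list(sl)].sum(axis=1, keepdims=True)
            hmm.trans[:, list(sl)] /= s
        models.append(hmm)
    if not models:
        raise HmmFormatError("no models found (missing 'HMMER3' format tag?)")
    return models


def _fmt(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.5f}"


def write_hmmer3(models: list[ProfileHMM] | ProfileHMM) -> str:
    """Serialise models to HMMER3/f ASCII (subset written by this package)."""
    if isinstance(models, ProfileHMM):
        models = [models]
    out: list[str] = []
    for hmm in models:
        out.append("HMMER3/f [ferroscan]")
        out.append(f"NAME  {hmm.name}")
        out.append(f"LENG  {hmm.M}")
        out.append("ALPH  amino")
        out.append("HMM          " + "        ".join(AMINO_ALPHABET))
        out.append("            m->m     m->i     m->d     i->m     i->i     d->m     d->d")
        out.append("  COMPO   " + "  ".join(_fmt(p) for p in hmm.background))
        # node-0 block for compatibility with standard readers
        out.append("          " + "  ".join(_fmt(p) for p in hmm.background))
        out.append("          " + "  ".join([_fmt(0.9), _fmt(0.05), _fmt(0.05), _fmt(0.9), _fmt(0.1), "0.00000", "*"]))
        for k in range(hmm.M):
            cons = AMINO_ALPHABET[int(np.argmax(hmm.match_emit[k]))].lower()
            out.append(
                f"{k + 1:7d}   " + "  ".join(_fmt(p) for p in hmm.match_emit[k])
                + f"  {k + 1} {cons} - - -"  # MAP CONS RF MM CS annotation columns
            )
            out.append("          " + "  ".join(_fmt(p) for p in hmm.insert_emit[k]))
            out.append("          " + "  ".join(_fmt(p) for p in hmm.trans[k]))
        out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Viterbi scoring
# ---------------------------------------------------------------------------

@njit(cache=True)
def _viterbi_kernel(match_lo, insert_lo, ltr, seq, entry_cost):  # pragma: no cover
    M = match_lo.shape[0]
    L = seq.shape[0]
    best = NEG_INF
    vm_prev = np.full(M, NEG_INF)
    vi_prev = np.full(M, NEG_INF)
    vm = np.empty(M)
    vi = np.empty(M)
    vd = np.full(M, NEG_INF)
    vd_prev = np.full(M, NEG_INF)
    for j in range(L):
        a = seq[j]
        for i in range(M):
            emit = 0.0 if a < 0 else match_lo[i, a]
            s = entry_cost  # fresh entry at match state i
            if i > 0:
                x = vm_prev[i - 1] + ltr[i - 1, 0]  # M->M
                if x > s:
                    s = x
                x = vi_prev[i - 1] + ltr[i - 1, 3]  # I->M
                if x > s:
                    s = x
                x = vd_prev[i - 1] + ltr[i - 1, 5]  # D->M
                if x > s:
                    s = x
            vm[i] = emit + s
            if vm[i] > best:
                best = vm[i]
        # delete chain for column j (depends on vm of column j)
        vd[0] = NEG_INF
        for i in range(1, M):
            x = vm[i - 1] + ltr[i - 1, 2]  # M->D
            y = vd[i - 1] + ltr[i - 1, 6]  # D->D
            vd[i] = x if x > y else y
        # insert states at column j
        for i in range(M):
            emit = 0.0 if a < 0 else insert_lo[i, a]
            x = vm[i] + ltr[i, 1]  # M->I
            y = vi_prev[i] + ltr[i, 4]  # I->I
            vi[i] = emit + (x if x > y else y)
        for i in range(M):
            vm_prev[i] = vm[i]
            vi_prev[i] = vi[i]
            vd_prev[i] = vd[i]
    return best


def encode_protein(protein: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown residues become -1."""
    return np.array([_AA_INDEX.get(a, -1) for a in protein.upper()], dtype=np.int64)


def viterbi_bits(hmm: ProfileHMM, protein: str) -> HmmScore:
    """Best uni-local alignment bit score of ``protein`` against ``hmm``.

    Deterministic; the score of the best single-residue alignment is the
    floor (an empty alignment is not reported).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    match_lo, insert_lo, ltr = hmm.log_odds()
    seq = encode_protein(protein)
    entry_cost = -math.log2(hmm.M)
    bits = _viterbi_kernel(match_lo, insert_lo, ltr, seq, entry_cost)
    return HmmScore(model=hmm.name, bits=float(bits), cutoff=hmm.bit_cutoff)


def best_scores(hmms: list[ProfileHMM], sample) -> dict[str, list[HmmScore]]:
    """Score every gene against every model; keep passing scores only.

    Each gene's list is sorted by margin (bits - cutoff) descending, ties
    broken by model name ascending.
    """
    if not hmms:
        raise ValueError("at least one model is required")
    out: dict[str, list[HmmScore]] = {}
    for gene in sample.genes:
        hits = [s for s in (viterbi_bits(h, gene.protein) for h in hmms) if s.passed]
        hits.sort(key=lambda s: (-s.margin, s.model))
        out[gene.gene_id] = hits
    return out
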