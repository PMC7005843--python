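"""Profile-HMM parsing and local Viterbi scoring.

The scoring contract is pinned against an exhaustive path-enumeration
oracle: for small models (M <= 4) and short sequences, every legal local
alignment path is enumerated and its log-odds computed directly from the
model probabilities; the dynamic-programming score must equal the maximum.
"""

import math

import numpy as np
import pytest

from conftest import random_hmm
from ferroscan.profile_hmm import (
    AMINO_ALPHABET,
    HmmFormatError,
    ProfileHMM,
    best_scores,
    encode_protein,
    parse_hmmer3,
    viterbi_bits,
    write_hmmer3,
)
from ferroscan.sequence_io import GeneCall, SampleInput
from ferroscan.synthetic_fixtures import make_toy_hmm

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# independent oracle: enumerate every local alignment path
# ---------------------------------------------------------------------------

def enumeration_score(hmm: ProfileHMM, protein: str) -> float:
    """Max log-odds over all uni-local paths, by explicit enumeration."""
    match_lo, insert_lo, ltr = hmm.log_odds()
    seq = encode_protein(protein)
    M, L = hmm.M, len(seq)
    entry = -math.log2(M)
    best = [NEG_INF]

    def emit(lo_row, a):
        return 0.0 if a < 0 else lo_row[a]

    def walk(kind, i, j, acc):
        # `acc` includes the emission at the current state
        if kind == "M":
            best[0] = max(best[0], acc)  # free exit from any match state
        if kind == "M":
            if i + 1 < M and j + 1 < L:
                walk("M", i + 1, j + 1, acc + ltr[i, 0] + emit(match_lo[i + 1], seq[j + 1]))
            if j + 1 < L:
                walk("I", i, j + 1, acc + ltr[i, 1] + emit(insert_lo[i], seq[j + 1]))
            if i + 1 < M:
                walk("D", i + 1, j, acc + ltr[i, 2])
        elif kind == "I":
            if i + 1 < M and j + 1 < L:
                walk("M", i + 1, j + 1, acc + ltr[i, 3] + emit(match_lo[i + 1], seq[j + 1]))
            if j + 1 < L:
                walk("I", i, j + 1, acc + ltr[i, 4] + emit(insert_lo[i], seq[j + 1]))
        else:  # D
            if i + 1 < M and j + 1 < L:
                walk("M", i + 1, j + 1, acc + ltr[i, 5] + emit(match_lo[i + 1], seq[j + 1]))
            if i + 1 < M:
                walk("D", i + 1, j, acc + ltr[i, 6])

    for i0 in range(M):
        for j0 in range(L):
            walk("M", i0, j0, entry + emit(match_lo[i0], seq[j0]))
    return best[0]


def _oracle_cases():
    cases = []
    rng = np.random.default_rng(20240917)
    aa = list(AMINO_ALPHABET)
    for M in (1, 2, 3, 4):
        for model_seed in range(6):
            hmm = random_hmm(M, seed=1000 * M + model_seed)
            for _ in range(9):
                L = int(rng.integers(1, 9))
                seq = "".join(rng.choice(aa + ["X"], p=[0.048] * 20 + [0.04], size=L))
                cases.append((hmm, seq))
    return cases


def test_viterbi_equals_path_enumeration_oracle():
    """DP score == exhaustive enumeration on >= 200 model x sequence cases."""
    cases = _oracle_cases()
    assert len(cases) >= 200
    for hmm, seq in cases:
        expected = enumeration_score(hmm, seq)
        got = viterbi_bits(hmm, seq).bits
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9), (hmm.name, seq)


def test_single_state_perfect_match_scores_log2_20():
    """1-node model emitting A with certainty vs 'A': log2(1/0.05) bits."""
    hmm = make_toy_hmm("A", match_prob=1.0)
    assert viterbi_bits(hmm, "A").bits == pytest.approx(math.log2(20), abs=1e-12)


def test_zero_probability_residue_scores_nonpositive():
    hmm = make_toy_hmm("A", match_prob=1.0)
    hmm.bit_cutoff = 0.5
    score = viterbi_bits(hmm, "G")
    assert score.bits <= 0
    assert not score.passed


def test_appending_residues_never_decreases_score():
    """Flanking residues cost nothing, so the local score is monotone."""
    rng = np.random.default_rng(5)
    hmm = random_hmm(3, seed=42)
    seq = "ACDE"
    prev = viterbi_bits(hmm, seq).bits
    for _ in range(10):
        seq += rng.choice(list(AMINO_ALPHABET))
        cur = viterbi_bits(hmm, seq).bits
        assert cur >= prev - 1e-12
        prev = cur


def test_score_invariant_under_odds_roundtrip():
    """Rebuilding emissions from their odds against background is a no-op."""
    hmm = random_hmm(3, seed=7)
    odds_m = hmm.match_emit / hmm.background[None, :]
    odds_i = hmm.insert_emit / hmm.background[None, :]
    hmm2 = ProfileHMM(
        name="roundtrip",
        match_emit=odds_m * hmm.background[None, :],
        insert_emit=odds_i * hmm.background[None, :],
        trans=hmm.trans.copy(),
        background=hmm.background.copy(),
    )
    for seq in ("ACD", "WYW", "MNPQRST"):
        assert viterbi_bits(hmm2, seq).bits == pytest.approx(
            viterbi_bits(hmm, seq).bits, abs=1e-9
        )


def test_empty_protein_rejected():
    with pytest.raises(ValueError):
        viterbi_bits(make_toy_hmm("ACD"), "")


# ---------------------------------------------------------------------------
# HMMER3 ASCII round trip
# ---------------------------------------------------------------------------

def test_hmmer3_roundtrip_preserves_probabilities():
    hmm = random_hmm(4, seed=11)
    hmm.name = "rt"
    (parsed,) = parse_hmmer3(write_hmmer3(hmm))
    np.testing.assert_allclose(parsed.match_emit, hmm.match_emit, atol=2e-5)
    np.testing.assert_allclose(parsed.trans, hmm.trans, atol=2e-5)
    np.testing.assert_allclose(parsed.background, hmm.background, atol=2e-5)
    for seq in ("ACDEF", "WW"):
        assert viterbi_bits(parsed, seq).bits == pytest.approx(
            viterbi_bits(hmm, seq).bits, abs=1e-3
        )


def test_hmmer3_roundtrip_matches_pyhmmer():
    """Independent reader: pyhmmer parses our files to the same emissions."""
    pyhmmer = pytest.importorskip("pyhmmer")
    import io

    hmm = make_toy_hmm("CAACH", match_prob=0.9)
    hmm.name = "toy"
    text = write_hmmer3(hmm)
    with io.BytesIO(text.encode()) as fh:
        (ph,) = list(pyhmmer.plan7.HMMFile(fh))
    # pyhmmer match_emissions row 0 is the BEGIN state; rows 1..M are nodes
    emissions = np.asarray(ph.match_emissions)[1:, :]
    np.testing.assert_allclose(emissions, hmm.match_emit, atol=2e-5)


def test_parse_concatenated_models():
    text = write_hmmer3(make_toy_hmm("ACD")) + write_hmmer3(make_toy_hmm("WYW"))
    models = parse_hmmer3(text)
    assert [m.M for m in models] == [3, 3]


def test_parse_rejects_non_amino_alphabet():
    hmm = make_toy_hmm("ACD")
    text = write_hmmer3(hmm).replace("ALPH  amino", "ALPH  DNA")
    with pytest.raises(HmmFormatError, match="alphabet"):
        parse_hmmer3(text)


def test_parse_rejects_truncated_model():
    text = write_hmmer3(make_toy_hmm("ACDEF"))
    lines = text.splitlines()
    with pytest.raises(HmmFormatError):
        parse_hmmer3("\n".join(lines[: len(lines) // 2]))


# ---------------------------------------------------------------------------
# best_scores
# ---------------------------------------------------------------------------

def _sample(proteins):
    genes = [
        GeneCall(gene_id=f"g{i}", contig_id="c", index=i, protein=p)
        for i, p in enumerate(proteins, start=1)
    ]
    return SampleInput(sample_id="s", genes=genes)


def test_best_scores_keeps_passing_and_sorts_by_margin():
    a = make_toy_hmm("AAAA", match_prob=0.99)
    a.name, a.bit_cutoff = "modA", 5.0
    w = make_toy_hmm("WWWW", match_prob=0.99)
    w.name, w.bit_cutoff = "modW", 5.0
    sample = _sample(["AAAA", "CDEF"])
    res = best_scores([w, a], sample)
    assert [s.model for s in res["g1"]] == ["modA"]
    assert res["g2"] == []


def test_best_scores_tie_breaks_by_model_name():
    m1 = make_toy_hmm("AAAA", match_prob=0.99)
    m2 = make_toy_hmm("AAAA", match_prob=0.99)
    m1.name, m1.bit_cutoff = "zeta", 1.0
    m2.name, m2.bit_cutoff = "alpha", 1.0
    res = best_scores([m1, m2], _sample(["AAAA"]))
    assert [s.model for s in res["g1"]] == ["alpha", "zeta"]
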