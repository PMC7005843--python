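"""Neighborhood construction and the category rule engine."""

import itertools
import random

import numpy as np
import pytest

from ferroscan.annotate import GeneAnnotation
from ferroscan.neighborhoods import (
    apply_rules,
    build_neighborhoods,
    default_ruleset,
    operon_completeness,
)

MAM = ["mamA", "mamB", "mamE", "mamK", "mamL", "mamM", "mamO", "mamP", "mamQ", "mamI"]


def ann(family, index, contig="c1", category="iron_reduction", extra=()):
    return GeneAnnotation(
        gene_id=f"{contig}_{index}", contig_id=contig, index=index,
        family_id=family, category=category, method="hmm",
        score=50.0, cutoff=30.0, margin=20.0, heme_motif_count=0, length=300,
        also_passing=tuple(extra),
    )


def anns_from(families, contig="c1", start=1, category="iron_reduction"):
    return [ann(f, start + i, contig, category) for i, f in enumerate(families)]


class TestBuildNeighborhoods:
    def test_gap_within_limit_joins(self):
        nbs = build_neighborhoods([ann("a1", 3), ann("a2", 4), ann("a3", 6)], max_gap=2)
        assert len(nbs) == 1
        assert nbs[0].span == (3, 6)

    def test_gap_beyond_limit_splits(self):
        nbs = build_neighborhoods([ann("a1", 3), ann("a2", 10)], max_gap=2)
        assert [nb.span for nb in nbs] == [(3, 3), (10, 10)]

    def test_contigs_never_merge(self):
        nbs = build_neighborhoods([ann("a1", 1, "c1"), ann("a2", 2, "c2")], max_gap=3)
        assert len(nbs) == 2

    def test_order_invariance(self):
        items = [ann(f"a{i}", i) for i in (1, 2, 7, 8, 15)]
        shuffled = items[:]
        random.Random(4).shuffle(shuffled)
        assert build_neighborhoods(items, 3) == build_neighborhoods(shuffled, 3)

    def test_matches_transitive_closure_oracle(self):
        """Connected components equal brute-force pairwise closure on 100
        random 20-gene contigs."""
        rng = np.random.default_rng(606)
        for _ in range(100):
            indices = sorted(
                rng.choice(np.arange(1, 21), size=int(rng.integers(2, 12)), replace=False)
            )
            max_gap = int(rng.integers(1, 5))
            items = [ann(f"f{i}", int(i)) for i in indices]
            nbs = build_neighborhoods(items, max_gap)
            got = sorted(tuple(a.index for a in nb.members) for nb in nbs)

            # oracle: transitive closure by repeated pairwise linking
            groups = [{i} for i in indices]
            changed = True
            while changed:
                changed = False
                for g1, g2 in itertools.combinations(groups, 2):
                    if any(abs(a - b) <= max_gap for a in g1 for b in g2):
                        groups.remove(g1)
                        groups.remove(g2)
                        groups.append(g1 | g2)
                        changed = True
                        break
            expected = sorted(tuple(sorted(g)) for g in groups)
            assert got == expected

    def test_invalid_gap(self):
        with pytest.raises(ValueError):
            build_neighborhoods([ann("a", 1)], max_gap=0)


class TestOperonCompleteness:
    @pytest.mark.parametrize("k,frac,called", [(6, 0.6, True), (5, 0.5, True), (4, 0.4, False)])
    def test_mam_completeness_and_call(self, db, k, frac, called):
        (nb,) = build_neighborhoods(anns_from(MAM[:k], category="magnetosome_formation"), 3)
        assert operon_completeness(nb, db.operon("mam")) == pytest.approx(frac)
        calls = apply_rules([nb], db, sample_id="s")
        mag = [c for c in calls if c.category == "magnetosome_formation"]
        assert bool(mag) is called
        if called:
            assert mag[0].completeness == pytest.approx(frac)


class TestRedoxRules:
    def calls_for(self, db, families, **kw):
        nbs = build_neighborhoods(anns_from(families, **kw), 3)
        return apply_rules(nbs, db, sample_id="s")

    def test_complete_mtrCAB_is_iron_reduction(self, db):
        calls = self.calls_for(db, ["mtrC", "mtrA", "mtrB"])
        assert [c.category for c in calls] == ["iron_reduction"]
        assert calls[0].rule_id == "mtrCAB"
        assert calls[0].completeness == 1.0

    def test_mtrAB_without_mtrC_is_probable(self, db):
        calls = self.calls_for(db, ["mtrA", "mtrB"])
        assert [c.category for c in calls] == ["probable_iron_reduction"]

    def test_mtrCB_without_mtrA_is_probable(self, db):
        calls = self.calls_for(db, ["mtrC", "mtrB"])
        assert [c.category for c in calls] == ["probable_iron_reduction"]

    def test_single_mtoA_is_possible_redox(self, db):
        calls = self.calls_for(
            db, ["mtoA"], category="possible_iron_oxidation_and_possible_iron_reduction"
        )
        assert [c.category for c in calls] == [
            "possible_iron_oxidation_and_possible_iron_reduction"
        ]

    def test_mtoAB_next_to_mtrC_is_probable_reduction(self, db):
        nbs = build_neighborhoods(
            anns_from(["mtoA", "mtoB"]) + [ann("mtrC", 3)], 3
        )
        calls = apply_rules(nbs, db, sample_id="s")
        assert [c.category for c in calls] == ["probable_iron_reduction"]
        assert calls[0].evidence_families == {"mtoA", "mtoB", "mtrC"}

    def test_complete_operon_shadows_partial(self, db):
        """mtrCAB yields exactly one call; the mtrAB fallback never co-fires."""
        calls = self.calls_for(db, ["mtrC", "mtrA", "mtrB"])
        assert len(calls) == 1
        assert not any(c.category == "probable_iron_reduction" for c in calls)

    def test_foxEYZ_requires_the_anchor(self, db):
        assert [
            c.category
            for c in self.calls_for(db, ["foxE", "foxY"], category="iron_oxidation")
        ] == ["iron_oxidation"]
        assert (
            self.calls_for(db, ["foxY", "foxZ"], category="iron_oxidation") == []
        )

    def test_secondary_families_feed_rules(self, db):
        """Operon rules see passing families beyond each gene's primary label."""
        items = [ann("mtrC", 1), ann("mtrA", 2, extra=("mtrB",))]
        calls = apply_rules(build_neighborhoods(items, 3), db, sample_id="s")
        assert any(c.rule_id == "mtrCAB" for c in calls)


class TestGeneLevelRules:
    def test_transport_gene_yields_call(self, db):
        nbs = build_neighborhoods([ann("feoB", 1, category="iron_transport")], 3)
        calls = apply_rules(nbs, db, sample_id="s")
        assert [(c.category, c.rule_id) for c in calls] == [
            ("iron_transport", "transport_genes")
        ]

    def test_siderophore_synthesis_pair_vs_singleton(self, db):
        pair = anns_from(["iucA", "iucC"], category="siderophore_synthesis")
        calls = apply_rules(build_neighborhoods(pair, 3), db, sample_id="s")
        assert [c.rule_id for c in calls] == ["sid_operon"]
        assert calls[0].flags == frozenset()

        single = [ann("iucA", 1, category="siderophore_synthesis")]
        calls = apply_rules(build_neighborhoods(single, 3), db, sample_id="s")
        assert [c.rule_id for c in calls] == ["sid_singleton"]
        assert "low_confidence" in calls[0].flags


class TestDeterminism:
    def test_rule_evaluation_is_pure(self, db):
        items = anns_from(["mtrC", "mtrA", "mtrB"]) + anns_from(MAM[:6], contig="c2")
        nbs = build_neighborhoods(items, 3)
        first = apply_rules(nbs, db, sample_id="s")
        for _ in range(3):
            assert apply_rules(nbs, db, sample_id="s") == first

    def test_ruleset_validates_against_database(self, db):
        rs = default_ruleset(db)
        assert rs.rules
        for r in rs.rules:
            assert r.scope in {"neighborhood", "gene"}
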