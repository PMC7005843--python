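"""Count matrices, normalisation, scaling, clustering, exports."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from ferroscan.family_db import CATEGORY_SCHEMA
from ferroscan.neighborhoods import CategoryCall
from ferroscan.sequence_io import GeneCall, SampleInput
from ferroscan.summarize import (
    Dendrogram,
    count_matrix,
    export,
    normalize,
    scale_rows,
    ward_cluster,
)


def call(category, genes, sample="s1", rule="r"):
    return CategoryCall(
        sample_id=sample, category=category, rule_id=rule,
        evidence=tuple((f"fam{i}", g) for i, g in enumerate(genes)),
        contig_id="c1",
    )


def sample(sid, orf_count=100):
    return SampleInput(sid, [GeneCall(f"{sid}_g1", "c1", 1, "MAR")], orf_count=orf_count)


class TestCountMatrix:
    def test_distinct_evidence_genes(self):
        calls = [call("iron_reduction", ["g1", "g2"])]
        m = count_matrix([(sample("s1"), calls)])
        assert m.loc["iron_reduction", "s1"] == 2

    def test_gene_in_two_categories_counts_once_each(self):
        calls = [call("iron_reduction", ["g1"]), call("iron_oxidation", ["g1"])]
        m = count_matrix([(sample("s1"), calls)])
        assert m.loc["iron_reduction", "s1"] == 1
        assert m.loc["iron_oxidation", "s1"] == 1

    def test_gene_cited_by_two_rules_counts_once(self):
        calls = [
            call("iron_reduction", ["g1", "g2"], rule="r1"),
            call("iron_reduction", ["g2"], rule="r2"),
        ]
        m = count_matrix([(sample("s1"), calls)])
        assert m.loc["iron_reduction", "s1"] == 2

    def test_empty_calls_all_zero(self):
        m = count_matrix([(sample("s1"), [])])
        assert (m["s1"] == 0).all()
        assert list(m.index) == list(CATEGORY_SCHEMA)


class TestNormalize:
    def test_percent_of_orfs(self):
        m = count_matrix([(sample("s1"), [call("iron_storage", ["g1"] * 1)])])
        m.loc["iron_storage", "s1"] = 5
        out = normalize(m, {"s1": 1000})
        assert out.loc["iron_storage", "s1"] == pytest.approx(0.5)

    def test_doubling_orfs_halves_values(self):
        m = count_matrix([(sample("s1"), [call("iron_storage", ["g1"])])])
        a = normalize(m, {"s1": 100})
        b = normalize(m, {"s1": 200})
        assert np.allclose(b.to_numpy(), a.to_numpy() / 2)

    def test_missing_orf_count_rejected(self):
        m = count_matrix([(sample("s1"), [])])
        with pytest.raises(ValueError, match="missing orf_count"):
            normalize(m, {})


class TestScaleRows:
    def test_two_sample_row_z_scores(self):
        m = pd.DataFrame({"a": [0.0], "b": [10.0]}, index=["iron_storage"])
        out = scale_rows(m)
        # sample (n-1) sd convention
        assert out.loc["iron_storage", "a"] == pytest.approx(-1 / math.sqrt(2))
        assert out.loc["iron_storage", "b"] == pytest.approx(1 / math.sqrt(2))

    def test_constant_row_maps_to_zero(self):
        m = pd.DataFrame({"a": [4.0], "b": [4.0], "c": [4.0]}, index=["x"])
        assert (scale_rows(m).to_numpy() == 0).all()

    def test_rows_centered(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((12, 5)), index=list(CATEGORY_SCHEMA))
        out = scale_rows(m)
        assert np.abs(out.mean(axis=1).to_numpy()).max() < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            scale_rows(pd.DataFrame({"a": [1.0]}))


def _matrix(profile_map):
    return pd.DataFrame(profile_map, index=[f"cat{i}" for i in range(len(next(iter(profile_map.values()))))], dtype=float)


class TestWardCluster:
    def test_identical_profiles_merge_first_at_height_zero(self):
        m = _matrix({"s1": [1, 2, 3], "s2": [9, 1, 4], "s3": [1, 2, 3]})
        dg = ward_cluster(m)
        first = dg.clades()[0]
        assert first == frozenset({"s1", "s3"})
        assert dg.heights[0] == 0.0

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.random((12, 6)), columns=[f"s{i}" for i in range(6)])
        dg = ward_cluster(m)
        assert (np.diff(dg.heights) >= -1e-12).all()

    def test_column_permutation_invariant_topology(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((12, 5)), columns=list("edcba"))
        dg1 = ward_cluster(m)
        dg2 = ward_cluster(m[list("abcde")])
        assert set(dg1.clades()) == set(dg2.clades())

    def test_bootstrap_seeded_and_stable(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        dg1 = ward_cluster(m, seed=123, bootstrap_b=100)
        dg2 = ward_cluster(m, seed=123, bootstrap_b=100)
        assert dg1.support == dg2.support
        assert all(0 <= v <= 100 for v in dg1.support.values())

    def test_root_support_is_100(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        dg = ward_cluster(m, seed=1, bootstrap_b=50)
        assert dg.support[frozenset("abcd")] == 100.0

    def test_support_absent_below_three_samples(self):
        m = _matrix({"a": [1, 2, 3], "b": [3, 1, 2]})
        dg = ward_cluster(m, seed=1, bootstrap_b=50)
        assert dg.support is None

    def test_duplicated_sample_is_sibling_at_zero(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        m["a_dup"] = m["a"]
        dg = ward_cluster(m)
        assert frozenset({"a", "a_dup"}) in dg.clades()
        idx = dg.clades().index(frozenset({"a", "a_dup"}))
        assert dg.heights[idx] == pytest.approx(0.0, abs=1e-12)


class TestExport:
    def _run(self, tmp_path, n=3, bootstrap=20):
        rng = np.random.default_rng(13)
        m = pd.DataFrame(
            rng.integers(0, 9, size=(12, n)).astype(float),
            index=list(CATEGORY_SCHEMA),
            columns=[f"s{i}" for i in range(n)],
        )
        dg = ward_cluster(m, seed=5, bootstrap_b=bootstrap)
        return m, export(m, dg, [], tmp_path, normalized=m / 10)

    def test_matrix_and_dotplot_shapes(self, tmp_path):
        m, written = self._run(tmp_path)
        back = pd.read_csv(written["matrix"], sep="\t", index_col=0)
        assert back.shape == (12, 3)
        dot = pd.read_csv(written["dotplot"], sep="\t")
        assert len(dot) == 36
        assert set(dot.columns) == {"sample", "category", "value"}

    def test_newick_roundtrip_topology(self, tmp_path):
        from Bio import Phylo

        m, written = self._run(tmp_path)
        tree = Phylo.read(io.StringIO(written["tree"].read_text()), "newick")
        leaves = {t.name for t in tree.get_terminals()}
        assert leaves == set(m.columns)
        # internal node labels (bootstrap support) parse as confidences
        inner = tree.get_nonterminals()
        assert any(c.confidence is not None for c in inner)

    def test_rendered_figures(self, tmp_path):
        rng = np.random.default_rng(14)
        m = pd.DataFrame(
            rng.random((12, 3)), index=list(CATEGORY_SCHEMA), columns=list("abc")
        )
        dg = ward_cluster(m)
        written = export(m, dg, [], tmp_path, render_figures=True)
        assert written["heatmap"].exists()
        assert written["dendrogram"].exists()


def test_dendrogram_newick_writer_directly():
    Z = np.array([[0.0, 1.0, 0.5, 2.0], [2.0, 3.0, 1.5, 3.0]])
    dg = Dendrogram(labels=["x", "y", "z"], linkage=Z, support={frozenset("xy"): 90.0, frozenset("xyz"): 100.0})
    nwk = dg.newick()
    assert nwk.endswith(";")
    assert "x:" in nwk and "90" in nwk
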