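"""LCA assignment, count matrices, decontamination and grouping."""

import numpy as np
import pandas as pd
import pytest

import sedapop as sp
from sedapop.readmap import AlignmentHit
from sedapop.taxprofile import TaxonomyTree, rank_rollup


@pytest.fixture()
def toy_tree():
    return TaxonomyTree(
        {
            "root": ("root", "no rank", "root"),
            "Metazoa": ("root", "kingdom", "Metazoa"),
            "G": ("Metazoa", "genus", "G"),
            "S1": ("G", "species", "S1"),
            "S2": ("G", "species", "S2"),
            "H": ("Metazoa", "genus", "H"),
            "S3": ("H", "species", "S3"),
            "Plants": ("root", "kingdom", "Viridiplantae"),
            "P1": ("Plants", "species", "P1"),
        }
    )


def hit(rid, ref, mism=0, L=40):
    return AlignmentHit(rid, ref, 0, L, "+", mism, (L - mism) / L)


class TestTaxonomyTree:
    def test_cycle_detected(self):
        with pytest.raises(ValueError, match="root"):
            TaxonomyTree({"a": ("b", "x", "a"), "b": ("a", "x", "b")})

    def test_unknown_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            TaxonomyTree({"root": ("root", "r", "root"), "a": ("ghost", "x", "a")})

    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="exactly one root"):
            TaxonomyTree({"r1": ("r1", "r", "r1"), "r2": ("r2", "r", "r2")})

    def test_tsv_roundtrip(self, toy_tree, tmp_path):
        p = tmp_path / "tax.tsv"
        toy_tree.to_tsv(p)
        again = TaxonomyTree.from_tsv(p)
        assert again.nodes == toy_tree.nodes


class TestLcaAssign:
    R2T = {"refS1": "S1", "refS2": "S2", "refS3": "S3", "refP1": "P1"}

    def test_single_hit_assigns_species(self, toy_tree):
        assert sp.lca_assign([hit("r", "refS1")], self.R2T, toy_tree) == "S1"

    def test_sibling_species_reduce_to_genus(self, toy_tree):
        hits = [hit("r", "refS1"), hit("r", "refS2")]
        assert sp.lca_assign(hits, self.R2T, toy_tree) == "G"

    def test_cross_genus_reduces_to_kingdom(self, toy_tree):
        hits = [hit("r", "refS1"), hit("r", "refS3")]
        assert sp.lca_assign(hits, self.R2T, toy_tree) == "Metazoa"

    def test_window_filters_hits(self, toy_tree):
        hits = [hit("r", "refS1"), hit("r", "refS2", mism=11, L=400)]
        assert sp.lca_assign(hits, self.R2T, toy_tree) == "S1"
        hits = [hit("r", "refS1"), hit("r", "refS2", mism=3, L=40)]  # identity 0.925
        assert sp.lca_assign(hits, self.R2T, toy_tree) == "S1"

    def test_no_surviving_hits_unassigned(self, toy_tree):
        assert sp.lca_assign([hit("r", "refS1", mism=11, L=400)], self.R2T, toy_tree) is None

    def test_unknown_reference_raises(self, toy_tree):
        with pytest.raises(ValueError, match="mystery"):
            sp.lca_assign([hit("r", "mystery")], self.R2T, toy_tree)


def brute_force_lca(tree: TaxonomyTree, nodes):
    """Oracle: intersect full ancestor sets, take the deepest."""
    common = None
    for n in nodes:
        anc = set(tree.path_to_root(n))
        common = anc if common is None else common & anc
    return max(common, key=lambda n: len(tree.path_to_root(n)))


def random_tree(rng, n_nodes):
    nodes = {"n0": ("n0", "no rank", "n0")}
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        nodes[f"n{i}"] = (parent, "clade", f"n{i}")
    return TaxonomyTree(nodes)


class TestLcaOracle:
    def test_random_instances_match_bruteforce(self, rng):
        for _ in range(50):
            tree = random_tree(rng, int(rng.integers(2, 50)))
            k = int(rng.integers(1, 6))
            nodes = [f"n{rng.integers(0, len(tree.nodes))}" for _ in range(k)]
            assert tree.lca(nodes) == brute_force_lca(tree, nodes)


class TestCountMatrix:
    def test_counts_and_conservation(self):
        m = sp.count_matrix(
            {"X": {"r1": "S1", "r2": "S1", "r3": "S1", "r4": "G"}, "Y": {}},
            unassigned={"X": 2, "Y": 0},
        )
        assert m.counts.loc["X", "S1"] == 3 and m.counts.loc["X", "G"] == 1
        assert (m.counts.loc["Y"] == 0).all()
        assert m.counts.loc["X"].sum() + m.unassigned["X"] == 6


def golden_matrix(toy_tree):
    """3 samples + 1 control x 6 taxa exercising every decontamination rule."""
    tree = TaxonomyTree(
        {
            "root": ("root", "no rank", "root"),
            "Primates": ("root", "order", "Primates"),
            "Homo_sapiens": ("Primates", "species", "Homo sapiens"),
            "t_min3": ("root", "species", "t_min3"),
            "t_contam": ("root", "species", "t_contam"),
            "t_allow": ("root", "species", "Leptonychotes weddellii"),
            "t_final_allow": ("root", "species", "Stercorarius maccormicki"),
            "t_keep": ("root", "species", "t_keep"),
        }
    )
    counts = pd.DataFrame(
        {
            "t_min3": [2, 0, 0, 0],
            "t_contam": [60, 40, 30, 5],
            "t_allow": [100, 60, 40, 4],
            "t_final_allow": [9, 6, 0, 40],
            "Homo_sapiens": [30, 30, 30, 0],
            "t_keep": [40, 30, 20, 0],
        },
        index=["S1", "S2", "S3", "CTRL"],
    )
    matrix = sp.TaxonCountMatrix(
        counts=counts,
        is_control=pd.Series([False, False, False, True], index=counts.index),
    )
    return tree, matrix


class TestDecontaminate:
    def test_golden_filters(self):
        tree, matrix = golden_matrix(None)
        out = sp.decontaminate(
            matrix,
            taxonomy=tree,
            allowlist=("Leptonychotes weddellii", "Stercorarius maccormicki"),
        )
        # t_min3: zeroed by the min-3 rule, then fails the min-sum 50 stage
        # t_contam: detected in the control, not allowlisted -> removed
        # t_allow: in control but allowlisted -> retained in samples
        # t_final_allow: allowlisted, but sample sum 15 < 20 -> final removal
        # Homo_sapiens: removed as a Primates descendant
        assert list(out.counts.columns) == ["t_allow", "t_keep"]
        assert list(out.counts.index) == ["S1", "S2", "S3"]
        assert out.counts["t_allow"].tolist() == [100, 60, 40]
        assert out.counts["t_keep"].tolist() == [40, 30, 20]

    def test_monotone_and_subset(self):
        tree, matrix = golden_matrix(None)
        out = sp.decontaminate(matrix, taxonomy=tree, allowlist=("Leptonychotes weddellii",))
        assert set(out.counts.columns) <= set(matrix.counts.columns)
        joint = matrix.counts.loc[out.counts.index, out.counts.columns]
        assert (out.counts.values <= joint.values).all()

    def test_no_controls_warns_and_skips_control_rule(self):
        counts = pd.DataFrame({"t": [60, 60]}, index=["S1", "S2"])
        m = sp.TaxonCountMatrix(counts, pd.Series([False, False], index=counts.index))
        with pytest.warns(UserWarning, match="no control samples"):
            out = sp.decontaminate(m, remove_taxa=())
        assert out.counts["t"].tolist() == [60, 60]

    def test_low_cell_zeroed(self):
        counts = pd.DataFrame({"t": [2, 60], "u": [60, 60]}, index=["S1", "S2"])
        m = sp.TaxonCountMatrix(counts, pd.Series([False, False], index=counts.index))
        with pytest.warns(UserWarning):
            out = sp.decontaminate(m, remove_taxa=())
        assert out.counts["t"].tolist() == [0, 60]


class TestNormalizeAndGroup:
    def test_tss_rows_sum_to_one(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [30, 0]}, index=["X", "Z"])
        m = sp.TaxonCountMatrix(counts, pd.Series([False, False], index=counts.index))
        norm = sp.normalize_tss(m)
        assert norm.counts.loc["X"].tolist() == [0.25, 0.75]
        assert norm.counts.loc["Z"].tolist() == [0.0, 0.0]

    def test_group_rollup_conserves_total(self, toy_tree):
        counts = pd.DataFrame(
            {"S1": [5], "S3": [2], "P1": [3], "root": [1]}, index=["X"]
        )
        m = sp.TaxonCountMatrix(counts, pd.Series([False], index=["X"]))
        g = sp.group_counts(m, toy_tree, ["Metazoa", "Plants"])
        assert g.counts.loc["X", "Metazoa"] == 7
        assert g.counts.loc["X", "Plants"] == 3
        assert g.counts.loc["X", "other"] == 1
        assert g.counts.loc["X"].sum() == counts.loc["X"].sum()

    def test_missing_group_node_errors(self, toy_tree):
        counts = pd.DataFrame({"S1": [1]}, index=["X"])
        m = sp.TaxonCountMatrix(counts, pd.Series([False], index=["X"]))
        with pytest.raises(ValueError, match="absent"):
            sp.group_counts(m, toy_tree, ["Fungi"])

    def test_rank_rollup(self, toy_tree):
        counts = pd.DataFrame({"S1": [4], "S2": [1], "S3": [2], "Metazoa": [9]}, index=["X"])
        m = sp.TaxonCountMatrix(counts, pd.Series([False], index=["X"]))
        g = rank_rollup(m, toy_tree, "genus")
        assert g.counts.loc["X", "G"] == 5
        assert g.counts.loc["X", "H"] == 2
        assert g.counts.loc["X", "other"] == 9


class TestMixtureRecovery:
    def test_three_taxon_mixture_recovered(self):
        """20k reads from a 0.7/0.2/0.1 three-taxon mixture come back within
        +-0.03 at the genus rollup.

        Taxa are diverged at 10%, safely beyond the 95% identity window, so
        reads resolve to their species.  At divergence equal to the window
        boundary (5%) cross-taxon hits become a coin flip and the LCA
        deliberately pushes those reads to the root: conservative, but then
        species proportions are not identifiable from exclusive assignments.
        """
        refs = sp.generate_references(
            31, [("tax1", 5000), ("tax2", 5000), ("tax3", 5000)], 0.10
        )
        mix = {"tax1": 0.7, "tax2": 0.2, "tax3": 0.1}
        cfg = sp.SimConfig(seed=32, n_reads=20_000, mixture=mix, d_max=0.02, seq_error=0.001)
        reads, _ = sp.simulate_sample(refs, cfg)
        hits = sp.map_reads(reads, sp.KmerIndex(refs.sequences))
        amap, unassigned = sp.assign_sample(
            hits, refs.taxon_of, refs.taxonomy, n_reads=len(reads)
        )
        raw = sp.count_matrix({"X": amap}, unassigned={"X": unassigned})
        genera = [f"{t}_genus" for t in mix]
        g = sp.group_counts(raw, refs.taxonomy, genera)
        species_assigned = g.counts.loc["X", genera].sum()
        for taxon, prop in mix.items():
            got = g.counts.loc["X", f"{taxon}_genus"] / species_assigned
            assert abs(got - prop) < 0.03, (taxon, got)
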