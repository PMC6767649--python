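"""Origin-node assignment, loss inference, tree pruning, age relationship."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from conftest import random_binary_newick
from tryptome import phylostrat as ps
from tryptome.hit_processing import Architecture, PlacedDomain


def tree_of(newick: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    t.is_rooted = True
    return t


def brute_force_origin(tree: dendropy.Tree, present: set[str]) -> frozenset[str]:
    """Deepest node whose subtree contains every presence taxon (all-nodes search)."""
    best, best_level = None, -1
    for node in tree.preorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if present <= leaves:
            level = ps._node_level(node)
            if level > best_level:
                best, best_level = frozenset(leaves), level
    return best


def arch(pid, *families):
    pos = 1
    doms = []
    for f in families:
        doms.append(PlacedDomain(family=f, start=pos, end=pos + 50, i_evalue=1e-8))
        pos += 60
    return Architecture(protein_id=pid, domains=tuple(doms))


class TestPresenceMatrix:
    def test_trypsin_only_taxon_has_no_pairs(self):
        pm = ps.presence_from_architectures({"Nv": [arch("a", "Trypsin")]})
        assert bool(pm.loc["Trypsin", "Nv"])
        assert not any(f.startswith("trypsin+") for f in pm.index)

    def test_association_only_where_observed(self):
        pm = ps.presence_from_architectures(
            {
                "Nv": [arch("a", "Trypsin", "ShK")],
                "Hs": [arch("b", "Trypsin"), arch("c", "ShK")],
            }
        )
        assert bool(pm.loc["trypsin+ShK", "Nv"])
        assert not bool(pm.loc["trypsin+ShK", "Hs"])  # never on the same protein
        assert bool(pm.loc["ShK", "Hs"])

    def test_round_trip_through_tsv(self, tmp_path):
        pm = ps.presence_from_architectures({"Nv": [arch("a", "Trypsin", "WSC")]})
        ps.write_presence_matrix(pm, tmp_path / "p.tsv")
        back = ps.read_presence_matrix(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(pm, back, check_names=False)


class TestAssignOrigin:
    def test_single_taxon_origin_is_leaf(self):
        tree = tree_of("((A,B),(C,D));")
        pm = pd.DataFrame({"A": [True], "B": [False], "C": [False], "D": [False]},
                          index=["f"])
        (a,) = ps.assign_origin(pm, tree)
        assert a.origin_leafset == frozenset({"A"})
        assert a.stratum == 2
        assert a.inferred_losses == ()

    def test_two_taxa_origin_is_mrca(self):
        tree = tree_of("((A,B),(C,D));")
        pm = pd.DataFrame({"A": [True], "B": [False], "C": [True], "D": [False]},
                          index=["f"])
        (a,) = ps.assign_origin(pm, tree)
        assert a.origin_leafset == frozenset("ABCD")  # root
        assert a.stratum == 0
        assert set(map(frozenset, a.inferred_losses)) == {frozenset("B"), frozenset("D")}

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            n = int(rng.integers(4, 33))
            tree = tree_of(random_binary_newick(rng, n))
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            k = int(rng.integers(1, n + 1))
            present = set(rng.choice(leaves, size=k, replace=False))
            pm = pd.DataFrame({t: [t in present] for t in leaves}, index=["f"])
            (a,) = ps.assign_origin(pm, tree)
            assert a.origin_leafset == brute_force_origin(tree, present)

    def test_loss_clades_disjoint_and_absent(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            tree = tree_of(random_binary_newick(rng, 12))
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            present = set(rng.choice(leaves, size=5, replace=False))
            pm = pd.DataFrame({t: [t in present] for t in leaves}, index=["f"])
            (a,) = ps.assign_origin(pm, tree)
            seen: set[str] = set()
            for clade in a.inferred_losses:
                assert not (clade & present)
                assert not (clade & seen)
                seen |= clade
            # losses + presences tile the origin subtree
            assert seen | set(a.origin_leafset) - seen >= present

    def test_adding_presence_taxon_never_younger(self):
        rng = np.random.default_rng(13)
        tree = tree_of(random_binary_newick(rng, 16))
        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        present = {leaves[0]}
        last = None
        for taxon in leaves[1:]:
            present.add(taxon)
            pm = pd.DataFrame({t: [t in present] for t in leaves}, index=["f"])
            (a,) = ps.assign_origin(pm, tree)
            if last is not None:
                assert a.stratum <= last
            last = a.stratum

    def test_zero_presence_feature_skipped(self):
        tree = tree_of("(A,B);")
        pm = pd.DataFrame({"A": [False], "B": [False]}, index=["f"])
        assert ps.assign_origin(pm, tree) == []

    def test_outgroup_plus_ingroup_origin_is_root(self):
        tree = tree_of("(Out,(A,(B,C)));")
        pm = pd.DataFrame({"Out": [True], "A": [False], "B": [True], "C": [False]},
                          index=["f"])
        (a,) = ps.assign_origin(pm, tree)
        assert a.stratum == 0


class TestAgeRelationship:
    def make(self, feature, stratum):
        return ps.OriginAssignment(
            feature=feature, origin_label=None, origin_leafset=frozenset({"x"}),
            stratum=stratum, inferred_losses=(),
        )

    def test_identical_age_vectors_correlate_perfectly(self):
        doms = [self.make(f, s) for f, s in [("A", 0), ("B", 1), ("C", 2)]]
        assocs = [self.make(f"trypsin+{f}", s) for f, s in [("A", 0), ("B", 1), ("C", 2)]]
        table, (rho, _p) = ps.age_relationship(doms, assocs)
        assert rho == pytest.approx(1.0)
        assert (table["domain_stratum"] == table["association_stratum"]).all()

    def test_toy_table_vs_hand_ranked_spearman(self):
        dom_strata = [0, 0, 1, 2, 3, 3]
        assoc_strata = [5, 2, 1, 4, 3, 6]
        doms = [self.make(f"F{i}", s) for i, s in enumerate(dom_strata)]
        assocs = [self.make(f"trypsin+F{i}", s) for i, s in enumerate(assoc_strata)]
        _table, (rho, _p) = ps.age_relationship(doms, assocs)

        def midranks(xs):
            order = sorted(range(len(xs)), key=lambda i: xs[i])
            ranks = [0.0] * len(xs)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        rx,ry = midranks(dom_strata), midranks(assoc_strata)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_association_predating_domain_errors(self):
        doms = [self.make("A", 3)]
        assocs = [self.make("trypsin+A", 1)]
        with pytest.raises(ValueError, match="trypsin\\+A"):
            ps.age_relationship(doms, assocs)

    def test_missing_domain_partner_errors(self):
        with pytest.raises(ValueError, match="no matching domain"):
            ps.age_relationship([], [self.make("trypsin+Z", 1)])


class TestPruneTree:
    @staticmethod
    def canonical(tree: dendropy.Tree):
        def go(node):
            if node.is_leaf():
                return node.taxon.label
            return frozenset(go(c) for c in node.child_nodes())

        return go(tree.seed_node)

    def oracle_induced(self, tree: dendropy.Tree, keep: set[str]):
        """Rebuild the induced subtree from scratch, suppressing unifurcations."""
        def go(node):
            if node.is_leaf():
                return node.taxon.label if node.taxon.label in keep else None
            kids = [k for k in (go(c) for c in node.child_nodes()) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return frozenset(kids)

        return go(tree.seed_node)

    def test_keep_all_is_identity(self):
        tree = tree_of("((A,B),(C,(D,E)));")
        keep = [lf.taxon.label for lf in tree.leaf_node_iter()]
        assert self.canonical(ps.prune_tree(tree, keep)) == self.canonical(tree)

    def test_keep_two_leaves(self):
        tree = tree_of("(((A,B),(C,D)),((E,F),(G,H)));")
        pruned = ps.prune_tree(tree, ["A", "H"])
        assert {lf.taxon.label for lf in pruned.leaf_node_iter()} == {"A", "H"}

    def test_random_subsets_vs_induced_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(4, 17))
            tree = tree_of(random_binary_newick(rng, n))
            leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
            k = int(rng.integers(2, n + 1))
            keep = set(rng.choice(leaves, size=k, replace=False))
            pruned = ps.prune_tree(tree, sorted(keep))
            assert self.canonical(pruned) == self.oracle_induced(tree, keep)

    def test_unknown_taxon_errors(self):
        with pytest.raises(ValueError, match="unknown taxa"):
            ps.prune_tree(tree_of("(A,B);"), ["A", "Z"])

    def test_input_tree_unmodified(self):
        tree = tree_of("((A,B),(C,D));")
        before = self.canonical(tree)
        ps.prune_tree(tree, ["A", "C"])
        assert self.canonical(tree) == before
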