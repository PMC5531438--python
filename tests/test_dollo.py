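"""Dollo mapping, synapomorphy counting, enrichment, networks, bipartitions."""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np
import pandas as pd
import pytest

from ecdysocomp._stats import exact_rank_sum_p, mann_whitney_u, rank_sum_test
from ecdysocomp.dollo import (average_normalized_weight, bipartition_support,
                              build_presence_matrix, clade_enrichment_test,
                              compare_hypotheses, cooccurrence_network,
                              coverage_histogram, dollo_map,
                              overrepresentation_fold, synapomorphies_at_node,
                              threshold_synapomorphy_report)
from ecdysocomp.errors import EcdysocompError
from ecdysocomp.formats import SpeciesTree
from ecdysocomp.simulate import simulate_gene_families
from .conftest import NEWICK_TA, NEWICK_TN, make_clusters


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

class TestPresenceMatrix:
    def test_counts_and_booleans(self):
        ct = make_clusters({"OG1": {"A": {"a1", "a2"}},
                            "OG2": {"A": {"a3"}, "B": {"b1"}}},
                           species_order=["A", "B", "C"])
        m = build_presence_matrix(ct)
        assert m.counts.shape == (2, 3)
        assert m.counts.loc["OG1", "A"] == 2
        assert bool(m.presence.loc["OG1", "A"]) is True
        assert bool(m.presence.loc["OG1", "B"]) is False

    def test_subset_drops_empty_families(self):
        ct = make_clusters({"OG1": {"A": {"a1"}}, "OG2": {"B": {"b1"}}},
                           species_order=["A", "B"])
        m = build_presence_matrix(ct, species_subset=["B"])
        assert m.families == ["OG2"]

    def test_unknown_subset_species(self):
        ct = make_clusters({"OG1": {"A": {"a1"}}}, species_order=["A"])
        with pytest.raises(EcdysocompError):
            build_presence_matrix(ct, species_subset=["Z"])


# ---------------------------------------------------------------------------
# Dollo mapping + brute-force oracle
# ---------------------------------------------------------------------------

def _brute_force_dollo(tree: SpeciesTree, present: set[str]):
    """Independent minimum-loss search: the birth must be an ancestor of all
    present leaves; losses can only root all-absent subtrees. Enumerate every
    (birth, loss subset) assignment and keep the consistent minimum."""
    best = None
    nodes = list(tree.tree.preorder_node_iter())
    for birth in nodes:
        below = tree.leafset(birth)
        if not present <= below:
            continue
        candidates = [n for n in tree.tree.preorder_node_iter()
                      if tree.leafset(n) <= below
                      and tree.leafset(n).isdisjoint(present)]
        for k in range(len(candidates) + 1):
            if best is not None and k >= best[0]:
                break
            for losses in combinations(candidates, k):
                dead = set().union(*(tree.leafset(l) for l in losses)) if losses else set()
                alive = below - dead
                if alive == present:
                    cand = (k, tree.leafset(birth),
                            sorted((tree.leafset(l) for l in losses), key=sorted))
                    if best is None or cand[0] < best[0]:
                        best = cand
                    break
            else:
                continue
            break
    return best


class TestDolloMap:
    def test_full_presence_no_losses(self):
        t = SpeciesTree.from_newick("((A,B),(C,D));")
        m = dollo_map(t, {"A", "B", "C", "D"})
        assert m.birth_node == frozenset("ABCD") and m.n_losses == 0

    def test_single_leaf_birth(self):
        t = SpeciesTree.from_newick("((A,B),(C,D));")
        m = dollo_map(t, {"A"})
        assert m.birth_node == frozenset({"A"}) and m.n_losses == 0

    def test_alternate_leaves_two_losses(self):
        t = SpeciesTree.from_newick("((A,B),(C,D));")
        m = dollo_map(t, {"A", "C"})
        assert m.birth_node == frozenset("ABCD")
        assert m.n_losses == 2
        assert sorted(sorted(l) for l in m.loss_nodes) == [["B"], ["D"]]

    def test_all_absent_errors(self):
        t = SpeciesTree.from_newick("((A,B),(C,D));")
        with pytest.raises(EcdysocompError):
            dollo_map(t, set())

    def test_matches_brute_force_on_all_rows_of_8_leaf_tree(self, eight_leaf_tree):
        """Every one of the 255 non-empty presence rows: birth node, loss
        count and loss set equal the exhaustive minimum-loss assignment."""
        leaves = eight_leaf_tree.leaf_labels
        for bits in range(1, 2 ** 8):
            present = {leaves[i] for i in range(8) if bits >> i & 1}
            m = dollo_map(eight_leaf_tree, present)
            k, birth, losses = _brute_force_dollo(eight_leaf_tree, present)
            assert m.n_losses == k
            assert m.birth_node == birth
            assert sorted(m.loss_nodes, key=sorted) == losses


# ---------------------------------------------------------------------------
# synapomorphies
# ---------------------------------------------------------------------------

def _matrix_from_presence(rows: dict[str, set[str]], species: list[str]):
    ct = make_clusters(
        {fam: {sp: {f"{sp}|{fam}"} for sp in present}
         for fam, present in rows.items()},
        species_order=species)
    return build_presence_matrix(ct)


class TestSynapomorphies:
    def test_full_coverage(self, tree_ta):
        species = tree_ta.leaf_labels
        panarthropoda = {"T1", "T2", "A1", "A2", "A3", "A4"}
        m = _matrix_from_presence({"OGfull": set(panarthropoda)}, species)
        (rec,) = synapomorphies_at_node(tree_ta, m, "Panarthropoda")
        assert rec.proportion_coverage == 1.0

    def test_partial_coverage_arithmetic(self, tree_ta):
        """3 of 4 arthropods + 1 of 2 tardigrades -> 4/6 coverage."""
        m = _matrix_from_presence({"OGpart": {"A1", "A2", "A3", "T1"}},
                                  tree_ta.leaf_labels)
        (rec,) = synapomorphies_at_node(tree_ta, m, "Panarthropoda")
        assert rec.proportion_coverage == pytest.approx(4 / 6)

    def test_single_child_family_excluded(self, tree_ta):
        """A family present only in arthropods is never credited to the
        deeper tardigrade+arthropod node."""
        m = _matrix_from_presence({"OGarth": {"A1", "A2", "A3", "A4"}},
                                  tree_ta.leaf_labels)
        assert synapomorphies_at_node(tree_ta, m, "Panarthropoda") == []
        assert len(synapomorphies_at_node(tree_ta, m, "Arthropoda")) == 1

    def test_family_present_outside_not_credited(self, tree_ta):
        m = _matrix_from_presence({"OGwide": {"T1", "A1", "N1"}},
                                  tree_ta.leaf_labels)
        assert synapomorphies_at_node(tree_ta, m, "Panarthropoda") == []

    def test_leaf_node_rejected(self, tree_ta):
        m = _matrix_from_presence({"OG": {"T1"}}, tree_ta.leaf_labels)
        with pytest.raises(EcdysocompError):
            synapomorphies_at_node(tree_ta, m, "T1")

    def test_two_leaf_clade_coverage_always_one(self, tree_ta):
        """Any synapomorphy of a 2-leaf clade must cover both leaves."""
        rows = {f"OG{i}": s for i, s in enumerate(
            [{"T1", "T2"}, {"T1"}, {"T2"}, {"T1", "T2", "A1"}])}
        m = _matrix_from_presence(rows, tree_ta.leaf_labels)
        recs = synapomorphies_at_node(tree_ta, m, "Tardigrada")
        assert [r.family_id for r in recs] == ["OG0"]
        assert all(r.proportion_coverage == 1.0 for r in recs)


class TestCompareHypotheses:
    def test_identical_subtree_nodes_identical_sets(self, tree_tn, tree_ta):
        """Nematoda and Arthropoda subtrees are shared by both hypotheses,
        so their synapomorphy *sets* (not just counts) must agree."""
        tree = tree_tn
        clusters, _ = simulate_gene_families(tree, n_families=300,
                                             loss_prob_per_branch=0.15, seed=5)
        matrix = build_presence_matrix(clusters)
        res = compare_hypotheses(matrix, tree_tn, tree_ta,
                                 {"Nematoda": "Nematoda",
                                  "Arthropoda": "Arthropoda",
                                  "Tardigrada": "Tardigrada"})
        for node in ("Nematoda", "Arthropoda", "Tardigrada"):
            assert res["A"][node]["families"] == res["B"][node]["families"]

    def test_planted_births_recovered(self, tree_ta):
        species = tree_ta.leaf_labels
        clade = {"T1", "T2", "A1", "A2", "A3", "A4"}
        rows = {f"OGplant{i}": set(clade) for i in range(20)}
        m = _matrix_from_presence(rows, species)
        res = compare_hypotheses(m, tree_ta, tree_ta,
                                 {"Panarthropoda": "Panarthropoda"})
        assert res["A"]["Panarthropoda"]["count"] == 20

    def test_empty_matrix_zero_counts(self, tree_tn, tree_ta):
        m = _matrix_from_presence({}, tree_tn.leaf_labels)
        res = compare_hypotheses(m, tree_tn, tree_ta, {"Nematoda": "Nematoda"})
        assert res["A"]["Nematoda"]["count"] == 0

    def test_leafset_mismatch_errors(self, tree_tn):
        other = SpeciesTree.from_newick("(A,(B,C));")
        m = _matrix_from_presence({}, tree_tn.leaf_labels)
        with pytest.raises(EcdysocompError):
            compare_hypotheses(m, tree_tn, other, {})

    def test_missing_node_reported_none(self, tree_tn, tree_ta):
        m = _matrix_from_presence({}, tree_tn.leaf_labels)
        res = compare_hypotheses(m, tree_tn, tree_ta,
                                 {"TarNem": "TarNem"})
        assert res["A"]["TarNem"] is not None
        assert res["B"]["TarNem"] is None


class TestThresholdReport:
    def _records(self, tree, rows):
        m = _matrix_from_presence(rows, tree.leaf_labels)
        return synapomorphies_at_node(tree, m, "Panarthropoda"), m

    def test_boundary_retention(self, tree_ta):
        # 5/6 = 0.83 retained; 3/6 = 0.5 dropped at min_coverage 0.7
        recs, m = self._records(tree_ta, {
            "OGhi": {"T1", "T2", "A1", "A2", "A3"},
            "OGlo": {"T1", "A1", "A2"}})
        df = threshold_synapomorphy_report(recs, 0.7, clades={
            "Tardigrada": ["T1", "T2"],
            "Arthropoda": ["A1", "A2", "A3", "A4"]}, matrix=m)
        assert list(df["family_id"]) == ["OGhi"]
        assert df.iloc[0]["Tardigrada"] == 1.0
        assert df.iloc[0]["Arthropoda"] == 0.75

    def test_all_below_threshold_empty(self, tree_ta):
        recs, _ = self._records(tree_ta, {"OGlo": {"T1", "A1"}})
        assert len(threshold_synapomorphy_report(recs, 0.7)) == 0

    def test_coverage_histogram_bins(self, tree_ta):
        recs, _ = self._records(tree_ta, {
            "OGfull": {"T1", "T2", "A1", "A2", "A3", "A4"},  # 1.0 -> closed bin
            "OGpart": {"T1", "A1", "A2"},                     # 0.5
        })
        hist = coverage_histogram(recs)
        assert hist["1.0"] == 1
        assert hist["[0.5,0.6)"] == 1
        assert hist.sum() == 2


# ---------------------------------------------------------------------------
# enrichment / overrepresentation
# ---------------------------------------------------------------------------

def _counts_clusters(fam_counts: dict[str, dict[str, int]], species: list[str]):
    fams = {}
    for fam, counts in fam_counts.items():
        fams[fam] = {sp: {f"{sp}|{fam}|{i}" for i in range(n)}
                     for sp, n in counts.items() if n > 0}
    return make_clusters(fams, species_order=species)


class TestEnrichment:
    def test_exact_p_matches_independent_enumeration(self):
        """Focal (3,3) vs 7 others all at 1: implementation's p equals a
        from-scratch permutation enumeration."""
        species = ["T1", "T2"] + [f"o{i}" for i in range(7)]
        ct = _counts_clusters(
            {"OG1": {"T1": 3, "T2": 3, **{f"o{i}": 1 for i in range(7)}}}, species)
        df = clade_enrichment_test(ct, ["T1", "T2"])
        # independent enumeration over assignments of pooled values
        from scipy.stats import rankdata
        pooled = np.array([3, 3] + [1] * 7, dtype=float)
        ranks = rankdata(pooled)
        mu = 2 * 7 / 2.0
        u_obs = ranks[:2].sum() - 3.0
        n_ext = n_tot = 0
        for idx in combinations(range(9), 2):
            u = ranks[list(idx)].sum() - 3.0
            n_tot += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                n_ext += 1
        assert df.iloc[0]["p_value"] == pytest.approx(n_ext / n_tot)
        assert df.iloc[0]["direction"] == "enriched"

    def test_flat_counts_p_one(self):
        species = ["T1", "T2"] + [f"o{i}" for i in range(5)]
        ct = _counts_clusters({"OG1": {sp: 2 for sp in species}}, species)
        df = clade_enrichment_test(ct, ["T1", "T2"])
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)
        assert not df.iloc[0]["significant"]

    def test_single_nonzero_taxon_skipped(self):
        species = ["T1", "T2", "o1", "o2"]
        ct = _counts_clusters({"OG1": {"T1": 5},
                               "OG2": {"T1": 1, "o1": 1}}, species)
        df = clade_enrichment_test(ct, ["T1", "T2"])
        assert list(df["family_id"]) == ["OG2"]

    def test_bonferroni_divides_by_tested_families(self):
        species = ["T1", "T2"] + [f"o{i}" for i in range(6)]
        fams = {f"OG{i}": {sp: 1 for sp in species} for i in range(10)}
        fams["OGx"] = {"T1": 9, "T2": 9, **{f"o{i}": 1 for i in range(6)}}
        ct = _counts_clusters(fams, species)
        df = clade_enrichment_test(ct, ["T1", "T2"], alpha=0.01, bonferroni=True)
        p = df.set_index("family_id").loc["OGx", "p_value"]
        assert df.set_index("family_id").loc["OGx", "significant"] == \
            (p < 0.01 / len(df))

    def test_focal_equal_to_all_errors(self):
        ct = _counts_clusters({"OG1": {"A": 1, "B": 1}}, ["A", "B"])
        with pytest.raises(EcdysocompError):
            clade_enrichment_test(ct, ["A", "B"])


class TestOverrepresentation:
    def test_strong_overrepresentation_flagged(self):
        species = ["T1", "T2"] + [f"o{i}" for i in range(5)]
        ct = _counts_clusters(
            {"OG1": {"T1": 21, "T2": 20, **{f"o{i}": 1 for i in range(5)}}},
            species)
        df = overrepresentation_fold(ct, ["T1", "T2"])
        assert list(df["family_id"]) == ["OG1"]
        assert df.iloc[0]["ratio"] > 14

    def test_exact_fourfold_not_flagged(self):
        """Strict >: focal mean exactly 4x other mean is excluded."""
        species = ["T", "o1", "o2"]
        ct = _counts_clusters({"OG1": {"T": 4, "o1": 1, "o2": 1}}, species)
        assert len(overrepresentation_fold(ct, ["T"], fold=4.0)) == 0

    def test_flat_counts_none_flagged(self):
        species = ["T", "o1", "o2"]
        ct = _counts_clusters({"OG1": {sp: 2 for sp in species}}, species)
        assert len(overrepresentation_fold(ct, ["T"])) == 0


# ---------------------------------------------------------------------------
# co-occurrence network
# ---------------------------------------------------------------------------

class TestNetwork:
    def test_weights_and_normalization(self):
        fams = {f"OG{i}": {"A": {f"a{i}"}, "B": {f"b{i}"}} for i in range(10)}
        fams["OG10"] = {"A": {"a10"}, "C": {"c0"}}
        ct = make_clusters(fams, species_order=["A", "B", "C"])
        g = cooccurrence_network(ct)
        assert g["A"]["B"]["weight"] == 10
        assert g["A"]["B"]["normalized"] == 1.0
        assert g["A"]["C"]["normalized"] == pytest.approx(0.1)
        assert not g.has_edge("B", "C")  # never co-clustered -> no edge

    def test_single_species_errors(self):
        ct = make_clusters({"OG1": {"A": {"a"}}}, species_order=["A"])
        with pytest.raises(EcdysocompError):
            cooccurrence_network(ct)

    def test_average_normalized_weight(self):
        fams = {f"OG{i}": {"A": {f"a{i}"}, "B": {f"b{i}"}} for i in range(4)}
        fams["OGx"] = {"A": {"ax"}, "C": {"cx"}}
        ct = make_clusters(fams, species_order=["A", "B", "C"])
        g = cooccurrence_network(ct)
        # edges A-B (norm 1.0) and A-C (0.25); B-C missing counts as 0
        assert average_normalized_weight(g, ["A"], ["B", "C"]) == \
            pytest.approx((1.0 + 0.25) / 2)


# ---------------------------------------------------------------------------
# bipartition support
# ---------------------------------------------------------------------------

class TestBipartitionSupport:
    GROUPS = ((["a", "b"], ["c", "d"]), (["e", "f"], ["g", "h"]))

    def test_trees_from_species_topology_all_support(self, eight_leaf_tree):
        support, n_sup, n_inf = bipartition_support(
            [eight_leaf_tree] * 10, *self.GROUPS)
        assert (support, n_sup, n_inf) == (1.0, 10, 10)

    def test_missing_side_excluded_from_denominator(self):
        full = SpeciesTree.from_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        # tree with no leaves from group (g,h): uninformative
        partial = SpeciesTree.from_newick("((a,b),(c,(e,f)));")
        support, n_sup, n_inf = bipartition_support([full, partial], *self.GROUPS)
        assert n_inf == 1 and support == 1.0

    def test_counted_fraction(self):
        good = SpeciesTree.from_newick("(((a,b),(c,d)),((e,f),(g,h)));")
        bad = SpeciesTree.from_newick("(((a,e),(c,g)),((b,f),(d,h)));")
        support, n_sup, n_inf = bipartition_support(
            [good] * 6 + [bad] * 4, *self.GROUPS)
        assert n_inf == 10 and n_sup == 6
        assert support == pytest.approx(0.6)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(EcdysocompError):
            bipartition_support([], (["a"], ["a"]), (["b"], ["c"]))


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

class TestRankSum:
    @pytest.mark.parametrize("x, y", [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 1, 2], [2, 2, 3]),
        ([5], [1, 2, 3, 4]),
        ([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6]),
    ])
    def test_exact_p_brute_force(self, x, y):
        from scipy.stats import rankdata
        pooled = np.array(x + y, dtype=float)
        ranks = rankdata(pooled)
        nx = len(x)
        mu = nx * len(y) / 2.0
        off = nx * (nx + 1) / 2.0
        u_obs = ranks[:nx].sum() - off
        n_ext = n_tot = 0
        for idx in combinations(range(len(pooled)), nx):
            u = ranks[list(idx)].sum() - off
            n_tot += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
                n_ext += 1
        assert exact_rank_sum_p(x, y) == pytest.approx(n_ext / n_tot)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.2, 1, 40)
        u, p = rank_sum_test(x, y)
        from scipy.stats import mannwhitneyu
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(float(ref.pvalue))
        assert u == pytest.approx(float(ref.statistic))
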