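"""Dollo-parsimony gene-family analysis on rooted species trees.

Under Dollo parsimony a gene family is gained exactly once — at the most
recent common ancestor (MRCA) of the species that carry it — and may then
be lost any number of times. The minimal loss set is the unique cover of
the absent leaves below the birth node by maximal all-absent clades.

A family is a *synapomorphy* of an internal node when its birth maps to
that node and every child clade of the node contributes at least one
carrying species; this guards against a family that is really private to
one descendant lineage being credited to the deeper node. Counting
synapomorphies under two competing species-tree hypotheses (e.g.
Tardigrada+Nematoda versus Tardigrada+Arthropoda) gives a rare-genomic-
change signal independent of sequence-based phylogenetics: any node whose
descendant leaf set is identical in both trees must receive identical
synapomorphy sets.

The module also provides clade enrichment tests of family size
(Mann-Whitney with midranks, exact by enumeration for small n),
fold-overrepresentation screens, species co-occurrence networks, and
per-bipartition support counting over sets of single-locus gene trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from ._stats import rank_sum_test, EXACT_LIMIT
from ._util import round_half_up
from .errors import EcdysocompError
from .formats import ClusterTable, SpeciesTree


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Family x species member counts; presence is count >= 1."""

    counts: pd.DataFrame  # index = family_id, columns = species_id, int

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise EcdysocompError("negative member counts")

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    def present_species(self, family_id: str) -> set[str]:
        row = self.counts.loc[family_id]
        return set(row.index[row >= 1])


def build_presence_matrix(clusters: ClusterTable,
                          species_subset: Iterable[str] | None = None) -> PresenceMatrix:
    """Member-count matrix from a cluster table; families empty on the
    (optional) species subset are dropped."""
    species = list(species_subset) if species_subset is not None \
        else list(clusters.species_order)
    unknown = set(species) - set(clusters.species_order)
    if unknown:
        raise EcdysocompError(f"species absent from clusters: {sorted(unknown)}")
    rows = {}
    for fam in clusters.families:
        counts = clusters.counts(fam)
        vec = [counts.get(sp, 0) for sp in species]
        if sum(vec) > 0:
            rows[fam] = vec
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=species).astype(int)
    counts = counts.sort_index()
    return PresenceMatrix(counts=counts)


# ---------------------------------------------------------------------------
# Dollo mapping
# ---------------------------------------------------------------------------

@dataclass
class DolloMapping:
    family_id: str
    birth_node: frozenset[str]        # descendant leaf set of the birth node
    loss_nodes: list[frozenset[str]]  # leaf sets of the maximal absent clades
    n_losses: int


def dollo_map(tree: SpeciesTree, presence_row: Mapping[str, bool] | Iterable[str],
              family_id: str = "") -> DolloMapping:
    """Single-gain / minimal-loss mapping of one presence row.

    ``presence_row`` is either a species -> bool mapping or an iterable of
    present species. Raises on an all-absent row.
    """
    if isinstance(presence_row, Mapping):
        present = {sp for sp, v in presence_row.items() if v}
    else:
        present = set(presence_row)
    if not present:
        raise EcdysocompError("all-absent presence row has no Dollo mapping")
    missing = present - set(tree.leaf_labels)
    if missing:
        raise EcdysocompError(f"present species not in tree: {sorted(missing)}")
    birth = tree.mrca(present)
    losses: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        leaves = tree.leafset(node)
        if leaves.isdisjoint(present):
            losses.append(leaves)
            return
        for child in node.child_nodes():
            walk(child)

    for child in birth.child_nodes():
        walk(child)
    if birth.is_leaf():
        pass  # birth at a leaf: no losses possible
    return DolloMapping(family_id=family_id, birth_node=tree.leafset(birth),
                        loss_nodes=sorted(losses, key=sorted), n_losses=len(losses))


# ---------------------------------------------------------------------------
# synapomorphies
# ---------------------------------------------------------------------------

@dataclass
class SynapomorphyRecord:
    node: frozenset[str]       # descendant leaf set of the node
    family_id: str
    n_proteins: int
    n_present: int
    n_descendants: int
    proportion_coverage: float
    child_representation: list[bool]

    @property
    def present_species(self) -> int:
        return self.n_present


def synapomorphies_at_node(tree: SpeciesTree, matrix: PresenceMatrix,
                           node) -> list[SynapomorphyRecord]:
    """Families born at ``node`` with every child clade represented.

    ``node`` may be a dendropy node, an internal-node label, or a leaf set.
    Coverage is (# descendant species carrying the family) / (# descendant
    species).
    """
    if not isinstance(node, dendropy.Node):
        node = tree.find_node(node)
    if node.is_leaf():
        raise EcdysocompError("synapomorphies are defined for internal nodes only")
    descendants = tree.leafset(node)
    child_sets = [tree.leafset(c) for c in node.child_nodes()]
    records = []
    cols = [sp for sp in matrix.species if sp in descendants]
    outside = [sp for sp in matrix.species if sp not in descendants]
    sub = matrix.counts
    for fam in matrix.families:
        row = sub.loc[fam]
        if outside and (row[outside] >= 1).any():
            continue  # present outside the node: born deeper
        present = {sp for sp in cols if row[sp] >= 1}
        if not present:
            continue
        flags = [bool(present & cs) for cs in child_sets]
        if not all(flags):
            continue  # birth maps inside one child clade
        records.append(SynapomorphyRecord(
            node=descendants, family_id=fam,
            n_proteins=int(row.sum()),
            n_present=len(present), n_descendants=len(descendants),
            proportion_coverage=len(present) / len(descendants),
            child_representation=flags))
    return records


#: histogram bin edges for coverage: [0,0.1), ..., [0.9,1.0), plus closed {1.0}
COVERAGE_BINS = [round(0.1 * i, 1) for i in range(11)]


def coverage_histogram(records: Sequence[SynapomorphyRecord]) -> pd.Series:
    """Counts of records per coverage bin of width 0.1; exact 1.0 coverage
    gets its own closed bin."""
    labels = [f"[{COVERAGE_BINS[i]:.1f},{COVERAGE_BINS[i+1]:.1f})" for i in range(10)]
    labels.append("1.0")
    counts = dict.fromkeys(labels, 0)
    for r in records:
        c = r.proportion_coverage
        if c >= 1.0:
            counts["1.0"] += 1
        else:
            counts[labels[min(int(c * 10), 9)]] += 1
    return pd.Series(counts, name="n_families")


def compare_hypotheses(matrix: PresenceMatrix, tree_a: SpeciesTree,
                       tree_b: SpeciesTree,
                       focal_nodes: Mapping[str, object]
                       ) -> dict[str, dict[str, dict]]:
    """Synapomorphy counts and coverage histograms per focal node under two
    competing species trees.

    ``focal_nodes`` maps a display name to a node key (internal label or
    leaf set) resolved against each tree; a node absent from one hypothesis
    is reported as None there.
    """
    if set(tree_a.leaf_labels) != set(tree_b.leaf_labels):
        raise EcdysocompError("hypothesis trees must share their leaf set")
    out: dict[str, dict[str, dict]] = {"A": {}, "B": {}}
    for hyp, tree in (("A", tree_a), ("B", tree_b)):
        for name, key in focal_nodes.items():
            try:
                node = tree.find_node(key)
            except KeyError:
                out[hyp][name] = None
                continue
            records = synapomorphies_at_node(tree, matrix, node)
            out[hyp][name] = {
                "count": len(records),
                "families": sorted(r.family_id for r in records),
                "histogram": coverage_histogram(records),
            }
    return out


def threshold_synapomorphy_report(records: Sequence[SynapomorphyRecord],
                                  min_coverage: float = 0.7,
                                  clades: Mapping[str, Iterable[str]] | None = None,
                                  matrix: PresenceMatrix | None = None
                                  ) -> pd.DataFrame:
    """Tabulate synapomorphies with coverage >= ``min_coverage``.

    With ``clades`` (name -> species subset) and the presence matrix, adds
    per-clade representation columns (fraction of the clade's proteomes
    carrying the family, 2 decimals).
    """
    rows = []
    for r in records:
        if r.proportion_coverage < min_coverage:
            continue
        row = {
            "family_id": r.family_id,
            "n_proteins": r.n_proteins,
            "proportion_coverage": round_half_up(r.proportion_coverage, 2),
        }
        if clades is not None and matrix is not None:
            for cname, members in clades.items():
                members = [sp for sp in members if sp in matrix.species]
                if not members:
                    row[cname] = float("nan")
                    continue
                pres = matrix.present_species(r.family_id)
                row[cname] = round_half_up(
                    sum(1 for sp in members if sp in pres) / len(members), 2)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["proportion_coverage", "family_id"],
                            ascending=[False, True]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# enrichment and overrepresentation
# ---------------------------------------------------------------------------

def clade_enrichment_test(clusters: ClusterTable, focal_species_set: Iterable[str],
                          alpha: float = 0.01, bonferroni: bool = False,
                          exact_limit: int = EXACT_LIMIT) -> pd.DataFrame:
    """Two-sided rank-sum test of per-species member counts, focal clade
    versus all other species, per family.

    Families where fewer than 2 taxa have non-zero counts are skipped.
    With ``bonferroni`` the significance threshold becomes alpha / number
    of families actually tested.
    """
    focal = list(dict.fromkeys(focal_species_set))
    others = [sp for sp in clusters.species_order if sp not in focal]
    if not focal or not others:
        raise EcdysocompError("focal set must be a proper non-empty subset of species")
    rows = []
    for fam in sorted(clusters.families):
        counts = clusters.counts(fam)
        x = np.array([counts[sp] for sp in focal], dtype=float)
        y = np.array([counts[sp] for sp in others], dtype=float)
        if (np.count_nonzero(x) + np.count_nonzero(y)) < 2:
            continue
        u, p = rank_sum_test(x, y, exact_limit=exact_limit)
        mean_f, mean_o = x.mean(), y.mean()
        if mean_o > 0 and mean_f > 0:
            log2_ratio = float(np.log2(mean_f / mean_o))
        elif mean_f > 0:
            log2_ratio = float("inf")
        else:
            log2_ratio = float("-inf")
        rows.append({"family_id": fam, "mean_focal": mean_f, "mean_other": mean_o,
                     "direction": "enriched" if mean_f > mean_o
                     else ("depleted" if mean_f < mean_o else "equal"),
                     "log2_mean_ratio": log2_ratio, "u_statistic": u, "p_value": p})
    df = pd.DataFrame(rows)
    if len(df):
        threshold = alpha / len(df) if bonferroni else alpha
        df["significant"] = df["p_value"] < threshold
    return df


def overrepresentation_fold(clusters: ClusterTable, focal_species_set: Iterable[str],
                            fold: float = 4.0) -> pd.DataFrame:
    """Families where the focal-clade mean member count strictly exceeds
    ``fold`` times the mean over all other species (zeros included)."""
    focal = list(dict.fromkeys(focal_species_set))
    others = [sp for sp in clusters.species_order if sp not in focal]
    rows = []
    for fam in sorted(clusters.families):
        counts = clusters.counts(fam)
        mean_f = float(np.mean([counts[sp] for sp in focal]))
        mean_o = float(np.mean([counts[sp] for sp in others])) if others else 0.0
        if mean_f > fold * mean_o:
            ratio = mean_f / mean_o if mean_o > 0 else float("inf")
            rows.append({"family_id": fam, "mean_focal": mean_f,
                         "mean_other": mean_o, "ratio": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# co-occurrence network
# ---------------------------------------------------------------------------

def cooccurrence_network(clusters: ClusterTable) -> nx.Graph:
    """Species graph; edge weight = number of families containing both
    species, ``normalized`` = weight / maximum weight over reported edges.
    Species pairs never co-clustered get no edge."""
    species = clusters.species_order
    if len(species) < 2:
        raise EcdysocompError("co-occurrence network needs >= 2 species")
    graph = nx.Graph()
    graph.add_nodes_from(species)
    for fam in clusters.families:
        members = sorted(clusters.species_of_family(fam))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if graph.has_edge(a, b):
                    graph[a][b]["weight"] += 1
                else:
                    graph.add_edge(a, b, weight=1)
    if graph.number_of_edges():
        w_max = max(d["weight"] for _, _, d in graph.edges(data=True))
        for _, _, d in graph.edges(data=True):
            d["normalized"] = d["weight"] / w_max
    return graph


def average_normalized_weight(graph: nx.Graph, group_a: Iterable[str],
                              group_b: Iterable[str]) -> float:
    """Mean of normalized edge weights between two species groups
    (normalization precedes averaging); absent edges count as 0."""
    group_a, group_b = list(group_a), list(group_b)
    weights = []
    for a in group_a:
        for b in group_b:
            if a == b:
                continue
            d = graph.get_edge_data(a, b)
            weights.append(d["normalized"] if d else 0.0)
    if not weights:
        raise EcdysocompError("no species pairs between the groups")
    return float(np.mean(weights))


# ---------------------------------------------------------------------------
# bipartition support over gene trees
# ---------------------------------------------------------------------------

def bipartition_support(gene_trees: Sequence[SpeciesTree],
                        side_a: tuple[Iterable[str], Iterable[str]],
                        side_b: tuple[Iterable[str], Iterable[str]]
                        ) -> tuple[float, int, int]:
    """Fraction of informative gene trees displaying the split A|B.

    The split is given as four leaf groups, two per side (the four subtrees
    adjacent to the tested internal edge of the species tree). A gene tree —
    which may contain only a subset of the species — is *informative* iff it
    carries at least one leaf from each of the four groups, and *supports*
    the split iff, as an unrooted tree, it has an edge separating its A
    leaves from its B leaves. Returns (support, n_supporting, n_informative).
    """
    a1, a2 = set(side_a[0]), set(side_a[1])
    b1, b2 = set(side_b[0]), set(side_b[1])
    groups = [a1, a2, b1, b2]
    for i, g in enumerate(groups):
        if not g:
            raise EcdysocompError("all four bipartition groups must be non-empty")
        for h in groups[i + 1:]:
            if g & h:
                raise EcdysocompError("bipartition groups must be disjoint")
    set_a, set_b = a1 | a2, b1 | b2
    n_informative = 0
    n_supporting = 0
    for gt in gene_trees:
        leaves = set(gt.leaf_labels)
        if any(not (leaves & g) for g in groups):
            continue
        n_informative += 1
        present_a = leaves & set_a
        present_b = leaves & set_b
        extraneous = leaves - set_a - set_b
        if _displays_split(gt, present_a, present_b, extraneous):
            n_supporting += 1
    support = n_supporting / n_informative if n_informative else float("nan")
    return support, n_supporting, n_informative


def _displays_split(tree: SpeciesTree, side_a: set[str], side_b: set[str],
                    ignore: set[str]) -> bool:
    """True iff some edge of the (unrooted) tree separates side_a from
    side_b, ignoring leaves in ``ignore``."""
    all_relevant = side_a | side_b
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = tree.leafset(node) & all_relevant
        if not below or below == all_relevant:
            continue
        if below == side_a or below == side_b:
            return True
        rest = all_relevant - below
        if rest == side_a or rest == side_b:
            return True
    return False
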