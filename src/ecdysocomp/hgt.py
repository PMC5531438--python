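"""HGT-index screening and the tiered validation cascade.

The HGT index of a gene is ``Hu = Bo - Bm``: the bit-score difference
between its best non-metazoan homology hit (Bo) and its best metazoan hit
(Bm), after discarding hits at or above the E-value cutoff. Genes with
``Hu >= tau`` (default 30 bits) and at least one non-metazoan hit are HGT
candidates. Candidates are then sifted through biological filters:

* tree-of-origin classification on a per-candidate gene tree (a candidate
  nesting inside a clean prokaryote / virus / non-metazoan-eukaryote clade
  is confirmed; one nesting inside metazoa is rejected),
* expression support (TPM above a cutoff in at least one library, or in
  the library mean, switchable),
* phyletic perdurance (an orthogroup shared with a sister species),
* intron presence (reported, but never gates a tier — gene finders are
  biased toward predicting introns).

Tiers are nested: ``high`` (tree-confirmed AND expressed AND conserved in
the sister species) is a subset of ``supported`` (tree-confirmed), itself
a subset of ``candidate`` (everything the index flagged). ``rejected``
marks candidates whose gene tree places them inside metazoa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._util import percentage
from .errors import EcdysocompError
from .formats import (GeneModelTable, HitTable, ClusterTable, ExpressionTable,
                      SpeciesTree, NONMETAZOAN_GROUPS)

HGT_CONFIRMED_CATEGORIES = frozenset(
    {"prokaryote", "virus", "nonmetazoan_eukaryote", "complex_hgt"})
REJECTED_CATEGORIES = frozenset({"metazoan", "complex_non_hgt"})

#: sentinel used for left/right neighbour distances at scaffold ends
SCAFFOLD_END_SENTINEL = 1000000


@dataclass
class ScreenConfig:
    """Thresholds of the screen; defaults are the standard published values."""

    tau: float = 30.0                 # bits; candidate iff Hu >= tau
    evalue_cutoff: float = 1e-5       # keep hits with evalue < cutoff
    expression_tpm_cutoff: float = 1.0
    expression_rule: str = "any_library"   # or "mean"
    min_tree_leaves: int = 4
    cluster_max_gap: int = 1          # intervening non-HGT genes allowed

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if self.expression_rule not in ("any_library", "mean"):
            raise ValueError(f"unknown expression_rule {self.expression_rule!r}")


@dataclass
class HgtScore:
    gene_id: str
    bo: float            # best non-metazoan bitscore, 0 if no such hit
    bm: float            # best metazoan bitscore, 0 if no such hit
    hu: float            # Bo - Bm
    hit_pattern: str     # both | metazoan_only | nonmetazoan_only | none
    is_candidate: bool
    best_nonmetazoan_subject: str | None = None
    best_metazoan_subject: str | None = None


@dataclass
class HgtValidation:
    gene_id: str
    tree_category: str           # prokaryote|virus|nonmetazoan_eukaryote|metazoan|
                                 # complex_hgt|complex_non_hgt|insufficient
    expressed: bool | None       # None = expression data unavailable
    has_intron: bool | None
    conserved_in_sister: bool | None
    tier: str = ""               # high | supported | candidate_only | rejected

    def __post_init__(self) -> None:
        if not self.tier:
            self.tier = assign_tier(self.tree_category, self.expressed,
                                    self.conserved_in_sister)


def compute_hgt_index(hits: HitTable, config: ScreenConfig | None = None,
                      query_species_id: str | None = None,
                      queries: Iterable[str] | None = None) -> list[HgtScore]:
    """Score every query in ``hits`` (plus any extra ids in ``queries``).

    Hits with ``evalue >= config.evalue_cutoff`` are discarded before the
    maxima are taken; hits whose subject species equals
    ``query_species_id`` (self-hits / same-lineage hits) are excluded, which
    emulates searching against a database stripped of the query's own
    lineage. Ties at the maximum keep the lexicographically smallest
    subject for reporting; the score is unaffected.
    """
    config = config or ScreenConfig()
    df = hits.df
    if len(df):
        df = df[df["evalue"] < config.evalue_cutoff]
        if query_species_id is not None:
            df = df[df["subject_species_id"] != query_species_id]
    all_queries: list[str] = sorted(set(df["query_id"]) | set(queries or ()))
    scores: list[HgtScore] = []
    grouped = {q: g for q, g in df.groupby("query_id")} if len(df) else {}
    for q in all_queries:
        g = grouped.get(q)
        bo = bm = 0.0
        bo_subj = bm_subj = None
        if g is not None and len(g):
            non = g[g["subject_taxon_group"].isin(NONMETAZOAN_GROUPS)]
            met = g[g["subject_taxon_group"] == "metazoan"]
            if len(non):
                bo = float(non["bitscore"].max())
                bo_subj = non.loc[non["bitscore"] == bo, "subject_id"].min()
            if len(met):
                bm = float(met["bitscore"].max())
                bm_subj = met.loc[met["bitscore"] == bm, "subject_id"].min()
        if bo > 0 and bm > 0:
            pattern = "both"
        elif bo > 0:
            pattern = "nonmetazoan_only"
        elif bm > 0:
            pattern = "metazoan_only"
        else:
            pattern = "none"
        hu = bo - bm
        scores.append(HgtScore(gene_id=q, bo=bo, bm=bm, hu=hu, hit_pattern=pattern,
                               is_candidate=(hu >= config.tau and bo > 0),
                               best_nonmetazoan_subject=bo_subj,
                               best_metazoan_subject=bm_subj))
    return scores


# ---------------------------------------------------------------------------
# tree-of-origin classification
# ---------------------------------------------------------------------------

def _maybe_midpoint_root(tree: SpeciesTree) -> SpeciesTree:
    """Midpoint-root when branch lengths are available; per-candidate gene
    trees carry no guaranteed outgroup, so midpoint rooting is the neutral
    choice. Trees without lengths keep their given rooting."""
    t = tree.tree
    has_lengths = any(e.length for e in t.preorder_edge_iter())
    if has_lengths:
        t = t.clone(depth=1)
        try:
            t.reroot_at_midpoint(update_bipartitions=False)
        except Exception:
            return tree
        return SpeciesTree(t)
    return tree


def classify_tree_origin(gene_tree: SpeciesTree, query_leaf: str,
                         taxon_groups: Mapping[str, str],
                         config: ScreenConfig | None = None) -> str:
    """Classify an HGT candidate by the taxon composition of its gene tree.

    From the query leaf, walk rootward and keep enlarging the clade while
    all its non-query leaves share a single taxon group; the group of the
    largest such clade is the category. If even the first informative
    clade mixes groups, the candidate is ``complex_non_hgt`` when metazoan
    leaves are the strict majority of that clade (the query nests within a
    metazoan radiation) and ``complex_hgt`` otherwise (HGT affirmed,
    affinity unclear). Trees with fewer than ``min_tree_leaves`` leaves are
    ``insufficient``.
    """
    config = config or ScreenConfig()
    labels = gene_tree.leaf_labels
    if query_leaf not in labels:
        raise EcdysocompError(f"query leaf {query_leaf!r} absent from gene tree")
    if len(labels) < config.min_tree_leaves:
        return "insufficient"
    tree = _maybe_midpoint_root(gene_tree)
    node = tree.tree.find_node_with_taxon_label(query_leaf)
    category: str | None = None
    first = True
    while node.parent_node is not None:
        node = node.parent_node
        others = [lf.taxon.label for lf in node.leaf_iter()
                  if lf.taxon.label != query_leaf]
        if not others:
            continue
        groups = {taxon_groups.get(o, "metazoan") for o in others}
        if len(groups) == 1:
            category = groups.pop()
            first = False
            continue
        if first:
            n_met = sum(1 for o in others
                        if taxon_groups.get(o, "metazoan") == "metazoan")
            if n_met * 2 > len(others):
                return "complex_non_hgt"
            return "complex_hgt"
        break
    if category is None:  # query attached directly at the root of a mixed tree
        others = [l for l in labels if l != query_leaf]
        n_met = sum(1 for o in others if taxon_groups.get(o, "metazoan") == "metazoan")
        return "complex_non_hgt" if n_met * 2 > len(others) else "complex_hgt"
    return category


def assign_tier(tree_category: str, expressed: bool | None,
                conserved_in_sister: bool | None) -> str:
    """Nested confidence tiers; unknown (None) flags never reach ``high``."""
    if tree_category in REJECTED_CATEGORIES:
        return "rejected"
    if tree_category in HGT_CONFIRMED_CATEGORIES:
        if expressed is True and conserved_in_sister is True:
            return "high"
        return "supported"
    return "candidate_only"


@dataclass
class GeneTreeRecord:
    """Per-candidate gene tree plus leaf taxon tags, ready for classification."""

    tree: SpeciesTree
    taxon_groups: Mapping[str, str]
    query_leaf: str


def annotate_validation(scores: Sequence[HgtScore],
                        gene_trees: Mapping[str, GeneTreeRecord],
                        expression: ExpressionTable | None,
                        models: GeneModelTable | None,
                        clusters: ClusterTable | None,
                        sister_species_id: str | None,
                        config: ScreenConfig | None = None) -> list[HgtValidation]:
    """Run the validation cascade over all index candidates.

    Missing ancillary data is permitted: the corresponding flag is recorded
    as None (unknown) and the gene can then never reach the high tier.
    """
    config = config or ScreenConfig()
    protein_index = clusters.protein_index() if clusters is not None else None
    max_tpm = mean_tpm = None
    if expression is not None:
        max_tpm = expression.tpm.max(axis=1)
        mean_tpm = expression.tpm.mean(axis=1)
    validations = []
    for score in scores:
        if not score.is_candidate:
            continue
        gid = score.gene_id
        rec = gene_trees.get(gid)
        if rec is None:
            category = "insufficient"
        else:
            category = classify_tree_origin(rec.tree, rec.query_leaf,
                                            rec.taxon_groups, config)
        expressed: bool | None = None
        if expression is not None and gid in expression.tpm.index:
            level = (max_tpm[gid] if config.expression_rule == "any_library"
                     else mean_tpm[gid])
            expressed = bool(level > config.expression_tpm_cutoff)
        has_intron: bool | None = None
        if models is not None and gid in models.genes:
            has_intron = len(models.genes[gid].exons) > 1
        conserved: bool | None = None
        if protein_index is not None and sister_species_id is not None:
            fam = protein_index.get(gid)
            if fam is not None:
                conserved = sister_species_id in clusters.species_of_family(fam)
            else:
                conserved = False
        validations.append(HgtValidation(gene_id=gid, tree_category=category,
                                         expressed=expressed, has_intron=has_intron,
                                         conserved_in_sister=conserved))
    return validations


@dataclass
class TierCounts:
    """Nested tier set sizes and their percentages of the gene total."""

    n_high: int
    n_supported: int     # includes high
    n_candidate: int     # all index candidates, includes supported + rejected
    n_rejected: int
    total_genes: int
    pct_high: float = field(init=False)
    pct_supported: float = field(init=False)
    pct_candidate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.total_genes <= 0:
            raise ValueError("total gene count must be positive")
        self.pct_high = percentage(self.n_high, self.total_genes)
        self.pct_supported = percentage(self.n_supported, self.total_genes)
        self.pct_candidate = percentage(self.n_candidate, self.total_genes)


def tier_counts(validations: Sequence[HgtValidation], total_genes: int) -> TierCounts:
    n_high = sum(1 for v in validations if v.tier == "high")
    n_supported = n_high + sum(1 for v in validations if v.tier == "supported")
    n_rejected = sum(1 for v in validations if v.tier == "rejected")
    return TierCounts(n_high=n_high, n_supported=n_supported,
                      n_candidate=len(validations), n_rejected=n_rejected,
                      total_genes=total_genes)


# ---------------------------------------------------------------------------
# genomic clustering of HGT loci
# ---------------------------------------------------------------------------

@dataclass
class HgtCluster:
    scaffold_id: str
    members: list[str]          # gene ids in scaffold order
    span_in_genes: int          # rank of last member - rank of first + 1


def cluster_hgt_loci(models: GeneModelTable, hgt_gene_ids: Iterable[str],
                     config: ScreenConfig | None = None
                     ) -> tuple[list[HgtCluster], pd.DataFrame, list[str]]:
    """Cluster HGT genes along scaffolds and report neighbour distances.

    Two HGT genes join one cluster iff they lie on the same scaffold with at
    most ``cluster_max_gap`` intervening non-HGT genes; clusters have >= 2
    members. The returned frame gives, per HGT gene, the number of genes to
    the nearest HGT candidate on each side (sentinel -1000000 / +1000000 at
    scaffold ends). Ids absent from the models are returned as skipped.
    """
    config = config or ScreenConfig()
    hgt_ids = set(hgt_gene_ids)
    skipped = sorted(hgt_ids - set(models.genes))
    hgt_ids -= set(skipped)

    clusters: list[HgtCluster] = []
    rows = []
    for scaffold, genes in sorted(models.by_scaffold().items()):
        positions = [(g.rank_on_scaffold, g.gene_id) for g in genes
                     if g.gene_id in hgt_ids]
        current: list[tuple[int, str]] = []
        for rank, gid in positions:
            if current and rank - current[-1][0] - 1 <= config.cluster_max_gap:
                current.append((rank, gid))
            else:
                if len(current) >= 2:
                    clusters.append(HgtCluster(
                        scaffold_id=scaffold,
                        members=[g for _, g in current],
                        span_in_genes=current[-1][0] - current[0][0] + 1))
                current = [(rank, gid)]
        if len(current) >= 2:
            clusters.append(HgtCluster(scaffold_id=scaffold,
                                       members=[g for _, g in current],
                                       span_in_genes=current[-1][0] - current[0][0] + 1))
        for i, (rank, gid) in enumerate(positions):
            left = (rank - positions[i - 1][0] - 1) if i > 0 else -SCAFFOLD_END_SENTINEL
            right = (positions[i + 1][0] - rank - 1) if i < len(positions) - 1 \
                else SCAFFOLD_END_SENTINEL
            rows.append((gid, scaffold, rank, left, right))
    distances = pd.DataFrame(rows, columns=["gene_id", "scaffold_id",
                                            "rank_on_scaffold",
                                            "genes_to_prev_hgt",
                                            "genes_to_next_hgt"])
    distances = distances.sort_values("gene_id").reset_index(drop=True)
    return clusters, distances, skipped


@dataclass
class AnnotationComparison:
    proportion_ref: float
    proportion_abinitio: float
    ratio: float | None      # None when the reference proportion is 0


def compare_annotation_hgt_rates(scores_ref: Sequence[HgtScore],
                                 scores_abinitio: Sequence[HgtScore]
                                 ) -> AnnotationComparison:
    """Candidate proportions in two annotations of the same genome; the
    ratio ab-initio / reference measures the inflation an uncurated gene
    set produces."""
    if not scores_ref or not scores_abinitio:
        raise ValueError("both score lists must be non-empty")
    p_ref = sum(s.is_candidate for s in scores_ref) / len(scores_ref)
    p_ab = sum(s.is_candidate for s in scores_abinitio) / len(scores_abinitio)
    ratio = (p_ab / p_ref) if p_ref > 0 else None
    return AnnotationComparison(proportion_ref=p_ref, proportion_abinitio=p_ab,
                                ratio=ratio)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def screen_report(scores: Sequence[HgtScore],
                  validations: Sequence[HgtValidation] | None = None) -> pd.DataFrame:
    """Per-gene summary frame mirroring the columns of a per-candidate
    supplementary table: scores, hit pattern, and validation flags."""
    sdf = pd.DataFrame([{
        "gene_id": s.gene_id, "best_nonmetazoan_bitscore": s.bo,
        "best_metazoan_bitscore": s.bm, "hgt_index": s.hu,
        "hit_pattern": s.hit_pattern, "is_candidate": s.is_candidate,
        "best_nonmetazoan_subject": s.best_nonmetazoan_subject or "",
        "best_metazoan_subject": s.best_metazoan_subject or "",
    } for s in scores])
    if validations:
        vdf = pd.DataFrame([{
            "gene_id": v.gene_id, "tree_category": v.tree_category,
            "expressed": v.expressed, "has_intron": v.has_intron,
            "conserved_in_sister": v.conserved_in_sister, "tier": v.tier,
        } for v in validations])
        sdf = sdf.merge(vdf, on="gene_id", how="left")
    return sdf.sort_values("gene_id").reset_index(drop=True)
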