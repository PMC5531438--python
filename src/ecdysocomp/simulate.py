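"""Seeded generators emulating the data each analysis stage consumes.

Every generator returns both the dataset (in the package's standard
containers, valid under the :mod:`ecdysocomp.formats` writers/readers) and
a ground-truth record sufficient to compute the expected downstream result
without re-simulation — planted HGT genes, family birth nodes and lost
branches, planted DEGs with their effect sizes, rearrangement operations.

Randomness derives from a single integer seed. Each generator draws from
its own fixed stream (``default_rng([seed, offset])``), so adding or
re-ordering generator calls never perturbs another generator's output and
identical configurations reproduce identical data byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import EcdysocompError
from .formats import (ClusterTable, ExpressionTable, GeneModel, GeneModelTable,
                      HitTable, HIT_COLUMNS, SpeciesTree)
from .synteny import RbhPair

# fixed stream offsets per generator
_STREAM_FAMILIES = 1
_STREAM_HGT = 2
_STREAM_GENOMES = 3
_STREAM_EXPRESSION = 4
_STREAM_MIRNA = 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


# ---------------------------------------------------------------------------
# gene families on a tree
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    family_id: str
    birth_node: frozenset[str]       # leaf set below the planted birth
    lost_branches: list[frozenset[str]]  # leaf sets below branches where loss hit
    present_leaves: frozenset[str]


def simulate_gene_families(tree: SpeciesTree, n_families: int = 1000,
                           birth_node_distribution: Mapping[frozenset, float] | None = None,
                           loss_prob_per_branch: float = 0.1,
                           count_lambda: float = 0.5,
                           seed: int = 0
                           ) -> tuple[ClusterTable, list[FamilyTruth]]:
    """Families gained once at a sampled node and surviving each descendant
    branch with probability 1 - ``loss_prob_per_branch``.

    Surviving leaves receive 1 + Poisson(``count_lambda``) members.
    Families extinct in every leaf are discarded and resampled, so each
    truth record has at least one present leaf. ``birth_node_distribution``
    maps node leaf sets to sampling weights (default: uniform over all
    nodes, leaves included).
    """
    leaves = tree.leaf_labels
    if len(leaves) < 2:
        raise EcdysocompError("tree must have >= 2 leaves")
    if not 0 <= loss_prob_per_branch < 1:
        raise EcdysocompError("loss probability must be in [0, 1)")
    rng = _rng(seed, _STREAM_FAMILIES)
    nodes = list(tree.tree.preorder_node_iter())
    node_sets = [tree.leafset(n) for n in nodes]
    if birth_node_distribution is not None:
        weights = np.array([birth_node_distribution.get(s, 0.0) for s in node_sets])
        if weights.sum() <= 0:
            raise EcdysocompError("birth distribution assigns no mass to tree nodes")
    else:
        weights = np.ones(len(nodes))
    weights = weights / weights.sum()

    families: dict[str, dict[str, set[str]]] = {}
    truths: list[FamilyTruth] = []
    width = max(4, len(str(max(n_families, 1))))
    i = 0
    while len(truths) < n_families:
        birth_idx = rng.choice(len(nodes), p=weights)
        birth = nodes[birth_idx]
        present: set[str] = set()
        lost: list[frozenset[str]] = []

        def descend(node, alive: bool) -> None:
            nonlocal present
            if not alive:
                return
            if node.is_leaf():
                present.add(node.taxon.label)
                return
            for child in node.child_nodes():
                if rng.random() < loss_prob_per_branch:
                    lost.append(tree.leafset(child))
                else:
                    descend(child, True)

        descend(birth, True)
        if not present:
            continue  # extinct everywhere: resample
        fam = f"FAM{i:0{width}d}"
        i += 1
        per_sp = {}
        for sp in sorted(present):
            k = 1 + int(rng.poisson(count_lambda))
            per_sp[sp] = {f"{sp}|{fam}|p{j}" for j in range(k)}
        families[fam] = per_sp
        truths.append(FamilyTruth(family_id=fam, birth_node=node_sets[birth_idx],
                                  lost_branches=lost,
                                  present_leaves=frozenset(present)))
    table = ClusterTable(families=families, species_order=list(leaves))
    return table, truths


# ---------------------------------------------------------------------------
# HGT hit tables
# ---------------------------------------------------------------------------

@dataclass
class HgtTruth:
    hgt_gene_ids: frozenset[str]
    margins: dict[str, float]        # planted Bo - Bm per gene
    single_sided: frozenset[str]     # genes given only one hit partition


def _draw_margin(rng: np.random.Generator, spec: float | tuple[float, float],
                 n: int) -> np.ndarray:
    if isinstance(spec, tuple):
        loc, scale = spec
        return rng.normal(loc, scale, size=n)
    return np.full(n, float(spec))


def simulate_hgt_hits(n_genes: int = 5000, hgt_fraction: float = 0.02,
                      margin_hgt: float | tuple[float, float] = 60.0,
                      margin_native: float | tuple[float, float] = -60.0,
                      single_sided_fraction: float = 0.05,
                      seed: int = 0) -> tuple[HitTable, HgtTruth]:
    """Hit tables with planted score margins.

    A fixed fraction of genes are horizontal-transfer genes whose best
    non-metazoan bit score exceeds their best metazoan score by a margin
    drawn from ``margin_hgt`` (a constant, or (loc, scale) of a normal);
    native genes get ``margin_native`` the same way. A further fraction is
    single-sided: HGT genes lose their metazoan hit, native genes their
    non-metazoan hit. E-values are drawn log-uniform in [1e-50, 1e-6],
    always below the default screen cutoff.
    """
    if not 0 <= hgt_fraction <= 1:
        raise EcdysocompError("hgt_fraction must be in [0, 1]")
    rng = _rng(seed, _STREAM_HGT)
    n_hgt = int(round(n_genes * hgt_fraction))
    width = len(str(max(n_genes, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(n_genes)]
    is_hgt = np.zeros(n_genes, dtype=bool)
    is_hgt[:n_hgt] = True
    rng.shuffle(is_hgt)
    margins = np.where(is_hgt,
                       _draw_margin(rng, margin_hgt, n_genes),
                       _draw_margin(rng, margin_native, n_genes))
    base = rng.uniform(100.0, 300.0, size=n_genes)  # metazoan anchor score
    single = rng.random(n_genes) < single_sided_fraction

    rows = []
    single_ids = []
    for i, gid in enumerate(gene_ids):
        bm = base[i]
        bo = max(bm + margins[i], 25.0)
        ev_m, ev_o = 10.0 ** rng.uniform(-50, -6, size=2)
        if single[i]:
            single_ids.append(gid)
            if is_hgt[i]:
                rows.append((gid, f"nonmet_{gid}", 60.0, ev_o, bo,
                             "prokaryote", "donor_sp"))
            else:
                rows.append((gid, f"met_{gid}", 60.0, ev_m, bm,
                             "metazoan", "met_sp"))
        else:
            rows.append((gid, f"met_{gid}", 60.0, ev_m, bm, "metazoan", "met_sp"))
            rows.append((gid, f"nonmet_{gid}", 60.0, ev_o, bo,
                         "prokaryote", "donor_sp"))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    truth = HgtTruth(
        hgt_gene_ids=frozenset(g for g, h in zip(gene_ids, is_hgt) if h),
        margins={g: float(m) for g, m in zip(gene_ids, margins)},
        single_sided=frozenset(single_ids))
    return HitTable(df=df), truth


# ---------------------------------------------------------------------------
# genome pairs
# ---------------------------------------------------------------------------

@dataclass
class GenomePairTruth:
    inversions: list[tuple[str, int, int]]       # scaffold, start idx, end idx
    translocations: list[tuple[str, str, str]]   # gene, from scaffold, to scaffold
    intron_scale_ratio: float
    orthologues: dict[str, str]                  # gene A -> gene B


def _make_gene(gene_id: str, scaffold: str, start: int,
               exon_lengths: Sequence[int], intron_lengths: Sequence[int]
               ) -> tuple[GeneModel, int]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return GeneModel(gene_id=gene_id, scaffold_id=scaffold, strand="+",
                     exons=exons), exons[-1][1]


def simulate_genome_pair(n_scaffolds: int = 5, genes_per_scaffold: int = 30,
                         n_inversions: int = 0, n_translocations: int = 0,
                         intron_scale_ratio: float = 1.0, seed: int = 0
                         ) -> tuple[GeneModelTable, GeneModelTable,
                                    list[RbhPair], GenomePairTruth]:
    """A genome pair with conserved gene content and controlled rearrangement.

    Genome B starts as a copy of genome A's gene order; each inversion
    reverses a random contiguous run of genes within a B scaffold (breaking
    local order, preserving linkage) and each translocation moves one gene
    to a different scaffold (breaking linkage). Genome A intron lengths are
    genome B's scaled by ``intron_scale_ratio``. RBH pairs link every
    orthologue pair.
    """
    rng = _rng(seed, _STREAM_GENOMES)
    exon_counts = {}
    exon_lens = {}
    intron_lens_b = {}
    order_a: dict[str, list[str]] = {}
    for s in range(n_scaffolds):
        scaffold = f"scaffoldA{s:03d}"
        order_a[scaffold] = []
        for g in range(genes_per_scaffold):
            gid = f"ga_{s:03d}_{g:03d}"
            order_a[scaffold].append(gid)
            k = 1 + int(rng.integers(0, 5))
            exon_counts[gid] = k
            exon_lens[gid] = [int(rng.integers(80, 400)) for _ in range(k)]
            intron_lens_b[gid] = [int(rng.integers(40, 200)) for _ in range(k - 1)]

    # genome B order: copy then rearrange
    order_b = {f"scaffoldB{s:03d}": [g for g in order_a[f"scaffoldA{s:03d}"]]
               for s in range(n_scaffolds)}
    b_names = sorted(order_b)
    inversions = []
    for _ in range(n_inversions):
        sc = b_names[int(rng.integers(0, len(b_names)))]
        genes = order_b[sc]
        if len(genes) < 2:
            continue
        i = int(rng.integers(0, len(genes) - 1))
        j = int(rng.integers(i + 1, len(genes)))
        if j - i + 1 > len(genes):
            raise EcdysocompError("inversion span exceeds scaffold")
        genes[i:j + 1] = genes[i:j + 1][::-1]
        inversions.append((sc, i, j))
    translocations = []
    for _ in range(n_translocations):
        src = b_names[int(rng.integers(0, len(b_names)))]
        if not order_b[src]:
            continue
        dst = b_names[int(rng.integers(0, len(b_names)))]
        if dst == src:
            dst = b_names[(b_names.index(src) + 1) % len(b_names)]
        gid = order_b[src].pop(int(rng.integers(0, len(order_b[src]))))
        order_b[dst].insert(int(rng.integers(0, len(order_b[dst]) + 1)), gid)
        translocations.append((gid, src, dst))

    genes_a: dict[str, GeneModel] = {}
    genes_b: dict[str, GeneModel] = {}
    orthologues: dict[str, str] = {}
    for scaffold, order in order_a.items():
        pos = 1
        for gid in order:
            introns_a = [max(1, int(round(l * intron_scale_ratio)))
                         for l in intron_lens_b[gid]]
            gm, end = _make_gene(gid, scaffold, pos, exon_lens[gid], introns_a)
            genes_a[gid] = gm
            pos = end + 500
    for scaffold, order in order_b.items():
        pos = 1
        for gid in order:
            bid = gid.replace("ga_", "gb_")
            gm, end = _make_gene(bid, scaffold, pos, exon_lens[gid],
                                 intron_lens_b[gid])
            genes_b[bid] = gm
            orthologues[gid] = bid
            pos = end + 500
    pairs = [RbhPair(gene_a=a, gene_b=b, score_ab=500.0, score_ba=500.0)
             for a, b in sorted(orthologues.items())]
    truth = GenomePairTruth(inversions=inversions, translocations=translocations,
                            intron_scale_ratio=intron_scale_ratio,
                            orthologues=orthologues)
    return (GeneModelTable(genes=genes_a), GeneModelTable(genes=genes_b),
            pairs, truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTruth:
    deg_gene_ids: frozenset[str]
    planted_log2fc: dict[str, float]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative binomial parameterized by (mean, dispersion); dispersion is
    the inverse size parameter, so variance = mean + dispersion * mean**2
    and dispersion -> 0 recovers Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(n_genes: int = 2000, n_replicates: int = 3,
                        deg_fraction: float = 0.05, log2fc_effect: float = 3.0,
                        dispersion: float = 0.05,
                        baseline_log_mean: float = 4.0,
                        baseline_log_sd: float = 1.5,
                        seed: int = 0,
                        active_condition: str = "active",
                        tun_condition: str = "tun"
                        ) -> tuple[ExpressionTable, ExpressionTruth]:
    """Two-condition replicated counts with planted differential expression.

    Baseline means are log-normal; planted DEGs multiply the tun-condition
    mean by 2**``log2fc_effect``. Counts are negative binomial; TPM is the
    library-size normalization of counts with all gene lengths equal to 1,
    keeping the TPM/count distinction visible without re-implementing
    quantification. The FDR column is produced by a per-gene pooled
    two-sample t-test on log2(count+1) with Benjamini-Hochberg correction —
    a stand-in for an external differential-expression caller (pooling the
    variance adds the degrees of freedom such callers recover by sharing
    dispersion information across genes).
    """
    if n_replicates < 2:
        raise EcdysocompError("need >= 2 replicates per condition")
    rng = _rng(seed, _STREAM_EXPRESSION)
    width = len(str(max(n_genes, 1)))
    gene_ids = [f"e{i:0{width}d}" for i in range(n_genes)]
    base = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    n_deg = int(round(n_genes * deg_fraction))
    is_deg = np.zeros(n_genes, dtype=bool)
    is_deg[:n_deg] = True
    rng.shuffle(is_deg)
    mean_active = base
    mean_tun = base * np.where(is_deg, 2.0 ** log2fc_effect, 1.0)

    samples = ([f"{active_condition}_{r+1}" for r in range(n_replicates)]
               + [f"{tun_condition}_{r+1}" for r in range(n_replicates)])
    counts = np.empty((n_genes, 2 * n_replicates), dtype=np.int64)
    for r in range(n_replicates):
        counts[:, r] = _nb_draw(rng, mean_active, dispersion)
        counts[:, n_replicates + r] = _nb_draw(rng, mean_tun, dispersion)
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    lib = counts_df.sum(axis=0).astype(float).replace(0, 1.0)
    tpm = counts_df / lib * 1e6

    log_counts = np.log2(counts + 1.0)
    import warnings
    with warnings.catch_warnings():
        # genes with identical replicate counts trigger a harmless scipy
        # precision warning; their p-value becomes NaN and is set to 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, pvals = _sps.ttest_ind(log_counts[:, n_replicates:],
                                      log_counts[:, :n_replicates],
                                      axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    design = pd.DataFrame(
        {"condition": [active_condition] * n_replicates + [tun_condition] * n_replicates,
         "replicate": list(range(1, n_replicates + 1)) * 2},
        index=pd.Index(samples, name="sample"))
    table = ExpressionTable(tpm=tpm, design=design, counts=counts_df,
                            fdr=pd.Series(fdr, index=gene_ids, name="fdr"))
    truth = ExpressionTruth(
        deg_gene_ids=frozenset(g for g, d in zip(gene_ids, is_deg) if d),
        planted_log2fc={g: (log2fc_effect if d else 0.0)
                        for g, d in zip(gene_ids, is_deg)})
    return table, truth


# ---------------------------------------------------------------------------
# miRNA hits
# ---------------------------------------------------------------------------

@dataclass
class MirnaTruth:
    records: pd.DataFrame  # query, reference, identity, mutated_position,
                           # expected_pass, expected_windows


_BASES = np.array(list("ACGU"))


def simulate_mirna_hits(n: int = 100, mature_length: int = 22,
                        mutation_positions: Sequence[int] | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, MirnaTruth]:
    """Mature-miRNA hit records with one planted mismatch each.

    Each record is a random mature sequence and a reference differing at a
    single known position (sampled uniformly over 1..length unless
    ``mutation_positions`` pins them). Identity is the exact ungapped
    identity. The truth lists, per record, which seed windows survive and
    whether the default filter should pass it.
    """
    from .expression import SeedMatchRule, mirna_seed_filter
    if mature_length < 9:
        raise EcdysocompError("mature length must be >= 9")
    rng = _rng(seed, _STREAM_MIRNA)
    rule = SeedMatchRule()
    rows = []
    for i in range(n):
        seq = "".join(rng.choice(_BASES, size=mature_length))
        if mutation_positions is not None:
            pos = int(mutation_positions[i % len(mutation_positions)])
        else:
            pos = int(rng.integers(1, mature_length + 1))
        old = seq[pos - 1]
        new = str(rng.choice([b for b in "ACGU" if b != old]))
        ref = seq[: pos - 1] + new + seq[pos:]
        identity = 100.0 * (mature_length - 1) / mature_length
        surviving = [w for w in rule.seed_windows if not (w[0] <= pos <= w[1])]
        expected_pass = identity > rule.identity_cutoff and bool(surviving)
        rows.append({"hit_id": f"mir{i:04d}", "query": seq, "reference": ref,
                     "percent_identity": identity, "mutated_position": pos,
                     "expected_pass": expected_pass,
                     "expected_windows": ";".join(f"{a}-{b}" for a, b in surviving)})
    df = pd.DataFrame(rows)
    return df, MirnaTruth(records=df.copy())
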