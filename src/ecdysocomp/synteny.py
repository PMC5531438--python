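"""Reciprocal-best-hit orthology, neighbourhood conservation, and
orthologue gene-structure comparison.

Two related genomes can conserve *linkage* (orthologues of genes sharing a
scaffold still share a scaffold in the partner) while losing *synteny*
(local gene order), the pattern produced by within-chromosome
rearrangement. The neighbourhood statistic here captures that: for each
sufficiently gene-rich scaffold of genome A, the maximal fraction of its
RBH orthologues mapping to a single genome-B scaffold.

Gene-structure statistics follow the fixed coordinate conventions of
:mod:`ecdysocomp.formats`: gene length is the genomic span from the first
CDS base to the last (start codon to stop codon), exon span is the summed
CDS exon length, and intron span is their difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import EcdysocompError
from .formats import GeneModelTable, HitTable


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    score_ab: float
    score_ba: float


def _best_hits(hits: HitTable) -> dict[str, tuple[str, float]]:
    """query -> (best subject, bitscore); ties keep the lowest subject id."""
    best: dict[str, tuple[str, float]] = {}
    df = hits.df.sort_values(["query_id", "subject_id"], kind="mergesort")
    for r in df.itertuples(index=False):
        cur = best.get(r.query_id)
        if cur is None or r.bitscore > cur[1]:
            best[r.query_id] = (r.subject_id, r.bitscore)
    return best


def reciprocal_best_hits(hits_ab: HitTable, hits_ba: HitTable) -> list[RbhPair]:
    """Mutual best-hit pairs between two genomes, ordered by gene_a."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, (b, s_ab) in best_ab.items():
        back = best_ba.get(b)
        if back is not None and back[0] == a:
            pairs.append(RbhPair(gene_a=a, gene_b=b, score_ab=s_ab, score_ba=back[1]))
    return sorted(pairs, key=lambda p: p.gene_a)


# ---------------------------------------------------------------------------
# neighbourhood conservation
# ---------------------------------------------------------------------------

def neighborhood_conservation(models_a: GeneModelTable, models_b: GeneModelTable,
                              pairs: Sequence[RbhPair], min_genes: int = 10
                              ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-scaffold maximal fraction of orthologues on one partner scaffold.

    Scaffolds of genome A with strictly more than ``min_genes`` genes are
    assessed; the fraction's denominator is the number of genes with an RBH
    partner. Scaffolds above the size threshold but with zero orthologued
    genes are excluded (reported in the frame with NaN fraction). Returns
    (per-scaffold frame, histogram of fractions in bins of width 0.1).
    """
    partner = {p.gene_a: p.gene_b for p in pairs}
    b_scaffold = {gid: g.scaffold_id for gid, g in models_b.genes.items()}
    rows = []
    for scaffold, genes in sorted(models_a.by_scaffold().items()):
        if len(genes) <= min_genes:
            continue
        mapped = []
        for g in genes:
            b_gene = partner.get(g.gene_id)
            if b_gene is not None and b_gene in b_scaffold:
                mapped.append(b_scaffold[b_gene])
        if not mapped:
            rows.append({"scaffold_id": scaffold, "n_genes": len(genes),
                         "n_orthologued": 0, "max_fraction": float("nan"),
                         "best_partner_scaffold": ""})
            continue
        counts = pd.Series(mapped).value_counts()
        rows.append({"scaffold_id": scaffold, "n_genes": len(genes),
                     "n_orthologued": len(mapped),
                     "max_fraction": counts.iloc[0] / len(mapped),
                     "best_partner_scaffold": counts.index[0]})
    df = pd.DataFrame(rows)
    fractions = df["max_fraction"].dropna() if len(df) else pd.Series(dtype=float)
    edges = np.round(np.arange(0, 1.1, 0.1), 1)
    labels = [f"({edges[i]:.1f},{edges[i+1]:.1f}]" for i in range(10)]
    hist = pd.Series(0, index=labels, name="n_scaffolds")
    for f in fractions:
        idx = min(int(np.ceil(f * 10)) - 1, 9) if f > 0 else 0
        hist.iloc[idx] += 1
    return df, hist


# ---------------------------------------------------------------------------
# gene structure
# ---------------------------------------------------------------------------

@dataclass
class GeneStructureStats:
    gene_id: str
    gene_length: int   # first CDS base to last CDS base, genomic span
    exon_span: int     # summed exon lengths (the CDS length)
    exon_count: int
    intron_span: int   # gene_length - exon_span
    intron_count: int  # exon_count - 1

    def __post_init__(self) -> None:
        if self.gene_length < self.exon_span:
            raise EcdysocompError(
                f"gene {self.gene_id}: gene_length < exon_span")
        if self.intron_span < 0:
            raise EcdysocompError(f"gene {self.gene_id}: negative intron span")


def gene_structure_stats(models: GeneModelTable) -> dict[str, GeneStructureStats]:
    out = {}
    for gid, g in models.genes.items():
        gene_length = g.end - g.start + 1
        exon_span = sum(e - s + 1 for s, e in g.exons)
        out[gid] = GeneStructureStats(
            gene_id=gid, gene_length=gene_length, exon_span=exon_span,
            exon_count=len(g.exons), intron_span=gene_length - exon_span,
            intron_count=len(g.exons) - 1)
    return out


def orthologue_structure_compare(pairs: Sequence[RbhPair],
                                 stats_a: dict[str, GeneStructureStats],
                                 stats_b: dict[str, GeneStructureStats],
                                 outlier_delta: float = 0.20) -> pd.DataFrame:
    """Per-pair intron-span log2 ratio and CDS-length outlier class.

    A pair is a ``long`` outlier when the genome-A CDS is strictly more than
    (1 + delta) times the genome-B CDS, ``short`` when strictly less than
    (1 - delta) times. The log2 intron ratio uses a 1 bp pseudo-count on
    both sides so intronless orthologues stay finite.
    """
    hi, lo = 1.0 + outlier_delta, 1.0 - outlier_delta
    rows = []
    for p in pairs:
        sa = stats_a.get(p.gene_a)
        sb = stats_b.get(p.gene_b)
        if sa is None or sb is None:
            continue
        cds_ratio = sa.exon_span / sb.exon_span if sb.exon_span else float("inf")
        if cds_ratio > hi:
            outlier = "long"
        elif cds_ratio < lo:
            outlier = "short"
        else:
            outlier = "none"
        log2_intron = float(np.log2((sa.intron_span + 1) / (sb.intron_span + 1)))
        rows.append({"gene_a": p.gene_a, "gene_b": p.gene_b,
                     "exon_span_a": sa.exon_span, "exon_span_b": sb.exon_span,
                     "intron_span_a": sa.intron_span, "intron_span_b": sb.intron_span,
                     "cds_ratio": cds_ratio, "log2_intron_ratio": log2_intron,
                     "outlier": outlier})
    return pd.DataFrame(rows)


_METRICS = ["gene_length", "exon_span", "exon_count", "intron_span", "intron_count"]


def summary_ratio_table(stats_a: dict[str, GeneStructureStats],
                        stats_b: dict[str, GeneStructureStats],
                        pairs: Sequence[RbhPair],
                        exclude_outliers: bool = False,
                        outlier_delta: float = 0.20) -> pd.DataFrame:
    """Mean/median per structure metric for each genome over the orthologue
    pairs, with ratios of means and medians rounded half-up to 2 decimals.

    With ``exclude_outliers`` the CDS-length outlier pairs are dropped
    first, removing likely misannotated gene models from the comparison.
    """
    usable = [(stats_a[p.gene_a], stats_b[p.gene_b]) for p in pairs
              if p.gene_a in stats_a and p.gene_b in stats_b]
    if exclude_outliers:
        hi, lo = 1.0 + outlier_delta, 1.0 - outlier_delta
        kept = []
        for sa, sb in usable:
            r = sa.exon_span / sb.exon_span if sb.exon_span else float("inf")
            if lo <= r <= hi:
                kept.append((sa, sb))
        usable = kept
    if not usable:
        raise EcdysocompError("no orthologue pairs to summarize")
    rows = []
    for metric in _METRICS:
        va = np.array([getattr(sa, metric) for sa, _ in usable], dtype=float)
        vb = np.array([getattr(sb, metric) for _, sb in usable], dtype=float)
        mean_a, mean_b = va.mean(), vb.mean()
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        rows.append({
            "metric": metric,
            "mean_a": mean_a, "median_a": med_a,
            "mean_b": mean_b, "median_b": med_b,
            "ratio_of_means": round_half_up(mean_a / mean_b, 2) if mean_b else float("inf"),
            "ratio_of_medians": round_half_up(med_a / med_b, 2) if med_b else float("inf"),
        })
    return pd.DataFrame(rows).set_index("metric")


def estimate_collapsed_copies(local_coverage: float, global_coverage: float) -> int:
    """Copy number of a collapsed repeat locus: local / global read depth,
    rounded to the nearest integer."""
    if local_coverage <= 0 or global_coverage <= 0:
        raise EcdysocompError("coverages must be positive")
    return int(round(local_coverage / global_coverage))
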