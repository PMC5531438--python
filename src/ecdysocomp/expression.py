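"""Anhydrobiosis expression statistics and the miRNA seed-match filter.

The central quantity is the desiccation fold change of a gene,

    FC = mean TPM in the anhydrobiotic (tun) condition
         / (mean TPM in the active condition + 0.1),

where the 0.1 pseudo-count keeps silent-in-active genes finite. A gene is
called differentially expressed (DEG) when the external caller's FDR is
below the cutoff, expression clears a TPM gate, and FC exceeds the fold
cutoff in either direction. The TPM gate wording "average expression level
of over 1" is ambiguous between the per-condition and overall mean; both
readings are implemented behind ``tpm_rule`` (default ``either_condition``
so that silent-to-induced genes — e.g. a catalase rising from 0 to 27.5
TPM — remain callable).

The seed-match filter annotates predicted mature miRNAs against a
reference set, keeping alignments with identity above a cutoff and at
least one perfectly matched seed window (query bases 1-7, 2-8 or 3-9 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import rank_sum_test, EXACT_LIMIT
from ._util import percentage, round_half_up
from .errors import EcdysocompError
from .formats import ClusterTable, ExpressionTable

FC_PSEUDOCOUNT = 0.1


@dataclass
class DEGCall:
    gene_id: str
    mean_tpm_active: float
    mean_tpm_tun: float
    fold_change: float    # mean_tun / (mean_active + pseudo)
    fdr: float            # NaN when the external caller did not test the gene
    is_deg: bool
    direction: str        # up | down


def compute_fold_changes(expr: ExpressionTable, active_condition: str,
                         tun_condition: str, pseudo: float = FC_PSEUDOCOUNT
                         ) -> tuple[pd.Series, dict[str, float]]:
    """Per-gene fold change and a (mean, median, sd) summary over all genes.

    Condition means are arithmetic means over replicates; SD is the sample
    standard deviation (n-1 denominator).
    """
    mean_active = expr.condition_means(active_condition)
    mean_tun = expr.condition_means(tun_condition)
    fc = mean_tun / (mean_active + pseudo)
    fc.name = "fold_change"
    summary = {"mean": float(fc.mean()), "median": float(fc.median()),
               "sd": float(fc.std(ddof=1)) if len(fc) > 1 else float("nan")}
    return fc, summary


def call_degs(expr: ExpressionTable, active_condition: str, tun_condition: str,
              fdr_cutoff: float = 0.05, tpm_cutoff: float = 1.0,
              fc_cutoff: float = 2.0, tpm_rule: str = "either_condition",
              pseudo: float = FC_PSEUDOCOUNT
              ) -> tuple[list[DEGCall], dict[str, float]]:
    """Threshold-filter DEG calling.

    A gene is a DEG iff FDR < ``fdr_cutoff``, the TPM gate passes
    (``either_condition``: max of the two condition means > ``tpm_cutoff``;
    ``overall_mean``: mean over all samples > cutoff), and fold change is
    > ``fc_cutoff`` or < 1/``fc_cutoff``. Genes without an FDR value are
    never DEGs. Returns the calls plus a summary with up/down counts and
    the DEG percentage of the gene total (1 decimal).
    """
    if tpm_rule not in ("either_condition", "overall_mean"):
        raise EcdysocompError(f"unknown tpm_rule {tpm_rule!r}")
    mean_active = expr.condition_means(active_condition)
    mean_tun = expr.condition_means(tun_condition)
    fc = mean_tun / (mean_active + pseudo)
    fdr = expr.fdr if expr.fdr is not None else pd.Series(np.nan, index=expr.tpm.index)
    if tpm_rule == "either_condition":
        tpm_gate = np.maximum(mean_active, mean_tun) > tpm_cutoff
    else:
        tpm_gate = expr.tpm.mean(axis=1) > tpm_cutoff
    fdr_gate = fdr < fdr_cutoff  # NaN compares False: untested genes never DEG
    fc_gate = (fc > fc_cutoff) | (fc < 1.0 / fc_cutoff)
    is_deg = fdr_gate & tpm_gate & fc_gate
    calls = [DEGCall(gene_id=g,
                     mean_tpm_active=float(mean_active[g]),
                     mean_tpm_tun=float(mean_tun[g]),
                     fold_change=float(fc[g]),
                     fdr=float(fdr[g]) if pd.notna(fdr[g]) else float("nan"),
                     is_deg=bool(is_deg[g]),
                     direction="up" if fc[g] > 1 else "down")
             for g in expr.tpm.index]
    n_total = len(calls)
    n_deg = int(is_deg.sum())
    n_up = sum(1 for c in calls if c.is_deg and c.direction == "up")
    summary = {"n_genes": n_total, "n_deg": n_deg, "n_up": n_up,
               "n_down": n_deg - n_up,
               "pct_deg": percentage(n_deg, n_total)}
    return calls, summary


def compare_fc_distributions(fc_a: Sequence[float], fc_b: Sequence[float],
                             exact_limit: int = EXACT_LIMIT) -> dict[str, float]:
    """Two-sided rank-sum comparison of two fold-change distributions.

    Symmetric in its arguments up to U -> n_a*n_b - U. Summaries are
    reported to 2 decimals (sample SD).
    """
    a = np.asarray(list(fc_a), dtype=float)
    b = np.asarray(list(fc_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EcdysocompError("fold-change lists must be non-empty")
    u, p = rank_sum_test(a, b, exact_limit=exact_limit)
    out = {"u_statistic": u, "p_value": p}
    for name, v in (("a", a), ("b", b)):
        out[f"mean_{name}"] = round_half_up(float(v.mean()), 2)
        out[f"median_{name}"] = round_half_up(float(np.median(v)), 2)
        out[f"sd_{name}"] = round_half_up(float(v.std(ddof=1)), 2) if len(v) > 1 \
            else float("nan")
    return out


@dataclass
class DeOverlap:
    n_genes_a_in_shared_families: int
    n_shared_families: int
    n_genes_b_in_shared_families: int
    shared_families: list[str]
    families_de_in_a_only: list[str]
    #: families DE in A whose species-B members include a highly expressed gene
    a_only_with_high_b_expression: list[str]


def cross_species_de_overlap(degs_a: Iterable[str], degs_b: Iterable[str],
                             clusters: ClusterTable,
                             species_a: str, species_b: str,
                             expr_b: ExpressionTable | None = None,
                             b_condition: str | None = None,
                             high_tpm_cutoff: float = 100.0) -> DeOverlap:
    """Overlap of DEG sets through shared protein families.

    A shared family contains at least one DEG from each species. Gene ids
    in ``degs_a``/``degs_b`` are matched to cluster members of the
    respective species. With genome-B expression provided, families DE in A
    only are additionally screened for B members highly expressed
    (mean TPM > ``high_tpm_cutoff``) in ``b_condition`` — constitutive
    expression where species A relies on induction.
    """
    degs_a, degs_b = set(degs_a), set(degs_b)
    fams_a: dict[str, set[str]] = {}
    fams_b: dict[str, set[str]] = {}
    for fam, per_sp in clusters.families.items():
        hit_a = per_sp.get(species_a, set()) & degs_a
        hit_b = per_sp.get(species_b, set()) & degs_b
        if hit_a:
            fams_a[fam] = hit_a
        if hit_b:
            fams_b[fam] = hit_b
    shared = sorted(set(fams_a) & set(fams_b))
    a_only = sorted(set(fams_a) - set(fams_b))
    high_b: list[str] = []
    if expr_b is not None and b_condition is not None:
        means = expr_b.condition_means(b_condition)
        for fam in a_only:
            members_b = clusters.families[fam].get(species_b, set())
            if any(g in means.index and means[g] > high_tpm_cutoff
                   for g in members_b):
                high_b.append(fam)
    return DeOverlap(
        n_genes_a_in_shared_families=sum(len(fams_a[f]) for f in shared),
        n_shared_families=len(shared),
        n_genes_b_in_shared_families=sum(len(fams_b[f]) for f in shared),
        shared_families=shared,
        families_de_in_a_only=a_only,
        a_only_with_high_b_expression=high_b)


def classify_expression_level(expr: ExpressionTable, condition: str,
                              high_cutoff: float = 100.0,
                              low_cutoff: float = 1.0) -> pd.Series:
    """Per-gene class from the condition mean TPM: ``high`` (> high_cutoff),
    ``silent`` (< low_cutoff), else ``expressed``. Boundaries are strict."""
    means = expr.condition_means(condition)
    out = pd.Series("expressed", index=means.index, name="expression_class")
    out[means > high_cutoff] = "high"
    out[means < low_cutoff] = "silent"
    return out


# ---------------------------------------------------------------------------
# miRNA seed-match filter
# ---------------------------------------------------------------------------

@dataclass
class SeedMatchRule:
    """Annotation-filter thresholds for mature-miRNA hits."""

    identity_cutoff: float = 70.0                      # percent, strict >
    seed_windows: tuple[tuple[int, int], ...] = ((1, 7), (2, 8), (3, 9))

    def __post_init__(self) -> None:
        for start, end in self.seed_windows:
            if start < 1 or end < start:
                raise EcdysocompError(f"bad seed window ({start},{end})")


@dataclass
class SeedMatchResult:
    passed: bool
    identity_ok: bool
    matched_windows: list[tuple[int, int]]


def mirna_seed_filter(query_mature: str, reference: str,
                      percent_identity: float,
                      rule: SeedMatchRule | None = None,
                      alignment: tuple[str, str] | None = None) -> SeedMatchResult:
    """Pass iff identity exceeds the cutoff AND at least one seed window is
    mismatch- and gap-free.

    ``alignment`` is a pair of equal-length aligned strings (query,
    reference) with ``-`` gaps; for ungapped equal-length sequences it is
    computed trivially. Windows are 1-based inclusive positions on the
    query.
    """
    rule = rule or SeedMatchRule()
    if alignment is None:
        if len(query_mature) != len(reference):
            raise EcdysocompError(
                "unequal-length sequences need an explicit alignment")
        alignment = (query_mature, reference)
    aln_q, aln_r = alignment
    if len(aln_q) != len(aln_r):
        raise EcdysocompError("aligned strings differ in length")
    max_end = max(end for _, end in rule.seed_windows)
    if max_end > len(query_mature):
        raise EcdysocompError(
            f"seed window end {max_end} exceeds mature length {len(query_mature)}")
    # map query positions (1-based) to alignment columns
    col_of: dict[int, int] = {}
    qpos = 0
    for col, ch in enumerate(aln_q):
        if ch != "-":
            qpos += 1
            col_of[qpos] = col
    matched = []
    for start, end in rule.seed_windows:
        ok = True
        for pos in range(start, end + 1):
            col = col_of.get(pos)
            if col is None:
                ok = False
                break
            q, r = aln_q[col].upper(), aln_r[col].upper()
            if q == "-" or r == "-" or q != r:
                ok = False
                break
        # gaps *inside* the window on the reference side break the match:
        # require consecutive alignment columns too
        if ok and end > start:
            cols = [col_of[p] for p in range(start, end + 1)]
            if any(c2 - c1 != 1 for c1, c2 in zip(cols, cols[1:])):
                ok = False
        if ok:
            matched.append((start, end))
    identity_ok = percent_identity > rule.identity_cutoff
    return SeedMatchResult(passed=identity_ok and bool(matched),
                           identity_ok=identity_ok, matched_windows=matched)
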