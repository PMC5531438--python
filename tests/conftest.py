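"""Shared fixtures: small trees, tables and files built programmatically."""

from __future__ import annotations

import pandas as pd
import pytest

from ecdysocomp.formats import (ClusterTable, ExpressionTable, GeneModel,
                                GeneModelTable, HitTable, SpeciesTree,
                                HIT_COLUMNS)

# two hypothesis trees sharing a leaf set: tardigrades sister to nematodes
# (tree "TN") versus sister to arthropods (tree "TA"); the Nematoda and
# Arthropoda subtrees are identical in both.
NEWICK_TN = ("(((((T1,T2)Tardigrada,(N1,(N2,N3))Nematoda)TarNem,"
             "(A1,(A2,(A3,A4)))Arthropoda)Ecdysozoa,P1)Inner,OUT)Root;")
NEWICK_TA = ("(((((T1,T2)Tardigrada,(A1,(A2,(A3,A4)))Arthropoda)Panarthropoda,"
             "(N1,(N2,N3))Nematoda)Ecdysozoa,P1)Inner,OUT)Root;")

SPECIES = ["T1", "T2", "N1", "N2", "N3", "A1", "A2", "A3", "A4", "P1", "OUT"]


@pytest.fixture
def tree_tn() -> SpeciesTree:
    return SpeciesTree.from_newick(NEWICK_TN)


@pytest.fixture
def tree_ta() -> SpeciesTree:
    return SpeciesTree.from_newick(NEWICK_TA)


@pytest.fixture
def eight_leaf_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("(((a,b),(c,d)),((e,f),(g,h)));")


def make_hit_table(rows) -> HitTable:
    """rows of (query, subject, evalue, bitscore, group, species)."""
    df = pd.DataFrame(
        [(q, s, 50.0, e, b, g, sp) for q, s, e, b, g, sp in rows],
        columns=HIT_COLUMNS)
    return HitTable(df=df)


def make_clusters(fams: dict[str, dict[str, set[str]]],
                  species_order: list[str]) -> ClusterTable:
    return ClusterTable(families=fams, species_order=species_order)


def make_expression(tpm: dict[str, list[float]], samples: list[str],
                    conditions: list[str],
                    fdr: dict[str, float] | None = None) -> ExpressionTable:
    tpm_df = pd.DataFrame.from_dict(tpm, orient="index", columns=samples)
    design = pd.DataFrame({"condition": conditions,
                           "replicate": list(range(1, len(samples) + 1))},
                          index=pd.Index(samples, name="sample"))
    fdr_s = pd.Series(fdr, name="fdr") if fdr is not None else None
    return ExpressionTable(tpm=tpm_df, design=design, fdr=fdr_s)


def make_models(genes) -> GeneModelTable:
    """genes: iterable of (gene_id, scaffold, exons)."""
    return GeneModelTable(genes={
        gid: GeneModel(gene_id=gid, scaffold_id=sc, strand="+", exons=list(exons))
        for gid, sc, exons in genes})
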