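"""Readers, writers and in-memory containers for the pipeline's file formats.

Formats in scope
----------------
* orthogroup cluster tables (OrthoFinder ``Orthogroups.tsv`` dialect),
* homology hit tables (BLAST/DIAMOND tabular ``outfmt 6``) joined to a
  subject -> taxon-group map,
* rooted species and gene trees (Newick, via dendropy),
* gene models (GFF3, 1-based inclusive coordinates),
* expression matrices (gene x sample TPM and optional fragment counts)
  with a sample -> condition design and per-gene FDR from an external
  differential-expression caller.

Conventions shared by every downstream module:

* genomic coordinates are 1-based inclusive, so a single-exon gene on
  (10, 19) has gene length 10;
* the longest-CDS transcript represents each gene;
* exons are stored in ascending genomic order regardless of strand;
* TSV outputs are tab-delimited UTF-8 with a single ``#``-commented header
  line and rows sorted by primary key.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

TAXON_GROUPS = ("metazoan", "prokaryote", "virus", "nonmetazoan_eukaryote")
NONMETAZOAN_GROUPS = ("prokaryote", "virus", "nonmetazoan_eukaryote")

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "evalue",
    "bitscore",
    "subject_taxon_group",
    "subject_species_id",
]

_OUTFMT6_FIELDS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# ClusterTable
# ---------------------------------------------------------------------------

@dataclass
class ClusterTable:
    """Orthogroup membership: family_id -> species_id -> set of protein ids.

    Every protein appears in exactly one family; ``species_order`` fixes
    the column order used for matrices and written files.
    """

    families: dict[str, dict[str, set[str]]]
    species_order: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        known = set(self.species_order)
        for fam, per_sp in self.families.items():
            size = sum(len(v) for v in per_sp.values())
            if size < 1:
                raise IntegrityError(f"family {fam} is empty")
            for sp, prots in per_sp.items():
                if sp not in known:
                    raise IntegrityError(
                        f"species {sp} of family {fam} missing from species_order")
                for p in prots:
                    if p in seen:
                        raise IntegrityError(
                            f"protein {p} listed in two families: {seen[p]} and {fam}")
                    seen[p] = fam

    @property
    def n_families(self) -> int:
        return len(self.families)

    def counts(self, family_id: str) -> dict[str, int]:
        """Per-species member count for one family (0 for absent species)."""
        per_sp = self.families[family_id]
        return {sp: len(per_sp.get(sp, ())) for sp in self.species_order}

    def family_of(self, protein_id: str) -> str | None:
        for fam, per_sp in self.families.items():
            for prots in per_sp.values():
                if protein_id in prots:
                    return fam
        return None

    def protein_index(self) -> dict[str, str]:
        """protein_id -> family_id over the whole table."""
        idx: dict[str, str] = {}
        for fam, per_sp in self.families.items():
            for prots in per_sp.values():
                for p in prots:
                    idx[p] = fam
        return idx

    def species_of_family(self, family_id: str) -> set[str]:
        return {sp for sp, prots in self.families[family_id].items() if prots}


def read_cluster_table(path: str | Path) -> ClusterTable:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    Header row = species names; each data row = family_id followed by
    per-species comma-separated protein lists (possibly empty cells).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError("empty cluster table", str(path), 1)
        cols = header.rstrip("\n").split("\t")
        species = [c for c in cols[1:] if c]
        if not species:
            raise FormatError("cluster table header has no species columns", str(path), 1)
        families: dict[str, dict[str, set[str]]] = {}
        seen_protein: dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            fam = cells[0]
            if fam in families:
                raise FormatError(f"duplicate family_id {fam}", str(path), lineno)
            if len(cells) - 1 > len(species):
                raise FormatError(
                    f"row has {len(cells) - 1} species cells, header has {len(species)}",
                    str(path), lineno)
            per_sp: dict[str, set[str]] = {}
            for sp, cell in zip(species, cells[1:]):
                prots = {p.strip() for p in cell.split(",") if p.strip()}
                if prots:
                    per_sp[sp] = prots
                    for p in prots:
                        if p in seen_protein:
                            raise IntegrityError(
                                f"protein {p} listed in two families: "
                                f"{seen_protein[p]} and {fam}", str(path), lineno)
                        seen_protein[p] = fam
            if not per_sp:
                raise FormatError(f"family {fam} has no members", str(path), lineno)
            families[fam] = per_sp
    return ClusterTable(families=families, species_order=species)


def write_cluster_table(table: ClusterTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species_order) + "\n")
        for fam in sorted(table.families):
            per_sp = table.families[fam]
            cells = [", ".join(sorted(per_sp.get(sp, ()))) for sp in table.species_order]
            fh.write(fam + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# HitTable
# ---------------------------------------------------------------------------

@dataclass
class HitTable:
    """Ranked homology hits joined to subject taxon groups.

    ``df`` holds one row per hit with columns :data:`HIT_COLUMNS`;
    ``n_unmapped`` counts outfmt-6 rows dropped because their subject was
    absent from the taxon map.
    """

    df: pd.DataFrame
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in HIT_COLUMNS if c not in self.df.columns]
        if missing:
            raise IntegrityError(f"HitTable missing columns: {missing}")
        if len(self.df):
            if (self.df["bitscore"] <= 0).any():
                raise IntegrityError("bitscore must be > 0")
            if (self.df["evalue"] < 0).any():
                raise IntegrityError("evalue must be >= 0")
            bad = set(self.df["subject_taxon_group"].unique()) - set(TAXON_GROUPS)
            if bad:
                raise IntegrityError(f"unknown taxon groups: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)


def read_taxon_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV of subject_id_or_prefix -> (taxon_group, species_id)."""
    path = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 3:
                raise FormatError("taxon map rows need 3 columns "
                                  "(subject, taxon_group, species)", str(path), lineno)
            key, group, species = cells[0], cells[1], cells[2]
            if group not in TAXON_GROUPS:
                raise FormatError(f"unknown taxon group {group!r}", str(path), lineno)
            mapping[key] = (group, species)
    return mapping


def _lookup_taxon(subject: str, taxon_map: Mapping[str, tuple[str, str]]):
    """Exact subject match first, then longest-prefix match."""
    if subject in taxon_map:
        return taxon_map[subject]
    best = None
    best_len = -1
    for key, val in taxon_map.items():
        if subject.startswith(key) and len(key) > best_len:
            best, best_len = val, len(key)
    return best


def read_hit_table(path: str | Path, taxon_map_path: str | Path) -> HitTable:
    """Read BLAST tabular outfmt 6 and join subjects to taxon groups.

    Unmapped subjects are dropped and counted in ``n_unmapped``, never
    silently ignored.
    """
    path = Path(path)
    taxon_map = read_taxon_map(taxon_map_path)
    rows = []
    n_unmapped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 12:
                raise FormatError(
                    f"expected >=12 outfmt-6 columns, got {len(cells)}", str(path), lineno)
            try:
                pident = float(cells[2])
                evalue = float(cells[10])
                bitscore = float(cells[11])
            except ValueError as exc:
                raise FormatError(f"malformed numeric field: {exc}", str(path), lineno)
            if bitscore <= 0:
                raise FormatError(f"non-positive bitscore {bitscore}", str(path), lineno)
            if evalue < 0:
                raise FormatError(f"negative evalue {evalue}", str(path), lineno)
            hit = _lookup_taxon(cells[1], taxon_map)
            if hit is None:
                n_unmapped += 1
                continue
            group, species = hit
            rows.append((cells[0], cells[1], pident, evalue, bitscore, group, species))
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return HitTable(df=df, n_unmapped=n_unmapped)


def write_hit_table(table: HitTable, path: str | Path,
                    taxon_map_path: str | Path | None = None) -> None:
    """Write outfmt-6 rows (dummy alignment coordinates) and, optionally,
    the matching taxon map, so simulated tables round-trip through
    :func:`read_hit_table`."""
    path = Path(path)
    df = table.df.sort_values(["query_id", "subject_id"], kind="mergesort")
    with open(path, "w", encoding="utf-8") as fh:
        for r in df.itertuples(index=False):
            fh.write("\t".join([
                r.query_id, r.subject_id, f"{r.percent_identity:g}", "100", "0", "0",
                "1", "100", "1", "100", f"{r.evalue:g}", f"{r.bitscore:g}",
            ]) + "\n")
    if taxon_map_path is not None:
        pairs = (df[["subject_id", "subject_taxon_group", "subject_species_id"]]
                 .drop_duplicates().sort_values("subject_id"))
        with open(taxon_map_path, "w", encoding="utf-8") as fh:
            for r in pairs.itertuples(index=False):
                fh.write(f"{r.subject_id}\t{r.subject_taxon_group}\t{r.subject_species_id}\n")


# ---------------------------------------------------------------------------
# SpeciesTree
# ---------------------------------------------------------------------------

class SpeciesTree:
    """A rooted (possibly multifurcating) tree with unique leaf labels.

    Thin convenience wrapper over a :class:`dendropy.Tree`; internal nodes
    are addressable by label or by their descendant leaf set.
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True  # the outermost node is read as the root
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise IntegrityError(f"duplicate leaf labels: {dupes}")
        self._leaf_labels = labels

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True,
                                     suppress_internal_node_taxa=False)
        except Exception as exc:
            if "Duplicate taxon" in str(exc) or "duplicate" in str(exc).lower():
                raise IntegrityError(f"duplicate leaf labels: {exc}")
            raise FormatError(f"unparseable Newick: {exc}")
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaf_labels)

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leafset(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(lf.taxon.label for lf in node.leaf_iter())

    def node_label(self, node: dendropy.Node) -> str | None:
        if node.is_leaf():
            return node.taxon.label
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label

    def find_node(self, key: str | Iterable[str]) -> dendropy.Node:
        """Locate a node by internal/leaf label or by exact descendant leaf set."""
        if isinstance(key, str):
            for node in self.tree.preorder_node_iter():
                if self.node_label(node) == key:
                    return node
            raise KeyError(f"no node labelled {key!r}")
        want = frozenset(key)
        for node in self.tree.preorder_node_iter():
            if self.leafset(node) == want:
                return node
        raise KeyError(f"no node with leaf set {sorted(want)}")

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        missing = set(labels) - set(self._leaf_labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(labels) == 1:
            return self.tree.find_node_with_taxon_label(labels[0])
        return self.tree.mrca(taxon_labels=labels)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_tree(path: str | Path) -> SpeciesTree:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise FormatError(f"cannot read tree: {exc}", str(path))
    try:
        return SpeciesTree.from_newick(text)
    except FormatError as exc:
        raise FormatError(str(exc), str(path))
    except IntegrityError as exc:
        raise IntegrityError(str(exc), str(path))


def write_tree(tree: SpeciesTree, path: str | Path) -> None:
    Path(path).write_text(tree.as_newick() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# GeneModelTable
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One gene: longest-CDS exons in ascending genomic order, 1-based inclusive."""

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    rank_on_scaffold: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise IntegrityError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        exons = sorted(self.exons)
        prev_end = None
        for start, end in exons:
            if start > end:
                raise IntegrityError(f"gene {self.gene_id}: exon start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise IntegrityError(f"gene {self.gene_id}: overlapping exons")
            prev_end = end
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class GeneModelTable:
    """Scaffold-ordered gene models; ``rank_on_scaffold`` is the 1..n order
    of gene start positions within each scaffold."""

    genes: dict[str, GeneModel]

    def __post_init__(self) -> None:
        self.assign_ranks()

    def assign_ranks(self) -> None:
        by_scaffold: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            by_scaffold.setdefault(g.scaffold_id, []).append(g)
        for models in by_scaffold.values():
            models.sort(key=lambda g: (g.start, g.gene_id))
            for rank, g in enumerate(models, start=1):
                g.rank_on_scaffold = rank

    def by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes.values():
            out.setdefault(g.scaffold_id, []).append(g)
        for models in out.values():
            models.sort(key=lambda g: g.rank_on_scaffold)
        return out

    def __len__(self) -> int:
        return len(self.genes)


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path) -> GeneModelTable:
    """Read GFF3 gene/mRNA/exon-or-CDS features into a :class:`GeneModelTable`.

    Each gene is represented by its longest-CDS transcript. Validation:
    coordinates numeric and start <= end, strand one of ``+ - .``, exons
    within the declared gene span and non-overlapping within a transcript.
    """
    path = Path(path)
    genes: dict[str, dict] = {}          # gene_id -> {scaffold, strand, span, line}
    transcripts: dict[str, dict] = {}    # mrna_id -> {gene, exons, line}
    standalone: dict[str, list] = {}     # exons attached directly to a gene

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 9:
                raise FormatError(f"expected 9 GFF3 columns, got {len(cells)}",
                                  str(path), lineno)
            seqid, _src, ftype, start_s, end_s, _score, strand, _frame, attrs_s = cells[:9]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"non-integer coordinates {start_s!r}/{end_s!r}",
                                  str(path), lineno)
            if start > end:
                raise FormatError(f"start {start} > end {end}", str(path), lineno)
            if strand not in ("+", "-", "."):
                raise FormatError(f"unknown strand symbol {strand!r}", str(path), lineno)
            attrs = _parse_gff_attributes(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError("gene feature lacks ID attribute", str(path), lineno)
                genes[gid] = {"scaffold": seqid, "strand": strand,
                              "span": (start, end), "line": lineno}
            elif ftype in ("mRNA", "transcript"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid is None or parent is None:
                    raise FormatError("mRNA feature lacks ID/Parent", str(path), lineno)
                transcripts[tid] = {"gene": parent, "exons": [], "line": lineno}
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{ftype} feature lacks Parent", str(path), lineno)
                for pid in parent.split(","):
                    if pid in transcripts:
                        transcripts[pid]["exons"].append((start, end, lineno, ftype))
                    else:
                        standalone.setdefault(pid, []).append((start, end, lineno, ftype))

    models: dict[str, GeneModel] = {}
    # group transcripts by gene, pick the longest CDS
    per_gene: dict[str, list[dict]] = {}
    for tid, t in transcripts.items():
        per_gene.setdefault(t["gene"], []).append(t)
    for gid, chunks in standalone.items():
        if gid in genes:
            per_gene.setdefault(gid, []).append({"gene": gid, "exons": chunks, "line": None})

    for gid, ginfo in genes.items():
        candidates = per_gene.get(gid, [])
        if not candidates:
            raise FormatError(f"gene {gid} has no exon/CDS features", str(path),
                              ginfo["line"])
        best = None
        best_span = -1
        for t in candidates:
            raw = t["exons"]
            cds = [(s, e, ln) for s, e, ln, ft in raw if ft == "CDS"]
            use = cds if cds else [(s, e, ln) for s, e, ln, ft in raw]
            span = sum(e - s + 1 for s, e, _ in use)
            if span > best_span:
                best, best_span = use, span
        gstart, gend = ginfo["span"]
        exons = []
        for s, e, ln in sorted(best):
            if s < gstart or e > gend:
                raise IntegrityError(
                    f"exon ({s},{e}) outside declared span of gene {gid} "
                    f"({gstart},{gend})", str(path), ln)
            exons.append((s, e))
        prev_end = None
        for s, e in exons:
            if prev_end is not None and s <= prev_end:
                raise IntegrityError(f"overlapping exons in gene {gid}", str(path),
                                     ginfo["line"])
            prev_end = e
        models[gid] = GeneModel(gene_id=gid, scaffold_id=ginfo["scaffold"],
                                strand=ginfo["strand"], exons=exons)
    return GeneModelTable(genes=models)


def write_gene_models(table: GeneModelTable, path: str | Path,
                      source: str = "ecdysocomp") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(table.genes, key=lambda g: (table.genes[g].scaffold_id,
                                                      table.genes[g].start, g)):
            g = table.genes[gid]
            fh.write(f"{g.scaffold_id}\t{source}\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={gid}\n")
            tid = f"{gid}.t1"
            fh.write(f"{g.scaffold_id}\t{source}\tmRNA\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={gid}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.scaffold_id}\t{source}\tCDS\t{s}\t{e}\t.\t"
                         f"{g.strand}\t0\tID={tid}.cds{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# ExpressionTable
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene x sample TPM with a sample design and optional counts / FDR.

    ``design`` maps sample -> (condition, replicate); ``fdr`` is indexed by
    gene with NaN marking genes the external DE caller did not test.
    """

    tpm: pd.DataFrame
    design: pd.DataFrame  # index = sample, columns = condition, replicate
    counts: pd.DataFrame | None = None
    fdr: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise IntegrityError("negative TPM values")
        missing = [s for s in self.tpm.columns if s not in self.design.index]
        if missing:
            raise IntegrityError(f"samples missing from design: {missing}")
        if self.counts is not None:
            if list(self.counts.columns) != list(self.tpm.columns):
                raise IntegrityError("counts columns do not match TPM columns")
        if self.fdr is not None:
            vals = self.fdr.dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise IntegrityError("FDR values outside [0, 1]")
            # genes absent from the FDR file get the missing-FDR marker (NaN)
            self.fdr = self.fdr.reindex(self.tpm.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def samples_of(self, condition: str) -> list[str]:
        samples = list(self.design.index[self.design["condition"] == condition])
        if not samples:
            raise KeyError(f"no samples for condition {condition!r}")
        return [s for s in self.tpm.columns if s in samples]

    def condition_means(self, condition: str) -> pd.Series:
        return self.tpm[self.samples_of(condition)].mean(axis=1)


def read_expression_table(tpm_path: str | Path, design_path: str | Path,
                          fdr_path: str | Path | None = None,
                          counts_path: str | Path | None = None) -> ExpressionTable:
    """Read TPM matrix + design (+ optional counts and FDR) TSVs."""
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0, comment=None)
    if (tpm.values < 0).any():
        raise IntegrityError("negative TPM values", str(tpm_path))
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    if "condition" not in design.columns:
        raise FormatError("design file needs a 'condition' column", str(design_path))
    missing = [s for s in tpm.columns if s not in design.index]
    if missing:
        raise IntegrityError(f"samples missing from design: {missing}", str(design_path))
    counts = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts = counts[tpm.columns]
    fdr = None
    if fdr_path is not None:
        fdr_df = pd.read_csv(fdr_path, sep="\t", index_col=0)
        fdr = fdr_df.iloc[:, 0].astype(float)
    return ExpressionTable(tpm=tpm, design=design, counts=counts, fdr=fdr)


def write_expression_table(table: ExpressionTable, tpm_path: str | Path,
                           design_path: str | Path,
                           fdr_path: str | Path | None = None,
                           counts_path: str | Path | None = None) -> None:
    table.tpm.sort_index().to_csv(tpm_path, sep="\t")
    table.design.to_csv(design_path, sep="\t")
    if fdr_path is not None and table.fdr is not None:
        table.fdr.sort_index().rename("fdr").to_csv(fdr_path, sep="\t")
    if counts_path is not None and table.counts is not None:
        table.counts.sort_index().to_csv(counts_path, sep="\t")
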