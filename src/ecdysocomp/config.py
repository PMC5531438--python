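"""Run configuration and workflow orchestration.

A run is described by a flat YAML mapping: input paths, every named
threshold, an output directory and a seed. Unknown keys are rejected so a
typo cannot silently fall back to a default. Workflows write their outputs
plus a manifest (input checksums, the full effective configuration, the
package version); reruns with identical configuration and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

log = logging.getLogger("ecdysocomp")

_PATH_KEYS = (
    "hits", "taxon_map", "clusters", "tree_a", "tree_b", "gene_models",
    "tpm", "design", "fdr", "counts",
)


@dataclass
class RunConfig:
    """All inputs and thresholds of an orchestrated run.

    Threshold defaults are the published values: Hu >= 30 bits, E < 1e-5,
    FDR < 0.05, TPM > 1, fold change > 2, synapomorphy coverage >= 0.7,
    CDS outliers beyond +-20%, miRNA identity > 70%.
    """

    # input paths (workflow-dependent subset may be required)
    hits: str | None = None
    taxon_map: str | None = None
    clusters: str | None = None
    tree_a: str | None = None
    tree_b: str | None = None
    gene_models: str | None = None
    tpm: str | None = None
    design: str | None = None
    fdr: str | None = None
    counts: str | None = None
    active_condition: str = "active"
    tun_condition: str = "tun"
    sister_species: str | None = None

    # thresholds
    tau: float = 30.0
    evalue_cutoff: float = 1e-5
    expression_tpm_cutoff: float = 1.0
    expression_rule: str = "any_library"
    min_tree_leaves: int = 4
    cluster_max_gap: int = 1
    fdr_cutoff: float = 0.05
    tpm_cutoff: float = 1.0
    fc_cutoff: float = 2.0
    deg_tpm_rule: str = "either_condition"
    min_coverage: float = 0.7
    outlier_delta: float = 0.20
    identity_cutoff: float = 70.0

    # run control
    outdir: str = "ecdysocomp_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, overrides: dict | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("run configuration must be a mapping")
        if overrides:
            raw.update(overrides)
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {unknown}")
        return cls(**raw)

    def validate(self) -> list[str]:
        """Return all violations; empty list iff the config is runnable."""
        v = []
        if self.tau <= 0:
            v.append(f"tau must be > 0 (got {self.tau})")
        if self.evalue_cutoff <= 0:
            v.append(f"evalue_cutoff must be > 0 (got {self.evalue_cutoff})")
        if not 0 < self.fdr_cutoff <= 1:
            v.append(f"fdr_cutoff must be in (0, 1] (got {self.fdr_cutoff})")
        if self.fc_cutoff <= 1:
            v.append(f"fc_cutoff must be > 1 (got {self.fc_cutoff})")
        if not 0 <= self.min_coverage <= 1:
            v.append(f"min_coverage must be in [0, 1] (got {self.min_coverage})")
        if not 0 < self.outlier_delta < 1:
            v.append(f"outlier_delta must be in (0, 1) (got {self.outlier_delta})")
        if not 0 <= self.identity_cutoff <= 100:
            v.append(f"identity_cutoff must be in [0, 100] (got {self.identity_cutoff})")
        if self.expression_rule not in ("any_library", "mean"):
            v.append(f"unknown expression_rule {self.expression_rule!r}")
        if self.deg_tpm_rule not in ("either_condition", "overall_mean"):
            v.append(f"unknown deg_tpm_rule {self.deg_tpm_rule!r}")
        if self.cluster_max_gap < 0:
            v.append("cluster_max_gap must be >= 0")
        if self.min_tree_leaves < 3:
            v.append("min_tree_leaves must be >= 3")
        if self.seed < 0:
            v.append("seed must be >= 0")
        return v


def validate_config(config: RunConfig) -> list[str]:
    return config.validate()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


WORKFLOWS = ("hgt", "synapomorphy", "expression", "simulate-all")

EXIT_OK = 0
EXIT_INTERNAL = 1
EXIT_MISSING_INPUT = 2
EXIT_VALIDATION = 3


def run_workflow(name: str, config: RunConfig) -> dict:
    """Execute one named workflow; returns the manifest.

    Raises ConfigError for validation problems and FileNotFoundError for
    missing inputs (the CLI maps these to distinct exit codes).
    """
    from . import __version__

    if name not in WORKFLOWS:
        raise ConfigError(f"unknown workflow {name!r}; choose from {WORKFLOWS}")
    violations = config.validate()
    if violations:
        raise ConfigError("; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    for key in _PATH_KEYS:
        val = getattr(config, key)
        if val is not None:
            p = Path(val)
            if not p.exists():
                raise FileNotFoundError(f"input {key!r}: {val} does not exist")
            inputs[key] = _sha256(p)

    log.info("workflow=%s thresholds: tau=%s evalue<%s fdr<%s tpm>%s fc>%s "
             "coverage>=%s outliers=+-%s%% identity>%s%%",
             name, config.tau, config.evalue_cutoff, config.fdr_cutoff,
             config.tpm_cutoff, config.fc_cutoff, config.min_coverage,
             config.outlier_delta * 100, config.identity_cutoff)

    if name == "hgt":
        outputs = _workflow_hgt(config, outdir)
    elif name == "synapomorphy":
        outputs = _workflow_synapomorphy(config, outdir)
    elif name == "expression":
        outputs = _workflow_expression(config, outdir)
    else:
        outputs = _workflow_simulate_all(config, outdir)

    manifest = {
        "workflow": name,
        "version": __version__,
        "config": asdict(config),
        "input_checksums": inputs,
        "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
    }
    manifest_path = outdir / f"manifest_{name}.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    return manifest


def _require(config: RunConfig, *keys: str) -> None:
    missing = [k for k in keys if getattr(config, k) is None]
    if missing:
        raise FileNotFoundError(f"workflow needs inputs: {missing}")


def _workflow_hgt(config: RunConfig, outdir: Path) -> dict[str, str]:
    from .formats import read_hit_table, read_gene_models, read_expression_table, \
        read_cluster_table
    from .hgt import (ScreenConfig, compute_hgt_index, annotate_validation,
                      tier_counts, cluster_hgt_loci, screen_report)

    _require(config, "hits", "taxon_map")
    hits = read_hit_table(config.hits, config.taxon_map)
    screen = ScreenConfig(tau=config.tau, evalue_cutoff=config.evalue_cutoff,
                          expression_tpm_cutoff=config.expression_tpm_cutoff,
                          expression_rule=config.expression_rule,
                          min_tree_leaves=config.min_tree_leaves,
                          cluster_max_gap=config.cluster_max_gap)
    scores = compute_hgt_index(hits, screen)
    expression = models = clusters = None
    if config.tpm and config.design:
        expression = read_expression_table(config.tpm, config.design, config.fdr)
    if config.gene_models:
        models = read_gene_models(config.gene_models)
    if config.clusters:
        clusters = read_cluster_table(config.clusters)
    validations = annotate_validation(scores, {}, expression, models, clusters,
                                      config.sister_species, screen)
    report = screen_report(scores, validations)
    report_path = outdir / "hgt_screen.tsv"
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(report.columns) + "\n")
        report.to_csv(fh, sep="\t", header=False, index=False)
    tiers = tier_counts(validations, total_genes=len(scores))
    summary = {"n_genes": len(scores), "tiers": asdict(tiers)}
    outputs = {"hgt_screen.tsv": str(report_path)}
    if models is not None:
        hgt_ids = [s.gene_id for s in scores if s.is_candidate]
        clusters_found, distances, skipped = cluster_hgt_loci(models, hgt_ids, screen)
        dist_path = outdir / "hgt_neighborhood.tsv"
        with open(dist_path, "w", encoding="utf-8") as fh:
            fh.write("# " + "\t".join(distances.columns) + "\n")
            distances.to_csv(fh, sep="\t", header=False, index=False)
        summary["n_hgt_clusters"] = len(clusters_found)
        summary["skipped_hgt_ids"] = skipped
        outputs["hgt_neighborhood.tsv"] = str(dist_path)
    summary_path = outdir / "hgt_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
    outputs["hgt_summary.json"] = str(summary_path)
    return outputs


def _workflow_synapomorphy(config: RunConfig, outdir: Path) -> dict[str, str]:
    from .formats import read_cluster_table, read_tree
    from .dollo import (build_presence_matrix, synapomorphies_at_node,
                        coverage_histogram, threshold_synapomorphy_report)

    _require(config, "clusters", "tree_a", "tree_b")
    clusters = read_cluster_table(config.clusters)
    matrix = build_presence_matrix(clusters)
    rows = []
    outputs: dict[str, str] = {}
    for hyp, path in (("A", config.tree_a), ("B", config.tree_b)):
        tree = read_tree(path)
        for node in tree.tree.preorder_internal_node_iter():
            label = tree.node_label(node)
            if not label:
                continue
            records = synapomorphies_at_node(tree, matrix, node)
            retained = threshold_synapomorphy_report(records, config.min_coverage)
            rows.append({"hypothesis": hyp, "node": label,
                         "n_synapomorphies": len(records),
                         "n_above_coverage": len(retained),
                         "histogram": "|".join(
                             str(int(x)) for x in coverage_histogram(records))})
    import pandas as pd
    df = pd.DataFrame(rows).sort_values(["hypothesis", "node"]).reset_index(drop=True)
    path = outdir / "synapomorphies.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    outputs["synapomorphies.tsv"] = str(path)
    return outputs


def _workflow_expression(config: RunConfig, outdir: Path) -> dict[str, str]:
    from .formats import read_expression_table
    from .expression import compute_fold_changes, call_degs

    _require(config, "tpm", "design")
    expr = read_expression_table(config.tpm, config.design, config.fdr)
    fc, fc_summary = compute_fold_changes(expr, config.active_condition,
                                          config.tun_condition)
    calls, deg_summary = call_degs(expr, config.active_condition,
                                   config.tun_condition,
                                   fdr_cutoff=config.fdr_cutoff,
                                   tpm_cutoff=config.tpm_cutoff,
                                   fc_cutoff=config.fc_cutoff,
                                   tpm_rule=config.deg_tpm_rule)
    import pandas as pd
    df = pd.DataFrame([{
        "gene_id": c.gene_id, "mean_tpm_active": c.mean_tpm_active,
        "mean_tpm_tun": c.mean_tpm_tun, "fold_change": c.fold_change,
        "fdr": c.fdr, "is_deg": c.is_deg, "direction": c.direction,
    } for c in calls]).sort_values("gene_id")
    path = outdir / "deg_calls.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
    summary_path = outdir / "expression_summary.json"
    summary_path.write_text(json.dumps(
        {"fold_change": fc_summary, "degs": deg_summary},
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return {"deg_calls.tsv": str(path),
            "expression_summary.json": str(summary_path)}


def _workflow_simulate_all(config: RunConfig, outdir: Path) -> dict[str, str]:
    from .formats import (SpeciesTree, write_cluster_table, write_gene_models,
                          write_hit_table, write_expression_table)
    from .simulate import (simulate_gene_families, simulate_hgt_hits,
                           simulate_genome_pair, simulate_expression,
                           simulate_mirna_hits)

    sim = outdir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    tree = SpeciesTree.from_newick(
        "((((T1,T2)Tardigrada,(A1,(A2,A3))Arthropoda)Panarthropoda,"
        "(N1,(N2,N3))Nematoda)Ecdysozoa,OUT)Root;")
    clusters, fam_truth = simulate_gene_families(tree, n_families=200, seed=seed)
    write_cluster_table(clusters, sim / "orthogroups.tsv")
    with open(sim / "families_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("# family_id\tbirth_node\tn_losses\tpresent_leaves\n")
        for t in fam_truth:
            fh.write(f"{t.family_id}\t{','.join(sorted(t.birth_node))}\t"
                     f"{len(t.lost_branches)}\t{','.join(sorted(t.present_leaves))}\n")
    hits, hgt_truth = simulate_hgt_hits(n_genes=1000, seed=seed)
    write_hit_table(hits, sim / "hits.outfmt6.tsv", sim / "taxon_map.tsv")
    with open(sim / "hgt_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tis_hgt\tmargin\n")
        for gid in sorted(hgt_truth.margins):
            fh.write(f"{gid}\t{int(gid in hgt_truth.hgt_gene_ids)}\t"
                     f"{hgt_truth.margins[gid]:.3f}\n")
    models_a, models_b, pairs, pair_truth = simulate_genome_pair(
        n_inversions=3, intron_scale_ratio=2.0, seed=seed)
    write_gene_models(models_a, sim / "genome_a.gff3")
    write_gene_models(models_b, sim / "genome_b.gff3")
    with open(sim / "orthologues.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(pair_truth.orthologues.items()):
            fh.write(f"{a}\t{b}\n")
    expr, expr_truth = simulate_expression(n_genes=500, seed=seed)
    write_expression_table(expr, sim / "tpm.tsv", sim / "design.tsv",
                           sim / "fdr.tsv", sim / "counts.tsv")
    with open(sim / "expression_truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("# gene_id\tis_deg\tplanted_log2fc\n")
        for gid in sorted(expr_truth.planted_log2fc):
            fh.write(f"{gid}\t{int(gid in expr_truth.deg_gene_ids)}\t"
                     f"{expr_truth.planted_log2fc[gid]:.2f}\n")
    mirna, _ = simulate_mirna_hits(n=50, seed=seed)
    mirna.to_csv(sim / "mirna_hits.tsv", sep="\t", index=False)
    return {p.name: str(p) for p in sorted(sim.iterdir())}
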