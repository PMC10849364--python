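"""End-to-end pipeline orchestration from a single YAML config.

Stages run in order — GWAS prioritization, seed-list merging, network
construction (level zero and level one), clustering with QC, expression
re-analysis and Monte-Carlo overlap enrichment, DE-table overlays, and
term grouping — skipping any stage whose inputs are absent from the config
(e.g. with no SNP tables the run starts from the provided seed lists).

A JSON run manifest records the thresholds, the RNG seed, SHA-256 digests
of every input and output table and per-stage row counts, so identical
config + inputs give an identical manifest (digest fields included).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, gwas, interactome, seeds, stats, terms

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All inputs and thresholds for a pipeline run.

    Threshold defaults are the study's published constants: +/-250 kb PD
    windows, r^2 >= 0.8 LD proxies, confidence >= 0.72, seed:bridge ratio
    >= 0.7, adjusted p < 0.05, alpha = 0.05, fold-change classes (2, 3, 4),
    100,000 overlap simulations.
    """

    outdir: str = "melanet_run"
    rng_seed: int = 17
    # stage inputs (absent -> stage skipped)
    snps: str | None = None
    gene_models: str | None = None
    elements: str | None = None
    ld_proxies: str | None = None
    eqtls: str | None = None
    gwas_genes: str | None = None
    familial_genes: str | None = None
    somatic_genes: str | None = None
    interactions: str | None = None
    expression_matrix: str | None = None
    expression_groups: str | None = None
    de_tables: dict[str, str] = field(default_factory=dict)
    term_tables: dict[str, str] = field(default_factory=dict)
    term_relations: str | None = None
    lexicon: str | None = None
    # thresholds
    half_window: int = 250_000
    r2_min: float = 0.8
    min_confidence: float = 0.72
    strict_gt: bool = False
    min_ratio: float = 0.7
    min_nodes: int = 10
    padj_max: float = 0.05
    alpha: float = 0.05
    fc_thresholds: tuple[float, ...] = (2.0, 3.0, 4.0)
    fc_scale: str = "log2"
    n_sims: int = 100_000
    max_term_size: int | None = 300
    term_size_op: str = "le"
    min_intersection: int | None = 3
    coverage: float = 0.5
    hub_min_degree: int = 14

    def validate(self) -> None:
        checks = [
            ("r2_min", 0.0, 1.0),
            ("min_confidence", 0.0, 1.0),
            ("padj_max", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("coverage", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.half_window < 0 or self.n_sims < 1 or self.min_ratio < 0:
            raise ValueError("negative threshold")


def load_config(path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "fc_thresholds" in raw:
        raw["fc_thresholds"] = tuple(raw["fc_thresholds"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (sorted(v.items()) if isinstance(v, dict) else v)
            for k, v in vars(config).items()
        },
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def record_input(name, path):
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def write_table(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _sha256(path)
        return path

    stage = "gwas_prioritization"
    gwas_list = None
    if config.snps and config.gene_models and config.elements:
        try:
            record_input("snps", config.snps)
            record_input("gene_models", config.gene_models)
            record_input("elements", config.elements)
            record_input("ld_proxies", config.ld_proxies)
            record_input("eqtls", config.eqtls)
            snps = gwas.read_snps(config.snps)
            table, summary = gwas.prioritize(
                snps,
                gwas.read_gene_models(config.gene_models),
                gwas.read_elements(config.elements),
                gwas.read_ld_proxies(config.ld_proxies) if config.ld_proxies else [],
                gwas.read_eqtls(config.eqtls) if config.eqtls else [],
                half_window=config.half_window,
                r2_min=config.r2_min,
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        write_table(table, "prioritized_genes.tsv")
        manifest["stages"][stage] = summary
        gwas_list = list(table["symbol"])
        log.info("%s: %d candidate genes", stage, len(table))

    stage = "seed_merge"
    seed_table = None
    if gwas_list is not None or config.gwas_genes:
        try:
            if config.gwas_genes:
                record_input("gwas_genes", config.gwas_genes)
                gwas_list = seeds.read_gene_list(config.gwas_genes)
            familial = somatic = []
            if config.familial_genes:
                record_input("familial_genes", config.familial_genes)
                familial = seeds.read_gene_list(config.familial_genes)
            if config.somatic_genes:
                record_input("somatic_genes", config.somatic_genes)
                somatic = seeds.read_gene_list(config.somatic_genes)
            seed_table = seeds.merge_seed_lists(gwas_list or [], familial, somatic)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        write_table(seed_table.table, "seeds.tsv")
        manifest["stages"][stage] = {
            "n_seeds": len(seed_table),
            "composition": seed_table.composition,
        }

    stage = "network"
    model_genes: set[str] | None = None
    level1 = None
    if seed_table is not None and config.interactions:
        try:
            record_input("interactions", config.interactions)
            records = interactome.read_interactions(config.interactions)
            qcd = interactome.qc_level_zero(records)
            g0, report0 = interactome.build_level_zero(seed_table.symbols, qcd)
            hc = interactome.filter_high_confidence(
                records, config.min_confidence, strict_gt=config.strict_gt
            )
            level1, report1 = interactome.build_level_one(seed_table.symbols, hc)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        interactome.write_network(g0, outdir / "level0.edges.tsv", outdir / "level0.nodes.tsv")
        interactome.write_network(level1, outdir / "level1.edges.tsv", outdir / "level1.nodes.tsv")
        for name in ("level0.edges.tsv", "level0.nodes.tsv", "level1.edges.tsv", "level1.nodes.tsv"):
            manifest["outputs"][name] = _sha256(outdir / name)
        core = interactome.largest_component(level1)
        model_genes = set(core.nodes)
        hubs = interactome.hub_nodes(core, config.hub_min_degree)
        manifest["stages"][stage] = {
            "records_in": len(records),
            "level0_qc_kept": len(qcd),
            "high_confidence_kept": len(hc),
            "level0_core_size": report0["component_sizes"][0] if report0["component_sizes"] else 0,
            "level0_components": report0["component_sizes"],
            "level1_core": report1["core"],
            "hubs": hubs[:25],
        }
        log.info("%s: model core %s", stage, report1["core"])

    stage = "clustering"
    if level1 is not None and level1.number_of_edges() > 0:
        try:
            core = interactome.largest_component(level1)
            partition = clustering.greedy_modularity(core)
            roles = {n: core.nodes[n]["role"] for n in core.nodes}
            reports = clustering.qc_clusters(
                partition, roles, config.min_nodes, config.min_ratio
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        membership = partition.membership()
        write_table(
            pd.DataFrame(
                sorted(membership.items()), columns=["node", "cluster_id"]
            ),
            "clusters.tsv",
        )
        write_table(clustering.reports_frame(reports), "cluster_qc.tsv")
        manifest["stages"][stage] = {
            "n_clusters": len(partition.clusters),
            "modularity_q": partition.modularity_q,
            "n_passed_qc": sum(r.passed_qc for r in reports),
        }

    stage = "expression_validation"
    if model_genes and config.expression_matrix and config.expression_groups:
        try:
            record_input("expression_matrix", config.expression_matrix)
            record_input("expression_groups", config.expression_groups)
            matrix, groups = stats.read_expression(
                config.expression_matrix, config.expression_groups
            )
            gene_stats = stats.analyze_expression(
                matrix, groups, config.alpha, config.fc_thresholds, config.fc_scale
            )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        write_table(gene_stats, "expression_stats.tsv")
        universe = set(gene_stats["gene"])
        overlaps = {}
        for i, k in enumerate(config.fc_thresholds):
            col = f"FC{k:g}"
            fc_set = set(gene_stats.loc[gene_stats[col], "gene"])
            res = stats.overlap_enrichment(
                fc_set,
                model_genes,
                universe,
                n_sims=config.n_sims,
                rng_seed=config.rng_seed + i,
            )
            overlaps[col] = vars(res)
        manifest["stages"][stage] = {
            "n_genes": len(gene_stats),
            "bonferroni_threshold": gene_stats.attrs["bonferroni_threshold"],
            "n_significant": int(gene_stats["significant"].sum()),
            "fc_overlaps": overlaps,
        }

    stage = "de_overlay"
    if model_genes and config.de_tables:
        results = {}
        for i, (label, path) in enumerate(sorted(config.de_tables.items())):
            try:
                record_input(f"de_{label}", path)
                de = stats.read_de_table(path)
                overlap, fraction = stats.overlay_de(de, model_genes, config.padj_max)
                universe = set(de["gene"]) | model_genes
                res = stats.overlap_enrichment(
                    {g for g, p in zip(de["gene"], de["padj"]) if float(p) < config.padj_max},
                    model_genes,
                    universe,
                    n_sims=config.n_sims,
                    rng_seed=config.rng_seed + 100 + i,
                )
            except Exception as exc:
                raise RuntimeError(f"stage {stage} ({label}) failed: {exc}") from exc
            results[label] = {
                "n_overlap": len(overlap),
                "fraction_of_model": fraction,
                "pct_of_model": 100.0 * fraction,
                "enrichment": vars(res),
            }
            write_table(
                pd.DataFrame({"gene": sorted(overlap)}), f"overlay_{label}.tsv"
            )
        manifest["stages"][stage] = results

    stage = "term_grouping"
    if config.term_tables:
        lexicon = (
            terms.read_lexicon(config.lexicon) if config.lexicon else terms.DEFAULT_LEXICON
        )
        results = {}
        for label, path in sorted(config.term_tables.items()):
            try:
                record_input(f"terms_{label}", path)
                table = terms.read_terms(path)
                filtered = terms.filter_terms(
                    table, config.max_term_size, config.min_intersection,
                    config.term_size_op,
                )
                groups, annotated = terms.group_by_keywords(filtered, lexicon)
                top = terms.top_groups(groups, config.coverage) if groups else []
            except Exception as exc:
                raise RuntimeError(f"stage {stage} ({label}) failed: {exc}") from exc
            write_table(annotated, f"terms_{label}_grouped.tsv")
            results[label] = {
                "n_terms_in": len(table),
                "n_terms_filtered": len(filtered),
                "groups": [
                    {"keyword": g.keyword, "n_terms": g.n_terms,
                     "pct": g.pct_of_filtered, "min_p_adj": g.min_p_adj}
                    for g in groups
                ],
                "top_groups": [g.keyword for g in top],
            }
        manifest["stages"][stage] = results

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
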