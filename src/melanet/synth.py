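"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis is testable offline: a HIPPIE-dialect interaction table with a
planted seed core, pendant seed pairs, true bridges and assorted decoys; a
two-group expression matrix with planted log2 fold changes (default group
sizes 7 vs 45, the normal-skin vs melanoma array design); a DESeq2-style DE
table with a planted fraction of model genes below the significance cutoff;
and a GWAS fixture (SNPs, gene models, genomic elements, LD proxies, skin
eQTLs) with a designed evidence composition.

Each generator is a pure function of its config: the same config (including
its ``rng_seed``) always yields identical tables.  Ground-truth objects
record exactly what was planted, so pipeline stages can be checked for
exact recovery.

Default shapes mirror the magnitudes of the melanoma study (232 seeds, a
~400-node level-one core, 7 vs 45 arrays over ~22k genes); unit tests use
small overrides for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactome import Interaction

__all__ = [
    "InteractomeConfig",
    "ExpressionConfig",
    "DeConfig",
    "SnpConfig",
    "InteractomeTruth",
    "ExpressionTruth",
    "SnpTruth",
    "gen_interactome",
    "gen_expression",
    "gen_de_table",
    "gen_snp_fixture",
]

_METHODS = (
    "two hybrid",
    "affinity chromatography",
    "pull down",
    "x-ray crystallography",
    "anti tag coimmunoprecipitation",
)


def _pmids(rng, k=1):
    return tuple(str(rng.integers(10_000_000, 40_000_000)) for _ in range(k))


# ===========================================================================
# Interactome

@dataclass(frozen=True)
class InteractomeConfig:
    """Planted-interactome design.

    The seed list splits into a densely connected core (direct seed-seed
    interactions), satellite seeds reachable only through bridges, pendant
    pairs (isolated two-seed components) and fully isolated seeds.  True
    bridges connect >= 2 mutually unconnected seeds with high-confidence
    edges; decoy interactors attach to already-connected seed pairs or to a
    single seed and must not be called bridges.  Noise records (confidence
    below threshold, missing PubMed ids, "unspecified"-only methods,
    ubiquitin partners, ambiguous/nonstandard mappings) exercise the QC
    paths without touching the planted censuses.
    """

    rng_seed: int = 17
    n_seeds: int = 232
    n_core_seeds: int = 148
    n_satellite_seeds: int = 46
    n_pendant_pairs: int = 4
    n_true_bridges: int = 208
    n_decoy_nonbridges: int = 30
    n_low_confidence: int = 120
    n_low_quality: int = 20
    n_ubiquitin_decoys: int = 10
    n_flagged: int = 10
    core_extra_edge_prob: float = 0.03
    triple_seed_bridge_prob: float = 0.3
    confidence_threshold: float = 0.72

    def __post_init__(self) -> None:
        reserved = self.n_core_seeds + self.n_satellite_seeds + 2 * self.n_pendant_pairs
        if reserved > self.n_seeds:
            raise ValueError("seed roles exceed n_seeds")
        if self.n_core_seeds < 2:
            raise ValueError("need >= 2 core seeds")
        if self.n_true_bridges < self.n_satellite_seeds:
            raise ValueError("each satellite seed needs at least one bridge")


@dataclass
class InteractomeTruth:
    seeds: list[str]
    core_level0: set[str]
    satellite_seeds: set[str]
    pendant_pairs: list[tuple[str, str]]
    isolated_seeds: set[str]
    bridges: set[str]
    decoys: set[str]
    level1_core_nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.level1_core_nodes:
            self.level1_core_nodes = (
                self.core_level0 | self.satellite_seeds | self.bridges
            )


def gen_interactome(cfg: InteractomeConfig) -> tuple[list[Interaction], InteractomeTruth]:
    """Generate a planted interaction table and its ground truth."""
    rng = np.random.default_rng(cfg.rng_seed)
    lo, hi = cfg.confidence_threshold, 1.0

    def conf_high():
        return round(float(rng.uniform(lo, hi)), 4)

    def conf_low():
        return round(float(rng.uniform(0.2, lo - 0.02)), 4)

    width = len(str(cfg.n_seeds))
    seeds = [f"S{i:0{width}d}" for i in range(1, cfg.n_seeds + 1)]
    core = seeds[: cfg.n_core_seeds]
    sats = seeds[cfg.n_core_seeds : cfg.n_core_seeds + cfg.n_satellite_seeds]
    pend_start = cfg.n_core_seeds + cfg.n_satellite_seeds
    pendants = [
        (seeds[pend_start + 2 * i], seeds[pend_start + 2 * i + 1])
        for i in range(cfg.n_pendant_pairs)
    ]
    isolated = set(seeds[pend_start + 2 * cfg.n_pendant_pairs :])

    records: list[Interaction] = []
    seed_edges: set[frozenset] = set()

    def add(a, b, conf, pmid=1, methods=None, **kw):
        records.append(
            Interaction(
                symbol_a=a,
                symbol_b=b,
                confidence=conf,
                pubmed_ids=_pmids(rng, pmid),
                detection_methods=methods
                if methods is not None
                else (str(rng.choice(_METHODS)),),
                **kw,
            )
        )

    def add_seed_edge(a, b):
        pair = frozenset((a, b))
        if pair in seed_edges:
            return
        seed_edges.add(pair)
        add(a, b, conf_high())

    # connected core: random spanning tree plus extra edges
    order = list(rng.permutation(core))
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        add_seed_edge(order[i], order[j])
    n_pairs_extra = int(
        cfg.core_extra_edge_prob * cfg.n_core_seeds * (cfg.n_core_seeds - 1) / 2
    )
    for _ in range(n_pairs_extra):
        a, b = rng.choice(cfg.n_core_seeds, size=2, replace=False)
        add_seed_edge(core[int(a)], core[int(b)])

    for a, b in pendants:
        add_seed_edge(a, b)

    # true bridges: each wired to >= 2 mutually unconnected seeds
    bwidth = len(str(max(cfg.n_true_bridges, 1)))
    bridges = [f"B{i:0{bwidth}d}" for i in range(1, cfg.n_true_bridges + 1)]
    connectable = core + sats  # pendant/isolated seeds stay outside the core
    for i, bridge in enumerate(bridges):
        if i < len(sats):
            s1 = core[int(rng.integers(0, len(core)))]
            s2 = sats[i]  # satellites carry no seed-seed edge: never adjacent
        else:
            while True:
                ia, ib = rng.choice(len(core), size=2, replace=False)
                s1, s2 = core[int(ia)], core[int(ib)]
                if frozenset((s1, s2)) not in seed_edges:
                    break
        add(bridge, s1, conf_high())
        add(bridge, s2, conf_high())
        if rng.random() < cfg.triple_seed_bridge_prob:
            s3 = connectable[int(rng.integers(0, len(connectable)))]
            if s3 not in (s1, s2):
                add(bridge, s3, conf_high())

    # decoys: attach to one seed or to a directly connected seed pair
    dwidth = len(str(max(cfg.n_decoy_nonbridges, 1)))
    decoys = [f"D{i:0{dwidth}d}" for i in range(1, cfg.n_decoy_nonbridges + 1)]
    connected_pairs = [tuple(sorted(p)) for p in sorted(seed_edges, key=sorted)]
    for i, decoy in enumerate(decoys):
        if i % 2 == 0 and connected_pairs:
            s1, s2 = connected_pairs[int(rng.integers(0, len(connected_pairs)))]
            add(decoy, s1, conf_high())
            add(decoy, s2, conf_high())
        else:
            add(decoy, core[int(rng.integers(0, len(core)))], conf_high())

    # sub-threshold noise: seed-nonseed and nonseed-nonseed only, so the
    # planted seed-seed structure is untouched at every level
    noise_partners = [f"N{i:04d}" for i in range(1, cfg.n_low_confidence + 1)]
    for i, partner in enumerate(noise_partners):
        other = seeds[int(rng.integers(0, len(seeds)))] if i % 3 else bridges[
            int(rng.integers(0, len(bridges)))
        ] if bridges else partner + "X"
        add(partner, other, conf_low())

    # low-quality records: fail level-zero QC (no PubMed id or
    # unspecified-only methods) and the confidence cut
    for i in range(cfg.n_low_quality):
        a = seeds[int(rng.integers(0, len(seeds)))]
        b = f"Q{i:03d}"
        if i % 2:
            add(a, b, conf_low(), pmid=0)
        else:
            records.append(
                Interaction(a, b, conf_low(), _pmids(rng), ("unspecified",))
            )

    # promiscuous ubiquitin partners: high confidence but always removed
    for i in range(cfg.n_ubiquitin_decoys):
        ub = ("UBB", "UBC", "UBD")[i % 3]
        add(ub, seeds[int(rng.integers(0, len(seeds)))], conf_high())

    # flagged records: ambiguous Entrez mapping / nonstandard symbol
    for i in range(cfg.n_flagged):
        a = seeds[int(rng.integers(0, len(seeds)))]
        if i % 2:
            add(a, f"A{i:03d}", conf_high(), ambiguous_mapping=True)
        else:
            add(a, f"X{i:03d}_HUMAN", conf_high(), nonstandard_symbol=True)

    # a couple of self-interactions for the QC path
    add(seeds[0], seeds[0], conf_high())

    truth = InteractomeTruth(
        seeds=seeds,
        core_level0=set(core),
        satellite_seeds=set(sats),
        pendant_pairs=pendants,
        isolated_seeds=isolated | set(sats),  # isolated *at level zero*
        bridges=set(bridges),
        decoys=set(decoys),
    )
    return records, truth


# ===========================================================================
# Expression matrix

@dataclass(frozen=True)
class ExpressionConfig:
    """Two-group array-style intensity matrix with planted log2 fold changes.

    Defaults mirror the melanoma array comparison: 7 reference (normal skin)
    vs 45 case (melanoma) samples over 22,321 genes (the family size implied
    by the Bonferroni cut 0.05 / 22,321 = 2.24e-6).  ``planted`` lists
    (log2fc, count) blocks; intensities are log-normal with i.i.d. Gaussian
    noise on the log2 scale.
    """

    rng_seed: int = 17
    n_genes: int = 22_321
    n_group1: int = 7
    n_group2: int = 45
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.4
    planted: tuple[tuple[float, int], ...] = (
        (1.0, 100),
        (2.5, 80),
        (-2.5, 80),
        (3.5, 50),
        (-3.5, 50),
        (4.5, 25),
        (-4.5, 25),
    )
    group_labels: tuple[str, str] = ("normal", "tumor")

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ValueError("need >= 2 samples per group")
        if sum(c for _, c in self.planted) > self.n_genes:
            raise ValueError("more planted genes than genes")


@dataclass
class ExpressionTruth:
    planted_log2fc: dict[str, float]  # gene -> planted shift (group2 - group1)
    fc_members: dict[str, set[str]]  # "FC2"/"FC3"/"FC4" -> genes by construction


def gen_expression(
    cfg: ExpressionConfig, gene_names: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Generate (matrix, groups, truth).

    ``matrix`` is genes x samples on the linear intensity scale; ``groups``
    maps sample to label.  ``gene_names`` may supply the gene universe (e.g.
    to embed network-model genes); missing names are padded with G-numbered
    fillers.  Planted genes are drawn deterministically from the start of
    the shuffled gene list.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    if gene_names is None:
        genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    else:
        genes = [str(g) for g in gene_names]
        genes += [f"G{i:05d}" for i in range(1, cfg.n_genes - len(genes) + 1)]
        if len(set(genes)) != cfg.n_genes:
            raise ValueError("gene_names must be unique and <= n_genes")
    samples = [f"{cfg.group_labels[0]}_{i}" for i in range(1, cfg.n_group1 + 1)] + [
        f"{cfg.group_labels[1]}_{i}" for i in range(1, cfg.n_group2 + 1)
    ]
    groups = pd.Series(
        [cfg.group_labels[0]] * cfg.n_group1 + [cfg.group_labels[1]] * cfg.n_group2,
        index=samples,
        name="group",
    )

    shuffled = list(rng.permutation(genes))
    planted: dict[str, float] = {}
    cursor = 0
    for lfc, count in cfg.planted:
        for g in shuffled[cursor : cursor + count]:
            planted[g] = lfc
        cursor += count

    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))
    log2 = base[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(len(genes), len(samples))
    )
    shift = np.array([planted.get(g, 0.0) for g in genes])
    log2[:, cfg.n_group1 :] += shift[:, None]
    matrix = pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"), columns=samples)

    fc_members = {
        f"FC{k:g}": {g for g, v in planted.items() if abs(v) > k} for k in (2, 3, 4)
    }
    return matrix, groups, ExpressionTruth(planted_log2fc=planted, fc_members=fc_members)


# ===========================================================================
# DE table

@dataclass(frozen=True)
class DeConfig:
    """Treated-vs-control DE export with a planted model overlap.

    Exactly ``round(model_fraction * |model|)`` model genes receive an
    adjusted p below ``padj_threshold``; background genes are significant at
    ``background_fraction``.  The default fraction matches the strongest
    treatment overlay in the study (215/402).
    """

    rng_seed: int = 17
    model_fraction: float = 215 / 402
    background_fraction: float = 0.3
    n_background: int = 15_000
    padj_threshold: float = 0.05
    log2fc_sd: float = 1.5

    def __post_init__(self) -> None:
        for name in ("model_fraction", "background_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def gen_de_table(cfg: DeConfig, model) -> tuple[pd.DataFrame, set[str]]:
    """Generate (DE table, planted significant model-gene set)."""
    rng = np.random.default_rng(cfg.rng_seed)
    model = sorted({str(g) for g in model})
    n_sig = round(cfg.model_fraction * len(model))
    sig_model = set(rng.choice(model, size=n_sig, replace=False)) if n_sig else set()
    background = [f"BG{i:05d}" for i in range(1, cfg.n_background + 1)]
    rows = []
    for g in model + background:
        if g in sig_model:
            significant = True
        elif g in background:
            significant = bool(rng.random() < cfg.background_fraction)
        else:
            significant = False
        if significant:
            padj = float(rng.uniform(1e-10, cfg.padj_threshold * 0.98))
        else:
            padj = float(rng.uniform(cfg.padj_threshold, 1.0))
        rows.append(
            {
                "gene": g,
                "log2fc": float(rng.normal(0.0, cfg.log2fc_sd)),
                "pvalue": padj * float(rng.uniform(0.05, 1.0)),
                "padj": padj,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "padj"]), sig_model


# ===========================================================================
# GWAS fixture

@dataclass(frozen=True)
class SnpConfig:
    """Designed GWAS fixture.

    Defaults reproduce the study's marker arithmetic: 54 risk SNPs of which
    10 are coding (exon/3'UTR) and 44 noncoding, and a prioritized-gene
    design of 108 proximity/LD-only, 25 proximity+eQTL and 2 eQTL-only genes
    (135 noncoding-derived candidates).  SNPs sit in disjoint 2-Mb blocks so
    +/-250 kb windows never overlap.
    """

    rng_seed: int = 17
    n_snps: int = 54
    n_coding: int = 10
    n_intronic: int = 20
    n_prox_only: int = 108
    n_both: int = 25
    n_eqtl_only: int = 2
    half_window: int = 250_000
    block: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_coding + self.n_intronic > self.n_snps:
            raise ValueError("category counts exceed n_snps")
        if 2 * self.half_window >= self.block:
            raise ValueError("blocks must be wider than the PD window")


@dataclass
class SnpTruth:
    coding_snps: set[str]
    intronic_snps: set[str]
    intergenic_snps: set[str]
    coding_genes: set[str]
    prox_only: set[str]
    both: set[str]
    eqtl_only: set[str]
    no_ld_panel_snp: str  # marker absent from the LD proxy panel


def gen_snp_fixture(cfg: SnpConfig) -> tuple[dict[str, pd.DataFrame], SnpTruth]:
    """Generate the five GWAS-input tables and the planted truth.

    Returns a dict with keys ``snps``, ``gene_models``, ``elements``,
    ``ld_proxies``, ``eqtls`` and the ground truth.  Junk elements carrying
    every exclusion keyword are planted inside windows so the keyword filter
    is exercised.
    """
    from .gwas import EXCLUSION_KEYWORDS

    rng = np.random.default_rng(cfg.rng_seed)
    chrom = "1"
    snps = []
    positions = {}
    for i in range(cfg.n_snps):
        rsid = f"rs{1000 + i}"
        pos = cfg.block // 2 + i * cfg.block
        positions[rsid] = pos
        snps.append({"rsid": rsid, "chrom": chrom, "pos": pos})
    rsids = [s["rsid"] for s in snps]
    coding_rs = rsids[: cfg.n_coding]
    intronic_rs = rsids[cfg.n_coding : cfg.n_coding + cfg.n_intronic]
    intergenic_rs = rsids[cfg.n_coding + cfg.n_intronic :]
    noncoding_rs = intronic_rs + intergenic_rs

    models = []
    elements = []
    eqtls = []
    proxies = []

    # coding SNPs: host gene with an exon (or 3'UTR) containing the marker
    coding_genes = set()
    for i, rsid in enumerate(coding_rs):
        pos = positions[rsid]
        sym = f"CG{i + 1:02d}"
        coding_genes.add(sym)
        feature = "utr3" if i == 0 else "exon"
        models.append(
            {"symbol": sym, "chrom": chrom, "start": pos - 5000, "end": pos + 5000, "feature": "span"}
        )
        models.append(
            {"symbol": sym, "chrom": chrom, "start": pos - 100, "end": pos + 100, "feature": feature}
        )
        elements.append(
            {"symbol": sym, "name": "protein coding", "chrom": chrom,
             "start": pos - 5000, "end": pos + 5000}
        )

    # intronic SNPs: host ORF span covers the marker, exon elsewhere
    for i, rsid in enumerate(intronic_rs):
        pos = positions[rsid]
        sym = f"HOST{i + 1:02d}"
        models.append(
            {"symbol": sym, "chrom": chrom, "start": pos - 20_000, "end": pos + 20_000, "feature": "span"}
        )
        models.append(
            {"symbol": sym, "chrom": chrom, "start": pos + 10_000, "end": pos + 11_000, "feature": "exon"}
        )
        # the host is itself a candidate element within the PD window
        elements.append(
            {"symbol": sym, "name": "protein coding", "chrom": chrom,
             "start": pos - 20_000, "end": pos + 20_000}
        )

    # proximity-gene budget (prox-only + both) spread over noncoding SNPs.
    # Intronic hosts already contribute one proximity gene each.
    host_syms = [f"HOST{i + 1:02d}" for i in range(len(intronic_rs))]
    n_prox_needed = cfg.n_prox_only + cfg.n_both - len(host_syms)
    if n_prox_needed < 0:
        raise ValueError("intronic hosts exceed the proximity-gene budget")
    prox_syms = [f"PG{i + 1:03d}" for i in range(n_prox_needed)]
    owner = {}
    for i, sym in enumerate(prox_syms):
        rsid = noncoding_rs[i % len(noncoding_rs)]
        owner[sym] = rsid
        pos = positions[rsid]
        offset = int(rng.integers(-cfg.half_window + 30_000, cfg.half_window - 40_000))
        elements.append(
            {"symbol": sym, "name": "protein coding", "chrom": chrom,
             "start": pos + offset, "end": pos + offset + 10_000}
        )
    all_prox = host_syms + prox_syms
    for i, sym in enumerate(host_syms):
        owner[sym] = intronic_rs[i]

    # "both" genes additionally appear in the eQTL tables (last n_both)
    both = set(all_prox[-cfg.n_both :])
    for sym in sorted(both):
        rsid = owner[sym]
        eqtls.append({"rsid": rsid, "symbol": sym, "tissue": "skin_sun_exposed"})
        if rng.random() < 0.5:
            eqtls.append({"rsid": rsid, "symbol": sym, "tissue": "skin_not_sun_exposed"})
    prox_only = set(all_prox) - both

    # eQTL-only genes: no element anywhere near a window
    eqtl_only = set()
    for i in range(cfg.n_eqtl_only):
        sym = f"EQ{i + 1:02d}"
        eqtl_only.add(sym)
        rsid = noncoding_rs[-(i + 1)]
        eqtls.append({"rsid": rsid, "symbol": sym, "tissue": "skin_not_sun_exposed"})

    # LD proxies: half the noncoding markers get passing proxies; one marker
    # gets failing-only proxies; the last marker is absent from the panel
    no_panel = noncoding_rs[-1]
    for i, rsid in enumerate(noncoding_rs[:-1]):
        pos = positions[rsid]
        if i % 2 == 0:
            for j in range(2):
                proxies.append(
                    {"rsid": rsid, "proxy_rsid": f"{rsid}_p{j}",
                     "r2": round(float(rng.uniform(0.8, 1.0)), 3),
                     "proxy_pos": pos + (j + 1) * 15_000}
                )
        else:
            proxies.append(
                {"rsid": rsid, "proxy_rsid": f"{rsid}_p0",
                 "r2": round(float(rng.uniform(0.1, 0.79)), 3),
                 "proxy_pos": pos + 15_000}
            )

    # junk elements: one per exclusion keyword, planted inside windows
    for i, kw in enumerate(EXCLUSION_KEYWORDS):
        rsid = noncoding_rs[i % len(noncoding_rs)]
        pos = positions[rsid]
        elements.append(
            {"symbol": f"JUNK{i + 1:02d}", "name": f"some {kw} element",
             "chrom": chrom, "start": pos + 1000, "end": pos + 2000}
        )

    tables = {
        "snps": pd.DataFrame(snps, columns=["rsid", "chrom", "pos"]),
        "gene_models": pd.DataFrame(models, columns=["symbol", "chrom", "start", "end", "feature"]),
        "elements": pd.DataFrame(elements, columns=["symbol", "name", "chrom", "start", "end"]),
        "ld_proxies": pd.DataFrame(proxies, columns=["rsid", "proxy_rsid", "r2", "proxy_pos"]),
        "eqtls": pd.DataFrame(eqtls, columns=["rsid", "symbol", "tissue"]),
    }
    truth = SnpTruth(
        coding_snps=set(coding_rs),
        intronic_snps=set(intronic_rs),
        intergenic_snps=set(intergenic_rs),
        coding_genes=coding_genes,
        prox_only=prox_only,
        both=both,
        eqtl_only=eqtl_only,
        no_ld_panel_snp=no_panel,
    )
    return tables, truth
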