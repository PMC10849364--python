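# melanet

Network modeling of the melanoma genetic-risk landscape.

Cutaneous melanoma risk is spread over many genes: rare familial mutations,
recurrent somatic mutations, and dozens of common GWAS variants of small
effect. `melanet` implements an in-silico pipeline that treats these genes
as a single functional unit: it prioritizes candidate genes around GWAS risk
markers, merges them with familial and somatic gene lists into a seed list,
builds a seeded protein–protein interaction (PPI) model around them,
partitions the model into functional communities, and asks — with a
Monte-Carlo enrichment test — whether independent gene sets (disease
expression signatures, drug-response signatures) hit the model more often
than chance.

## The method

**Locus-to-gene prioritization.** Each risk SNP is classified as coding
(inside an exon/3′UTR of a coding ORF), intronic, or intergenic. Coding
markers map to their host gene. For each noncoding marker, candidate genes
are collected from three evidence routes: a physical-distance locus of
±250 kb, a linkage-disequilibrium locus spanning all proxies with
*r*² ≥ 0.8, and skin eQTL target genes (sun-exposed and non-sun-exposed).
Non-protein-coding elements (pseudogenes, lncRNAs, readthroughs, …) are
removed by a name-keyword filter.

**Seed network with bridges.** Seeds are the merged risk genes. The
*level-zero* network keeps direct seed–seed literature interactions after
QC (publication identifier present, detection method not
"unspecified"-only). The *level-one* network ("the model") first filters
interactions to high confidence (score ≥ 0.72), removes promiscuous
ubiquitin partners (UBB/UBC/UBD), then adds **bridges**: non-seed proteins
interacting with ≥ 2 seeds that are not directly connected to each other.
The largest connected component is the disease model.

**Clustering.** Agglomerative greedy modularity maximization (fast-greedy):
starting from singletons, repeatedly merge the community pair with the
largest Newman–Girvan modularity gain

    ΔQ(i, j) = e_ij / m − d_i d_j / (2 m²)

until no merge improves Q. Clusters pass QC when they have enough nodes and
a seed:bridge ratio ≥ 0.7.

**Overlap enrichment.** For a query gene set (e.g. the Bonferroni-significant
genes with |log2FC| > 2 in a tumor-vs-normal comparison, or the genes
differentially expressed after drug treatment), the observed overlap *k*
with the model is scored against `n_sims` random same-size gene lists drawn
uniformly without replacement from the universe:

    p = 1 − Φ((k − μ̂) / σ̂)

with μ̂, σ̂ the simulated null mean and SD (the upper-tail normal
convention of R's `pnorm(..., lower.tail = FALSE)`).

A synthetic-data module generates every input with planted ground truth
(interactome with true bridges and decoys, two-group 7-vs-45 expression
matrices with planted fold changes, DE tables with a planted model overlap,
GWAS fixtures with a designed evidence composition), so the whole pipeline
is testable offline.

## Worked example

```python
from melanet import synth, interactome, clustering, stats

# planted interactome at study magnitude (232 seeds)
records, truth = synth.gen_interactome(synth.InteractomeConfig(rng_seed=17))
hc = interactome.filter_high_confidence(records)           # score >= 0.72
g, report = interactome.build_level_one(set(truth.seeds), hc)
print(report["core"])
# {'n_nodes': 402, 'n_seeds': 194, 'n_bridges': 208}

core = interactome.largest_component(g)
part = clustering.greedy_modularity(core)
roles = {n: core.nodes[n]["role"] for n in core}
qc = clustering.qc_clusters(part, roles, min_nodes=10, min_ratio=0.7)
print(len(part.clusters), sum(r.passed_qc for r in qc))
# 12 10

# drug-treatment DE table with a planted 215/402 model overlap
de, _ = synth.gen_de_table(synth.DeConfig(rng_seed=17), sorted(core.nodes))
overlap, frac = stats.overlay_de(de, set(core.nodes), padj_max=0.05)
print(len(overlap), f"{100 * frac:.1f}%")
# 215 53.5%
```

The level-one model here contains 402 proteins — 194 of the 232 seeds plus
208 bridges — and 53.5% of it responds to the simulated treatment; the
Monte-Carlo test then tells you whether that fraction beats same-size random
gene lists.

A `melanet` CLI wraps each stage (`melanet prioritize`, `merge-seeds`,
`build-network`, `cluster`, `validate-expression`, `overlay-de`,
`simulate-overlap`, `group-terms`, `synth`, `run`); `melanet run --config
run.yaml` executes the whole pipeline and writes a manifest with input
digests and per-stage counts.

## Layout

- `melanet.gwas` — SNP classification, PD/LD loci, eQTL joins, prioritization
- `melanet.seeds` — three-source seed-list merging with Venn composition
- `melanet.interactome` — interaction QC, bridge discovery, network builds
- `melanet.clustering` — greedy modularity and cluster QC
- `melanet.stats` — Welch/Bonferroni/FC classes, Monte-Carlo overlap test,
  DE overlays, hypergeometric term enrichment
- `melanet.terms` — term filtering, keyword grouping, ontology components
- `melanet.synth` — synthetic-data generators with planted ground truth
- `melanet.pipeline`, `melanet.cli` — orchestration and command line

See `docs/methods.md` for modeling assumptions, parameter defaults and
limitations.
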