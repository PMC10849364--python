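# Methods

This note documents the models, conventions and numerical choices behind
`melanet`, and what the synthetic-data generators do and do not emulate.

## Coordinates and symbols

All genomic coordinates are 1-based with inclusive–inclusive intervals; two
intervals overlap when they share at least one base pair. Physical-distance
loci are clipped at position 1; no upper clipping is applied (no assembly
lengths are required). Gene symbols are uppercased and stripped of
surrounding whitespace before any set operation, since every join in the
pipeline is symbol-keyed. A gene encoding several proteins (e.g. CDKN2A) is
one node by construction.

## GWAS prioritization

A SNP is *coding* when it falls in an exon or 3′UTR interval of a coding
ORF, *intronic* when inside an ORF span but outside its exons, *intergenic*
otherwise. When overlapping ORFs both contain a coding SNP the marker is
attached to all of them (the tie rule is a declared convention).

The PD locus is ±`half_window` (default 250,000 bp). The LD locus spans the
tag SNP and all proxies with *r*² ≥ `r2_min` (default 0.8, inclusive). A
marker absent from the LD panel — operationalized as: no proxy rows
reference it — gets no LD locus and is annotated with PD only; a marker
whose proxies all fail the threshold gets the degenerate single-position
window. Markers inside a configurable HLA interval are likewise excluded
from LD annotation only, because LD structure there is too complex to
annotate reliably.

The element keyword filter is a case-insensitive substring match on the
element *name* over: nan, none, pseudogene, novel, antisense, microRNA,
IncRNA, lncRNA, small nucleolar RNA, yRNA, TEC, readthrough, intergenic,
intronic. Both the "IncRNA" spelling (capital I) and the intended "lncRNA"
are matched for robustness. The filter is idempotent.

## Network construction

Two QC regimes exist because the two downloads differ:

* level zero (seed–seed only): records must carry ≥ 1 PubMed id and ≥ 1
  detection method other than "unspecified" (case-insensitive);
  self-interactions are dropped.
* level one: records are filtered to confidence ≥ 0.72. The threshold is
  inclusive — 0.72 is the third-quartile score that defines "high
  confidence" — with a `strict_gt` switch to flip to exclusive. Records
  touching UBB/UBC/UBD are removed as unspecific, as are records with
  ambiguous Entrez mapping or nonstandard symbols (derived in the reader
  from multi-valued Entrez cells and UniProt-style names when explicit flag
  columns are absent).

A non-seed protein is a **bridge** iff among its seed neighbors at least
one pair lacks a direct interaction in the filtered set (the existential
reading: for a node touching ≥ 3 seeds, one unconnected pair suffices).
Level-one seed–seed edges come from the high-confidence set, not from the
manually QC'd level-zero set, since the confidence cut applies to the whole
level-one download. Bridge–bridge edges are excluded: the model describes
how risk proteins communicate, not the full first shell.

All graphs are simple and undirected; components are ranked by node count
with ties broken by the lexicographically smallest member, so outputs are
order-independent. Hubs are nodes with degree ≥ 14 (the degree range
observed for the most connected risk proteins), ranked by degree then name.

## Clustering

Fast-greedy agglomerative modularity maximization: from singleton
communities, repeatedly merge the connected pair with the largest

ΔQ(i, j) = e_ij/m − d_i·d_j/(2m²)

and stop when no merge has ΔQ > 0. Because m, e_ij and the degrees are
integers, candidate merges are compared on the exact integer numerator
2·m·e_ij − d_i·d_j; ties break on the lexicographic pair of community
representatives (smallest member). Partitions are therefore
bit-reproducible and invariant to node insertion order. The reported Q is
the Newman–Girvan modularity of the final partition, recomputed directly.
Isolated nodes become singletons; disconnected components never merge
(ΔQ > 0 requires at least one cross edge).

Cluster QC keeps communities with ≥ `min_nodes` nodes (default 10 — the
size criterion is part of the design but its published threshold is not
stated, so the default is explicit and configurable) and seed:bridge ratio
≥ 0.7. A cluster with no bridges is maximally seed-enriched and passes the
ratio (treated as +∞).

## Expression re-analysis and overlap enrichment

The two-group comparison (reference group vs case group, e.g. 7 normal-skin
vs 45 melanoma arrays) computes per gene: log2FC = log2 of the ratio of
linear-scale group means; Welch's unequal-variance t on log2-transformed
intensities; two-sided p. Significance is the strict Bonferroni rule
p < α/m. With m = 22,321 tests and α = 0.05 the threshold is 2.24 × 10⁻⁶.
Fold-change classes FC2/FC3/FC4 are assigned only to significant genes,
with strict thresholds on |log2FC| by default (`fc_scale="linear"` applies
them to the linear ratio instead; the published group definitions do not
disambiguate the scale, so both are implemented). Classes are nested by
construction. A degenerate gene (zero variance in both groups, equal means)
reports t = 0, p = 1.

The Monte-Carlo overlap test draws `n_sims` (default 100,000) gene lists of
the query's size uniformly without replacement from the universe
(vectorized as the smallest-k order statistics of random keys, in chunks),
records each list's overlap with the model, and reports
p = 1 − Φ((k − μ̂)/σ̂) with sample μ̂ and σ̂ (ddof 1), no continuity
correction. Draws are gene-label samples, not degree-preserving graph
nulls — matching the stated procedure. The default universe is all genes
measured in the experiment (the natural sampling frame); it is
configurable because the published universe is unstated. With σ̂ = 0 the p
degenerates to 0 (k > μ̂) or 1, with a warning.

Two accuracy caveats are inherent to this estimator and verified by the
test suite: the null overlap count is exactly hypergeometric, so μ̂ and σ̂
converge to the hypergeometric moments; but the *normal upper tail* is only
a good approximation of the exact tail in the moderate-significance regime
(within a factor of a few for z ≲ 3). Deep in the tail (z ≳ 5) the normal
p underestimates the exact hypergeometric tail by orders of magnitude —
both still call the result extremely significant, but the numerical value
should not be read as an exact tail probability.

The DE overlay is a plain filter-then-intersect: model genes with adjusted
p < 0.05 in the treatment table, reported as a count and fraction of the
model.

Term enrichment (`hypergeom_term_enrichment`) is offline plumbing — a
one-sided hypergeometric test with Benjamini–Hochberg adjustment — standing
where an enrichment server would be queried; the server's own multiple-
testing procedure is out of scope and its outputs are consumed as tables.

## Term post-processing

Term-size and intersection-size filters use a configurable comparator for
term size (< or ≤, both conventions occur in practice) and strictly remove
terms with intersection_size ≤ the cutoff. Keyword grouping assigns each
term to the *first* matching keyword of an ordered lexicon
(case-insensitive substring on the term name); the lexicon is data, not
code — reproducing a grouping requires the exact ordered lexicon, and a
small melanoma-flavored default ships for demonstrations. Top groups are
the largest classes (ties by smaller best adjusted p, then keyword) whose
cumulative percentage strictly exceeds the coverage target (default 50%).
Ontology components are connected components of the filtered terms under
parent–child relations given as a two-column table.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their configs (byte-identical outputs
per seed) and plant exactly recoverable truth:

* **Interactome** — a connected seed core, satellite seeds reachable only
  via bridges, pendant seed pairs, isolated seeds, true bridges wired to
  mutually unconnected seeds, decoys wired to connected pairs or single
  seeds, and QC chaff (sub-threshold confidences, missing PubMed ids,
  "unspecified"-only methods, ubiquitin partners, ambiguous/nonstandard
  records). All seed–seed records are planted and QC-clean, and noise
  records never join two seeds, so the planted level-zero and level-one
  censuses are exact. Default magnitudes mirror the study design
  (232 seeds; a 148-seed level-zero core; a 402-node model with 194 seeds
  and 208 bridges). What it does not emulate: the empirical degree
  distribution, study bias toward well-known proteins, and score–method
  correlations of a literature interactome.
* **Expression** — log-normal intensities, i.i.d. Gaussian noise on the
  log2 scale (sd 0.4, a typical gene-wise residual sd for array
  intensities), planted mean shifts in the case group, 7 vs 45 samples over
  22,321 genes by default (the family size implied by the 2.24 × 10⁻⁶
  Bonferroni cut). Under this design the Welch df is ≈ 8, so power at the
  family-wise cut is the binding constraint: planted 2.5-fold genes are
  recovered at ≥ 90% at the reduced scale used in the tests (3,000 genes),
  and at ~89% at the full family size. Not emulated: probe-level effects,
  normalization artifacts, correlated genes, variance–mean trends.
* **DE tables** — adjusted p placed so that exactly round(fraction·|model|)
  model genes are significant (default fraction 215/402), background genes
  significant at a configurable rate. Only the threshold-crossing structure
  is meaningful; p-value magnitudes are arbitrary.
* **GWAS fixture** — markers in disjoint 2-Mb blocks with designed category
  and evidence composition (10 coding / 44 noncoding; 108 proximity-only,
  25 proximity+eQTL, 2 eQTL-only = 135 candidates), junk elements carrying
  every exclusion keyword, a marker absent from the LD panel and markers
  with failing-only proxies.

Passing tests on these fixtures demonstrate that the pipeline's logic
(filters, set algebra, graph predicates, statistics) is correct and
deterministic; they do not certify performance on real interactome or
expression data, whose biases the generators deliberately do not model.

## Problem sizes and reproducibility

The test suite and the acceptance script run everything at the design
magnitudes above except where brute-force oracles bound the size (random
graphs ≤ 40 nodes for the bridge oracle, ≤ 7 nodes for the exhaustive
merge-tree search, 3,000-gene matrices for recovery runs, 2,000-simulation
nulls for the uniformity check over 500 repetitions). Every stochastic
operation takes an explicit RNG seed; pipeline runs write a manifest with
SHA-256 digests of all inputs and outputs, and identical config + inputs
reproduce identical bytes.

## Known limitations

* The model inherits literature ascertainment bias; hubs may reflect study
  frequency as much as biology (a caveat of the approach itself).
* The greedy modularity optimizer makes no optimality claim; it is the
  standard fast-greedy heuristic with a deterministic tie rule.
* The overlap null is a label-sampling null, not degree-aware; enrichment
  p-values deep in the tail are normal-approximation figures (see above).
* No liftover, no splicing QTLs, no bridge–bridge expansion (level ≥ 2),
  no re-scoring of interaction confidence.
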