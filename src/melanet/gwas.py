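"""GWAS locus-to-gene prioritization.

Risk markers from a melanoma GWAS are turned into a candidate-gene table in
four steps: (1) each SNP is classified as coding (inside an exon or 3'UTR of
a protein-coding ORF), intronic (inside an ORF span but outside its exons) or
intergenic; (2) a physical-distance (PD) locus of +/-250 kb and a linkage-
disequilibrium (LD) locus spanning all proxies with r^2 >= 0.8 are drawn
around each noncoding marker; (3) genomic elements overlapping the loci are
collected and non-protein-coding elements are removed by a name-keyword
filter; (4) skin eQTL target genes are joined per marker. Coding markers are
attached directly to their host gene.

Coordinates are 1-based and intervals inclusive on both ends; two intervals
overlap when they share at least one base pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SnpRecord",
    "Locus",
    "GenomicElement",
    "LdProxy",
    "EqtlRecord",
    "PrioritizedGene",
    "EXCLUSION_KEYWORDS",
    "EQTL_TISSUES",
    "normalize_symbol",
    "classify_snp",
    "build_pd_locus",
    "build_ld_locus",
    "map_elements_to_locus",
    "filter_coding_elements",
    "join_eqtl",
    "prioritize",
    "read_snps",
    "read_gene_models",
    "read_elements",
    "read_ld_proxies",
    "read_eqtls",
    "write_prioritized",
]

#: Name keywords marking non-protein-coding genomic elements.  Matching is a
#: case-insensitive substring test.  The published list contains "IncRNA"
#: (capital i); we match both that literal string and the intended "lncRNA".
EXCLUSION_KEYWORDS = (
    "nan",
    "none",
    "pseudogene",
    "novel",
    "antisense",
    "microrna",
    "incrna",
    "lncrna",
    "small nucleolar rna",
    "yrna",
    "tec",
    "readthrough",
    "intergenic",
    "intronic",
)

EQTL_TISSUES = frozenset({"skin_sun_exposed", "skin_not_sun_exposed"})

DEFAULT_HALF_WINDOW = 250_000
DEFAULT_R2_MIN = 0.8


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol before any set operation."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class SnpRecord:
    """A risk marker: dbSNP identifier and 1-based genomic position."""

    rsid: str
    chrom: str
    pos: int
    category: str | None = None  # assigned by classify_snp

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class Locus:
    """A genomic window drawn around a marker by the PD or LD method."""

    rsid: str
    chrom: str
    start: int
    end: int
    method: str  # "PD" | "LD"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.rsid}: malformed locus [{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class GenomicElement:
    """A genomic element (gene, pseudogene, ncRNA ...) with its name text."""

    symbol: str
    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: malformed interval")


@dataclass(frozen=True)
class LdProxy:
    rsid: str
    proxy_rsid: str
    r2: float
    proxy_pos: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise ValueError(f"{self.rsid}/{self.proxy_rsid}: r2={self.r2} outside [0, 1]")


@dataclass(frozen=True)
class EqtlRecord:
    rsid: str
    symbol: str
    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in EQTL_TISSUES:
            raise ValueError(f"unknown eQTL tissue {self.tissue!r}")


@dataclass
class PrioritizedGene:
    """A candidate gene with the evidence routes that implicated it."""

    symbol: str
    evidence: set[str] = field(default_factory=set)  # subset of {coding, PD, LD, eQTL}
    source_rsids: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# SNP classification

def classify_snp(snp: SnpRecord, gene_models: pd.DataFrame) -> str:
    """Classify a marker as ``coding``, ``intronic`` or ``intergenic``.

    ``gene_models`` holds one row per feature interval with columns
    (symbol, chrom, start, end, feature), feature in {exon, utr3, intron,
    span}.  A marker inside an exon or 3'UTR of a coding ORF is coding; one
    inside an ORF span but outside all its exons/UTRs is intronic; anything
    else is intergenic.
    """
    _check_intervals(gene_models)
    same_chrom = gene_models[gene_models["chrom"].astype(str) == str(snp.chrom)]
    inside = same_chrom[(same_chrom["start"] <= snp.pos) & (snp.pos <= same_chrom["end"])]
    if (inside["feature"].isin(("exon", "utr3"))).any():
        return "coding"
    if (inside["feature"] == "span").any():
        return "intronic"
    return "intergenic"


def host_genes(snp: SnpRecord, gene_models: pd.DataFrame) -> list[str]:
    """Genes whose exon/3'UTR contains the marker (all of them, if ORFs overlap)."""
    same_chrom = gene_models[gene_models["chrom"].astype(str) == str(snp.chrom)]
    hit = same_chrom[
        same_chrom["feature"].isin(("exon", "utr3"))
        & (same_chrom["start"] <= snp.pos)
        & (snp.pos <= same_chrom["end"])
    ]
    return sorted({normalize_symbol(s) for s in hit["symbol"]})


def _check_intervals(df: pd.DataFrame) -> None:
    bad = df[df["start"] > df["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"malformed interval for {row['symbol']}: [{row['start']}, {row['end']}]"
        )


# ---------------------------------------------------------------------------
# Locus construction

def build_pd_locus(snp: SnpRecord, half_window: int = DEFAULT_HALF_WINDOW) -> Locus:
    """Physical-distance locus: +/- ``half_window`` bp, clipped at position 1."""
    return Locus(
        rsid=snp.rsid,
        chrom=snp.chrom,
        start=max(1, snp.pos - half_window),
        end=snp.pos + half_window,
        method="PD",
    )


def build_ld_locus(
    snp: SnpRecord,
    proxies: list[LdProxy],
    r2_min: float = DEFAULT_R2_MIN,
) -> Locus | None:
    """LD locus spanning the marker and all proxies with r^2 >= ``r2_min``.

    Returns ``None`` when the marker is absent from the LD panel (no proxy
    rows reference it at all) — such markers are annotated with PD only.
    A marker present in the panel whose proxies all fail the threshold gets
    the degenerate single-position window [pos, pos].
    """
    mine = [p for p in proxies if p.rsid == snp.rsid]
    if not mine:
        return None
    positions = [snp.pos] + [p.proxy_pos for p in mine if p.r2 >= r2_min]
    return Locus(
        rsid=snp.rsid,
        chrom=snp.chrom,
        start=min(positions),
        end=max(positions),
        method="LD",
    )


def map_elements_to_locus(locus: Locus, elements: list[GenomicElement]) -> list[str]:
    """Symbols of elements overlapping the locus by >= 1 bp (same chromosome)."""
    out = {
        normalize_symbol(e.symbol)
        for e in elements
        if str(e.chrom) == str(locus.chrom)
        and e.start <= locus.end
        and locus.start <= e.end
    }
    return sorted(out)


def filter_coding_elements(elements: list[GenomicElement]) -> list[GenomicElement]:
    """Drop elements whose name contains any exclusion keyword (case-insensitive)."""
    kept = []
    for e in elements:
        name = e.name.lower()
        if any(k in name for k in EXCLUSION_KEYWORDS):
            continue
        if not normalize_symbol(e.symbol):
            continue
        kept.append(e)
    return kept


def join_eqtl(
    snps: list[SnpRecord], eqtls: list[EqtlRecord]
) -> dict[str, set[str]]:
    """Per-marker union of eQTL target genes over the two skin tissues.

    Only noncoding (intronic/intergenic) markers may be passed; coding
    markers are attached to their host gene directly and never enter the
    eQTL join.
    """
    for snp in snps:
        if snp.category == "coding":
            raise ValueError(f"{snp.rsid} is coding; eQTL join is for noncoding markers")
    rsids = {s.rsid for s in snps}
    out: dict[str, set[str]] = {s.rsid: set() for s in snps}
    for rec in eqtls:
        if rec.rsid in rsids:
            out[rec.rsid].add(normalize_symbol(rec.symbol))
    return out


# ---------------------------------------------------------------------------
# Full prioritization

def prioritize(
    snps: list[SnpRecord],
    gene_models: pd.DataFrame,
    elements: list[GenomicElement],
    proxies: list[LdProxy],
    eqtls: list[EqtlRecord],
    half_window: int = DEFAULT_HALF_WINDOW,
    r2_min: float = DEFAULT_R2_MIN,
    hla_region: tuple[str, int, int] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full locus-to-gene workflow over a marker table.

    Returns ``(table, summary)``.  ``table`` has one row per candidate gene
    with 0/1 evidence columns (coding, PD, LD, eQTL) and the markers that
    implicated it.  ``summary`` reports the SNP category census and, over the
    noncoding-derived ("prioritized") genes, the counts and percentages of
    the evidence combinations: eQTL plus proximity/LD, eQTL only, and
    proximity/LD only.

    Markers inside ``hla_region`` (chrom, start, end) are excluded from LD
    locus construction but still receive a PD locus, mirroring the treatment
    of markers in regions too complex to annotate for LD.
    """
    seen: dict[str, int] = {}
    for s in snps:
        seen[s.rsid] = seen.get(s.rsid, 0) + 1
    dups = [r for r, n in seen.items() if n > 1]
    if dups:
        raise ValueError(f"duplicate rsids in SNP table: {dups}")

    coding_elements = filter_coding_elements(elements)
    classified = [replace(s, category=classify_snp(s, gene_models)) for s in snps]
    noncoding = [s for s in classified if s.category != "coding"]
    eqtl_map = join_eqtl(noncoding, eqtls)

    genes: dict[str, PrioritizedGene] = {}

    def _add(symbol: str, evidence: str, rsid: str) -> None:
        g = genes.setdefault(symbol, PrioritizedGene(symbol))
        g.evidence.add(evidence)
        g.source_rsids.add(rsid)

    for snp in classified:
        if snp.category == "coding":
            for sym in host_genes(snp, gene_models):
                _add(sym, "coding", snp.rsid)
            continue
        pd_locus = build_pd_locus(snp, half_window)
        for sym in map_elements_to_locus(pd_locus, coding_elements):
            _add(sym, "PD", snp.rsid)
        in_hla = hla_region is not None and (
            str(snp.chrom) == str(hla_region[0])
            and hla_region[1] <= snp.pos <= hla_region[2]
        )
        if not in_hla:
            ld_locus = build_ld_locus(snp, proxies, r2_min)
            if ld_locus is not None:
                for sym in map_elements_to_locus(ld_locus, coding_elements):
                    _add(sym, "LD", snp.rsid)
        for sym in eqtl_map[snp.rsid]:
            _add(sym, "eQTL", snp.rsid)

    rows = []
    for sym in sorted(genes):
        g = genes[sym]
        rows.append(
            {
                "symbol": sym,
                "coding": int("coding" in g.evidence),
                "PD": int("PD" in g.evidence),
                "LD": int("LD" in g.evidence),
                "eQTL": int("eQTL" in g.evidence),
                "source_rsids": ";".join(sorted(g.source_rsids)),
            }
        )
    table = pd.DataFrame(
        rows, columns=["symbol", "coding", "PD", "LD", "eQTL", "source_rsids"]
    )

    # "prioritized" genes are the noncoding-derived ones: any PD/LD/eQTL
    # evidence.  A gene hit by both a coding SNP and a locus stays in the
    # coding count only.
    is_coding_gene = table["coding"] == 1 if len(table) else pd.Series(dtype=bool)
    prio = table[~is_coding_gene] if len(table) else table
    prox = (prio["PD"] == 1) | (prio["LD"] == 1) if len(prio) else pd.Series(dtype=bool)
    has_eqtl = prio["eQTL"] == 1 if len(prio) else pd.Series(dtype=bool)
    n_prio = int(len(prio))
    n_both = int((has_eqtl & prox).sum())
    n_eqtl_only = int((has_eqtl & ~prox).sum())
    n_prox_only = int((~has_eqtl & prox).sum())

    def _pct(k: int) -> float:
        return 100.0 * k / n_prio if n_prio else 0.0

    summary = {
        "n_snps": len(classified),
        "n_coding_snps": sum(s.category == "coding" for s in classified),
        "n_noncoding_snps": sum(s.category != "coding" for s in classified),
        "snp_categories": {
            c: sum(s.category == c for s in classified)
            for c in ("coding", "intronic", "intergenic")
        },
        "n_coding_genes": int(is_coding_gene.sum()) if len(table) else 0,
        "n_prioritized_genes": n_prio,
        "eqtl_and_proximity": n_both,
        "eqtl_only": n_eqtl_only,
        "proximity_only": n_prox_only,
        "pct_eqtl_and_proximity": _pct(n_both),
        "pct_eqtl_only": _pct(n_eqtl_only),
        "pct_proximity_only": _pct(n_prox_only),
    }
    return table, summary


# ---------------------------------------------------------------------------
# TSV interfaces

def read_snps(path) -> list[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    return [
        SnpRecord(rsid=r.rsid, chrom=r.chrom, pos=int(r.pos))
        for r in df.itertuples(index=False)
    ]


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str, "feature": str})
    required = {"symbol", "chrom", "start", "end", "feature"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-model table missing columns: {sorted(missing)}")
    return df


def read_elements(path) -> list[GenomicElement]:
    df = pd.read_csv(
        path, sep="\t", dtype={"symbol": str, "name": str, "chrom": str},
        keep_default_na=False,
    )
    return [
        GenomicElement(r.symbol, r.name, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_ld_proxies(path) -> list[LdProxy]:
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "proxy_rsid": str})
    return [
        LdProxy(r.rsid, r.proxy_rsid, float(r.r2), int(r.proxy_pos))
        for r in df.itertuples(index=False)
    ]


def read_eqtls(path) -> list[EqtlRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [EqtlRecord(r.rsid, r.symbol, r.tissue) for r in df.itertuples(index=False)]


def write_prioritized(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
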