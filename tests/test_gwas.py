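"""Locus construction, SNP classification and candidate-gene prioritization."""

import numpy as np
import pandas as pd
import pytest

from melanet import gwas
from melanet.gwas import (
    EqtlRecord,
    GenomicElement,
    LdProxy,
    Locus,
    SnpRecord,
    build_ld_locus,
    build_pd_locus,
    classify_snp,
    filter_coding_elements,
    join_eqtl,
    map_elements_to_locus,
    prioritize,
)

GENE_MODELS = pd.DataFrame(
    [
        {"symbol": "G", "chrom": "1", "start": 100, "end": 1000, "feature": "span"},
        {"symbol": "G", "chrom": "1", "start": 100, "end": 200, "feature": "exon"},
        {"symbol": "G", "chrom": "1", "start": 900, "end": 950, "feature": "utr3"},
    ]
)


@pytest.mark.parametrize(
    "pos, expected",
    [
        (150, "coding"),     # inside exon
        (920, "coding"),     # inside 3'UTR
        (500, "intronic"),   # inside ORF span, outside exons
        (5000, "intergenic"),
    ],
)
def test_classify_snp(pos, expected):
    assert classify_snp(SnpRecord("rs1", "1", pos), GENE_MODELS) == expected


def test_classify_snp_other_chromosome_is_intergenic():
    assert classify_snp(SnpRecord("rs1", "2", 150), GENE_MODELS) == "intergenic"


def test_classify_snp_rejects_malformed_interval():
    bad = pd.DataFrame(
        [{"symbol": "B", "chrom": "1", "start": 10, "end": 5, "feature": "exon"}]
    )
    with pytest.raises(ValueError, match="malformed"):
        classify_snp(SnpRecord("rs1", "1", 7), bad)


@pytest.mark.parametrize(
    "pos, half, expected",
    [
        (300_000, 250_000, (50_000, 550_000)),
        (100_000, 250_000, (1, 350_000)),  # clipped at chromosome start
        (7, 0, (7, 7)),
    ],
)
def test_build_pd_locus(pos, half, expected):
    locus = build_pd_locus(SnpRecord("rs1", "1", pos), half)
    assert (locus.start, locus.end) == expected
    assert locus.method == "PD"


def test_pd_locus_constant_width_except_clipping():
    for pos in (260_000, 500_000, 10_000_000):
        locus = build_pd_locus(SnpRecord("rs1", "1", pos), 250_000)
        assert locus.end - locus.start == 500_000


def test_build_ld_locus_marker_only_window():
    proxies = [LdProxy("rs1", "p1", 0.5, 90_000)]
    locus = build_ld_locus(SnpRecord("rs1", "1", 100_000), proxies)
    assert (locus.start, locus.end) == (100_000, 100_000)


def test_build_ld_locus_spans_passing_proxies_and_contains_tag():
    proxies = [
        LdProxy("rs1", "p1", 0.9, 90_000),
        LdProxy("rs1", "p2", 0.9, 130_000),
        LdProxy("rs1", "p3", 0.2, 999_999),
    ]
    locus = build_ld_locus(SnpRecord("rs1", "1", 100_000), proxies)
    assert (locus.start, locus.end) == (90_000, 130_000)
    assert locus.start <= 100_000 <= locus.end


def test_build_ld_locus_r2_threshold_is_inclusive():
    proxies = [LdProxy("rs1", "p1", 0.8, 150_000)]
    locus = build_ld_locus(SnpRecord("rs1", "1", 100_000), proxies)
    assert locus.end == 150_000


def test_build_ld_locus_absent_from_panel():
    assert build_ld_locus(SnpRecord("rs1", "1", 100_000), []) is None


def test_ld_proxy_rejects_bad_r2():
    with pytest.raises(ValueError, match="r2"):
        LdProxy("rs1", "p1", 1.2, 5)


@pytest.mark.parametrize(
    "interval, included",
    [
        ((600, 700), False),
        ((500, 700), True),   # 1-bp touch
        ((50, 800), True),    # spans the whole locus
    ],
)
def test_map_elements_to_locus(interval, included):
    locus = Locus("rs1", "1", 100, 500, "PD")
    element = GenomicElement("X", "protein coding", "1", *interval)
    got = map_elements_to_locus(locus, [element])
    assert ("X" in got) == included


def test_map_elements_ignores_other_chromosomes():
    locus = Locus("rs1", "1", 100, 500, "PD")
    element = GenomicElement("X", "protein coding", "2", 100, 500)
    assert map_elements_to_locus(locus, [element]) == []


def test_filter_coding_elements_removes_keyword_names():
    elements = [
        GenomicElement("A", "ABCD1 pseudogene 2", "1", 1, 10),
        GenomicElement("TP53", "tumor protein p53", "1", 1, 10),
        GenomicElement("B", "novel transcript", "1", 1, 10),
        GenomicElement("C", "IncRNA something", "1", 1, 10),
        GenomicElement("D", "lncRNA thing", "1", 1, 10),
    ]
    kept = filter_coding_elements(elements)
    assert [e.symbol for e in kept] == ["TP53"]


def test_filter_coding_elements_idempotent_and_keyword_free():
    elements = [
        GenomicElement(f"E{i}", name, "1", 1, 10)
        for i, name in enumerate(
            ["protein coding", "yRNA cluster", "readthrough x", "good gene", "TEC stub"]
        )
    ]
    once = filter_coding_elements(elements)
    assert filter_coding_elements(once) == once
    for e in once:
        assert not any(k in e.name.lower() for k in gwas.EXCLUSION_KEYWORDS)


def test_join_eqtl_unions_tissues():
    snps = [SnpRecord("rs1", "1", 100, category="intronic")]
    eqtls = [
        EqtlRecord("rs1", "A", "skin_sun_exposed"),
        EqtlRecord("rs1", "A", "skin_not_sun_exposed"),
        EqtlRecord("rs1", "B", "skin_not_sun_exposed"),
        EqtlRecord("rs2", "C", "skin_sun_exposed"),  # other marker, ignored
    ]
    assert join_eqtl(snps, eqtls) == {"rs1": {"A", "B"}}


def test_join_eqtl_rejects_coding_marker():
    with pytest.raises(ValueError, match="coding"):
        join_eqtl([SnpRecord("rs1", "1", 100, category="coding")], [])


def test_join_eqtl_empty_table():
    snps = [SnpRecord("rs1", "1", 100, category="intergenic")]
    assert join_eqtl(snps, []) == {"rs1": set()}


def _brute_force_evidence(snps, gene_models, elements, proxies, eqtls, half, r2_min):
    """Independent set-algebra oracle: per-marker gene sets, then union."""
    coding_elems = filter_coding_elements(elements)
    evidence: dict[str, set[str]] = {}
    rsids: dict[str, set[str]] = {}

    def mark(sym, ev, rsid):
        evidence.setdefault(sym, set()).add(ev)
        rsids.setdefault(sym, set()).add(rsid)

    for snp in snps:
        cat = classify_snp(snp, gene_models)
        if cat == "coding":
            for sym in gwas.host_genes(snp, gene_models):
                mark(sym, "coding", snp.rsid)
            continue
        pd_genes = {
            gwas.normalize_symbol(e.symbol)
            for e in coding_elems
            if str(e.chrom) == str(snp.chrom)
            and e.start <= snp.pos + half
            and max(1, snp.pos - half) <= e.end
        }
        for sym in pd_genes:
            mark(sym, "PD", snp.rsid)
        mine = [p for p in proxies if p.rsid == snp.rsid]
        if mine:
            pos = [snp.pos] + [p.proxy_pos for p in mine if p.r2 >= r2_min]
            lo, hi = min(pos), max(pos)
            for e in coding_elems:
                if str(e.chrom) == str(snp.chrom) and e.start <= hi and lo <= e.end:
                    mark(gwas.normalize_symbol(e.symbol), "LD", snp.rsid)
        for rec in eqtls:
            if rec.rsid == snp.rsid:
                mark(gwas.normalize_symbol(rec.symbol), "eQTL", snp.rsid)
    return evidence, rsids


def test_prioritize_matches_set_algebra_oracle():
    rng = np.random.default_rng(11)
    snps = [
        SnpRecord(f"rs{i}", "1", int(rng.integers(1, 5_000_000))) for i in range(12)
    ]
    gene_models = pd.DataFrame(
        [
            {"symbol": "HOSTA", "chrom": "1", "start": 1, "end": 2_000_000, "feature": "span"},
            {"symbol": "HOSTA", "chrom": "1", "start": 10, "end": 20, "feature": "exon"},
        ]
    )
    elements = [
        GenomicElement(
            f"EL{i}",
            "protein coding" if i % 4 else "pseudogene x",
            "1",
            int(start := rng.integers(1, 5_000_000)),
            int(start + rng.integers(1, 50_000)),
        )
        for i in range(40)
    ]
    proxies = [
        LdProxy(f"rs{int(rng.integers(0, 12))}", f"p{i}",
                float(rng.uniform(0.5, 1.0)), int(rng.integers(1, 5_000_000)))
        for i in range(30)
    ]
    eqtls = [
        EqtlRecord(f"rs{int(rng.integers(0, 12))}", f"EL{int(rng.integers(0, 40))}",
                   "skin_sun_exposed")
        for _ in range(15)
    ]
    # oracle needs the eQTL join restricted to noncoding markers, same as prioritize
    noncoding = [s for s in snps if classify_snp(s, gene_models) != "coding"]
    noncoding_ids = {s.rsid for s in noncoding}
    eqtls_nc = [e for e in eqtls if e.rsid in noncoding_ids]

    table, summary = prioritize(snps, gene_models, elements, proxies, eqtls_nc)
    expected_ev, expected_rs = _brute_force_evidence(
        snps, gene_models, elements, proxies, eqtls_nc, 250_000, 0.8
    )
    assert set(table["symbol"]) == set(expected_ev)
    for row in table.itertuples(index=False):
        flags = {f for f in ("coding", "PD", "LD", "eQTL") if getattr(row, f)}
        assert flags == expected_ev[row.symbol]
        assert set(row.source_rsids.split(";")) == expected_rs[row.symbol]
    # every gene traces to at least one marker
    assert (table["source_rsids"].str.len() > 0).all()


def test_prioritize_single_coding_snp():
    snps = [SnpRecord("rs1", "1", 150)]
    table, summary = prioritize(snps, GENE_MODELS, [], [], [])
    assert list(table["symbol"]) == ["G"]
    assert table.iloc[0]["coding"] == 1
    assert summary["n_prioritized_genes"] == 0
    assert summary["n_coding_genes"] == 1


def test_prioritize_rejects_duplicate_rsids():
    snps = [SnpRecord("rs1", "1", 150), SnpRecord("rs1", "1", 200)]
    with pytest.raises(ValueError, match="duplicate"):
        prioritize(snps, GENE_MODELS, [], [], [])


def test_prioritize_hla_marker_gets_pd_only():
    snp = SnpRecord("rs9", "6", 30_000_000)
    elements = [GenomicElement("FAR", "protein coding", "6", 40_000_000, 40_000_100)]
    proxies = [LdProxy("rs9", "p", 0.95, 40_000_050)]  # would reach FAR via LD
    empty_models = pd.DataFrame(columns=["symbol", "chrom", "start", "end", "feature"])
    with_hla, _ = prioritize(
        [snp], empty_models, elements, proxies, [],
        hla_region=("6", 28_000_000, 34_000_000),
    )
    without_hla, _ = prioritize([snp], empty_models, elements, proxies, [])
    assert "FAR" not in set(with_hla["symbol"])
    assert "FAR" in set(without_hla["symbol"])


def test_tsv_round_trips(tmp_path, snp_fixture):
    tables, _ = snp_fixture
    paths = {}
    for name, df in tables.items():
        p = tmp_path / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    snps = gwas.read_snps(paths["snps"])
    assert len(snps) == len(tables["snps"])
    elements = gwas.read_elements(paths["elements"])
    assert len(elements) == len(tables["elements"])
    proxies = gwas.read_ld_proxies(paths["ld_proxies"])
    assert len(proxies) == len(tables["ld_proxies"])
    eqtls = gwas.read_eqtls(paths["eqtls"])
    assert len(eqtls) == len(tables["eqtls"])
    models = gwas.read_gene_models(paths["gene_models"])
    assert set(models.columns) >= {"symbol", "chrom", "start", "end", "feature"}
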