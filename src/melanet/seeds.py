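"""Seed-list assembly: merging GWAS, familial and somatic melanoma gene lists.

The three provenance routes for melanoma risk genes — GWAS locus
prioritization, familial (germline) mutation curation, and somatic-mutation
catalogues — produce overlapping gene lists.  They are merged into a single
table of unique risk genes ("seeds" for the network stage), each carrying
per-source flags, together with the Venn composition: how many genes came
from exactly one, two, or all three lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .gwas import normalize_symbol

log = logging.getLogger(__name__)

SOURCES = ("GWAS", "familial", "somatic")

__all__ = ["SeedTable", "merge_seed_lists", "read_gene_list", "read_seed_table", "write_seed_table"]


@dataclass
class SeedTable:
    """Unique risk genes with 0/1 source columns and Venn composition counts."""

    table: pd.DataFrame  # columns: symbol, GWAS, familial, somatic
    composition: dict[int, int]  # {1: n_single, 2: n_double, 3: n_triple}

    @property
    def symbols(self) -> set[str]:
        return set(self.table["symbol"])

    def __len__(self) -> int:
        return len(self.table)


def _normalize_list(symbols, source: str) -> set[str]:
    out: set[str] = set()
    for s in symbols:
        sym = normalize_symbol(s)
        if not sym:
            continue
        if sym in out:
            log.warning("duplicate symbol %s in %s list collapsed", sym, source)
        out.add(sym)
    return out


def merge_seed_lists(gwas, familial, somatic) -> SeedTable:
    """Merge the three source lists into the unique risk-gene table.

    Duplicates within one list collapse (with a logged warning); membership
    is conserved: the sum over genes of their source counts equals the sum
    of the deduplicated list sizes.
    """
    lists = {
        "GWAS": _normalize_list(gwas, "GWAS"),
        "familial": _normalize_list(familial, "familial"),
        "somatic": _normalize_list(somatic, "somatic"),
    }
    union = set().union(*lists.values())
    if not union:
        raise ValueError("all three seed lists are empty")
    rows = []
    for sym in sorted(union):
        flags = {src: int(sym in lists[src]) for src in SOURCES}
        rows.append({"symbol": sym, **flags})
    table = pd.DataFrame(rows, columns=["symbol", *SOURCES])
    n_sources = table[list(SOURCES)].sum(axis=1)
    composition = {k: int((n_sources == k).sum()) for k in (1, 2, 3)}
    return SeedTable(table=table, composition=composition)


def read_gene_list(path) -> list[str]:
    """One symbol per line; '#' starts a comment; blank lines ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


def write_seed_table(seed_table: SeedTable, path) -> None:
    seed_table.table.to_csv(path, sep="\t", index=False)


def read_seed_table(path) -> SeedTable:
    """Read a seed TSV back, re-validating uniqueness and nonempty sources."""
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str})
    missing = {"symbol", *SOURCES} - set(df.columns)
    if missing:
        raise ValueError(f"seed table missing columns: {sorted(missing)}")
    if df["symbol"].duplicated().any():
        dup = df.loc[df["symbol"].duplicated(), "symbol"].tolist()
        raise ValueError(f"duplicate symbols in seed table: {dup}")
    n_sources = df[list(SOURCES)].sum(axis=1)
    if (n_sources == 0).any():
        bad = df.loc[n_sources == 0, "symbol"].tolist()
        raise ValueError(f"seed rows with no source flag: {bad}")
    composition = {k: int((n_sources == k).sum()) for k in (1, 2, 3)}
    return SeedTable(table=df, composition=composition)
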