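"""Seed-and-bridge protein-protein interaction network construction.

Two networks are built from a literature PPI table (HIPPIE-style dialect):

* the **level-zero** network — direct interactions among the risk proteins
  (seeds) only, after manual-style QC (publication identifier present,
  detection method not "unspecified"-only, self-interactions removed);
* the **level-one** network (the disease "model") — seeds plus **bridges**:
  non-seed proteins that interact with at least two seeds which are not
  themselves directly connected.  Level-one interactions are pre-filtered to
  high confidence (score >= 0.72, the third quartile of the HIPPIE score
  distribution), interactions touching the promiscuous ubiquitin partners
  UBB/UBC/UBD are dropped, as are records with ambiguous Entrez mapping or
  nonstandard symbols.

All graphs are simple and undirected; node roles are tagged ``seed`` or
``bridge``.  The largest connected component of either network is its
"core".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import pandas as pd

from .gwas import normalize_symbol

__all__ = [
    "Interaction",
    "read_interactions",
    "write_interactions",
    "qc_level_zero",
    "filter_high_confidence",
    "find_bridges",
    "build_level_zero",
    "build_level_one",
    "component_report",
    "largest_component",
    "hub_nodes",
    "write_network",
    "read_network",
    "DEFAULT_CONFIDENCE",
    "DEFAULT_EXCLUDED_PARTNERS",
]

DEFAULT_CONFIDENCE = 0.72
DEFAULT_EXCLUDED_PARTNERS = frozenset({"UBB", "UBC", "UBD"})
UNSPECIFIED = "unspecified"

_STANDARD_SYMBOL = re.compile(r"^[A-Z0-9][A-Z0-9\-\.]*$")


@dataclass(frozen=True)
class Interaction:
    """One literature PPI record; pair identity is unordered."""

    symbol_a: str
    symbol_b: str
    confidence: float
    pubmed_ids: tuple[str, ...] = ()
    detection_methods: tuple[str, ...] = ()
    ambiguous_mapping: bool = False
    nonstandard_symbol: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"{self.symbol_a}-{self.symbol_b}: confidence {self.confidence} outside [0, 1]"
            )

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.symbol_a, self.symbol_b))

    def is_self(self) -> bool:
        return self.symbol_a == self.symbol_b


def _split(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(p.strip() for p in text.split(";") if p.strip())


def _nonstandard(symbol: str) -> bool:
    return (not symbol) or symbol.endswith("_HUMAN") or not _STANDARD_SYMBOL.match(symbol)


def read_interactions(path) -> list[Interaction]:
    """Read the canonical interaction TSV.

    Mandatory columns: symbol_a, symbol_b, confidence.  Optional: entrez_a,
    entrez_b, detection_methods, pubmed_ids (';'-joined; empty cells are
    empty lists), and explicit 0/1 ambiguous_mapping / nonstandard_symbol
    columns.  When the explicit flag columns are absent the flags are
    derived: ambiguous mapping from multi-valued Entrez cells, nonstandard
    symbol from empty or UniProt-style ("*_HUMAN") names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"symbol_a", "symbol_b", "confidence"} - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    records = []
    for r in df.itertuples(index=False):
        row = r._asdict()
        a = normalize_symbol(row["symbol_a"])
        b = normalize_symbol(row["symbol_b"])
        try:
            conf = float(row["confidence"])
        except ValueError as exc:
            raise ValueError(f"unparsable confidence {row['confidence']!r}") from exc
        if "ambiguous_mapping" in row:
            ambiguous = bool(int(row["ambiguous_mapping"] or 0))
        else:
            ambiguous = any(
                len(_split(row.get(c, ""))) > 1 for c in ("entrez_a", "entrez_b")
            )
        if "nonstandard_symbol" in row:
            nonstd = bool(int(row["nonstandard_symbol"] or 0))
        else:
            nonstd = _nonstandard(a) or _nonstandard(b)
        records.append(
            Interaction(
                symbol_a=a,
                symbol_b=b,
                confidence=conf,
                pubmed_ids=_split(row.get("pubmed_ids", "")),
                detection_methods=_split(row.get("detection_methods", "")),
                ambiguous_mapping=ambiguous,
                nonstandard_symbol=nonstd,
            )
        )
    return records


def write_interactions(records: list[Interaction], path) -> None:
    rows = [
        {
            "symbol_a": r.symbol_a,
            "symbol_b": r.symbol_b,
            "confidence": r.confidence,
            "detection_methods": ";".join(r.detection_methods),
            "pubmed_ids": ";".join(r.pubmed_ids),
            "ambiguous_mapping": int(r.ambiguous_mapping),
            "nonstandard_symbol": int(r.nonstandard_symbol),
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "symbol_a", "symbol_b", "confidence", "detection_methods",
            "pubmed_ids", "ambiguous_mapping", "nonstandard_symbol",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC filters

def qc_level_zero(interactions: list[Interaction]) -> list[Interaction]:
    """Manual-style QC for the level-zero download.

    Keeps records with at least one PubMed identifier AND at least one
    detection method other than "unspecified" (case-insensitive); removes
    self-interactions.
    """
    kept = []
    for rec in interactions:
        if rec.is_self():
            continue
        if not rec.pubmed_ids:
            continue
        methods = {m.lower() for m in rec.detection_methods}
        if not (methods - {UNSPECIFIED}):
            continue
        kept.append(rec)
    return kept


def filter_high_confidence(
    interactions: list[Interaction],
    threshold: float = DEFAULT_CONFIDENCE,
    excluded_partners: frozenset[str] = DEFAULT_EXCLUDED_PARTNERS,
    strict_gt: bool = False,
) -> list[Interaction]:
    """High-confidence filter for the level-one download.

    Keeps records with confidence >= ``threshold`` (strictly > when
    ``strict_gt``); removes self-interactions, records touching an excluded
    (promiscuous) partner, and records flagged as ambiguously mapped or
    carrying a nonstandard symbol.
    """
    excluded = {normalize_symbol(s) for s in excluded_partners}
    kept = []
    for rec in interactions:
        if rec.is_self():
            continue
        if rec.confidence < threshold or (strict_gt and rec.confidence == threshold):
            continue
        if rec.symbol_a in excluded or rec.symbol_b in excluded:
            continue
        if rec.ambiguous_mapping or rec.nonstandard_symbol:
            continue
        kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# Network construction

def _edge_set(interactions: list[Interaction]) -> set[frozenset[str]]:
    return {rec.pair for rec in interactions if not rec.is_self()}


def build_level_zero(
    seed_symbols: set[str], interactions: list[Interaction]
) -> tuple[nx.Graph, dict]:
    """Seed-only graph from QC'd interactions, plus a component report.

    The graph holds every seed that appears in at least one seed-seed edge;
    the report lists components by size (largest = "core-level-zero") and
    the seeds with no seed-seed interaction ("isolated").
    """
    seeds = {normalize_symbol(s) for s in seed_symbols}
    g = nx.Graph()
    for pair in sorted(_edge_set(interactions), key=sorted):
        a, b = sorted(pair)
        if a in seeds and b in seeds:
            g.add_edge(a, b)
    nx.set_node_attributes(g, "seed", "role")
    report = component_report(g)
    report["isolated_seeds"] = sorted(seeds - set(g.nodes))
    return g, report


def find_bridges(
    seed_symbols: set[str], interactions: list[Interaction]
) -> set[str]:
    """Bridge interactors in a high-confidence-filtered interaction set.

    A non-seed node X is a bridge iff among its seed neighbors there is at
    least one pair (s1, s2) with no direct s1-s2 interaction.  (For nodes
    touching three or more seeds, one unconnected pair suffices.)
    """
    seeds = {normalize_symbol(s) for s in seed_symbols}
    edges = _edge_set(interactions)
    neighbors: dict[str, set[str]] = {}
    for pair in edges:
        a, b = tuple(pair)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    bridges = set()
    for node, nbrs in neighbors.items():
        if node in seeds:
            continue
        seed_nbrs = sorted(nbrs & seeds)
        if len(seed_nbrs) < 2:
            continue
        for s1, s2 in combinations(seed_nbrs, 2):
            if frozenset((s1, s2)) not in edges:
                bridges.add(node)
                break
    return bridges


def build_level_one(
    seed_symbols: set[str], interactions: list[Interaction]
) -> tuple[nx.Graph, dict]:
    """Level-one ("model") graph: seed-seed edges plus seed-bridge edges.

    Bridge-bridge edges are excluded by construction.  Returns the graph
    (roles tagged on nodes) and a component report whose largest component
    is the core-first-level network.
    """
    seeds = {normalize_symbol(s) for s in seed_symbols}
    bridges = find_bridges(seeds, interactions)
    g = nx.Graph()
    for pair in sorted(_edge_set(interactions), key=sorted):
        a, b = sorted(pair)
        if a in seeds and b in seeds:
            g.add_edge(a, b)
        elif (a in seeds and b in bridges) or (b in seeds and a in bridges):
            g.add_edge(a, b)
    for node in g.nodes:
        g.nodes[node]["role"] = "seed" if node in seeds else "bridge"
    report = component_report(g)
    report["isolated_seeds"] = sorted(seeds - set(g.nodes))
    core = largest_component(g)
    report["core"] = {
        "n_nodes": core.number_of_nodes(),
        "n_seeds": sum(1 for n in core if core.nodes[n]["role"] == "seed"),
        "n_bridges": sum(1 for n in core if core.nodes[n]["role"] == "bridge"),
    }
    return g, report


def component_report(g: nx.Graph) -> dict:
    """Connected components sorted by size (desc), ties by smallest member."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return {
        "n_components": len(comps),
        "components": comps,
        "component_sizes": [len(c) for c in comps],
    }


def largest_component(g: nx.Graph) -> nx.Graph:
    """Copy of the largest connected component (ties: smallest first member)."""
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return g.subgraph(comps[0]).copy()


def hub_nodes(g: nx.Graph, min_degree: int = 14) -> list[tuple[str, int]]:
    """Nodes with degree >= ``min_degree``, descending degree, ties lexicographic."""
    hubs = [(n, d) for n, d in g.degree() if d >= min_degree]
    return sorted(hubs, key=lambda nd: (-nd[1], nd[0]))


# ---------------------------------------------------------------------------
# Graph serialization (edge-list + node-attribute TSVs; optional GraphML)

def write_network(g: nx.Graph, edge_path, node_path=None, graphml_path=None) -> None:
    rows = [
        {
            "node_a": a,
            "node_b": b,
            "role_a": g.nodes[a].get("role", ""),
            "role_b": g.nodes[b].get("role", ""),
        }
        for a, b in sorted(tuple(sorted(e)) for e in g.edges)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "role_a", "role_b"]).to_csv(
        edge_path, sep="\t", index=False
    )
    if node_path is not None:
        nrows = [
            {"node": n, "role": g.nodes[n].get("role", ""), "degree": d}
            for n, d in sorted(g.degree())
        ]
        pd.DataFrame(nrows, columns=["node", "role", "degree"]).to_csv(
            node_path, sep="\t", index=False
        )
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)


def read_network(edge_path) -> nx.Graph:
    df = pd.read_csv(edge_path, sep="\t", dtype=str, keep_default_na=False)
    g = nx.Graph()
    for r in df.itertuples(index=False):
        g.add_edge(r.node_a, r.node_b)
        if r.role_a:
            g.nodes[r.node_a]["role"] = r.role_a
        if r.role_b:
            g.nodes[r.node_b]["role"] = r.role_b
    return g
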