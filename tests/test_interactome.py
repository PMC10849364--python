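"""Interaction QC, bridge discovery and network construction."""

from itertools import combinations

import numpy as np
import pytest

from melanet.interactome import (
    Interaction,
    build_level_one,
    build_level_zero,
    filter_high_confidence,
    find_bridges,
    hub_nodes,
    largest_component,
    qc_level_zero,
    read_interactions,
    read_network,
    write_interactions,
    write_network,
)


def rec(a, b, conf=0.9, pmids=("123",), methods=("two hybrid",), **kw):
    return Interaction(a, b, conf, pmids, methods, **kw)


# ---------------------------------------------------------------------------
# I/O

def test_read_interactions_round_trip(tmp_path):
    records = [
        rec("A", "B"),
        rec("C", "D", pmids=(), methods=()),
        rec("E", "F", ambiguous_mapping=True),
    ]
    path = tmp_path / "ppi.tsv"
    write_interactions(records, path)
    back = read_interactions(path)
    assert len(back) == 3
    assert back[1].pubmed_ids == () and back[1].detection_methods == ()
    assert back[2].ambiguous_mapping


def test_read_interactions_derives_flags(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text(
        "symbol_a\tentrez_a\tsymbol_b\tentrez_b\tconfidence\tdetection_methods\tpubmed_ids\n"
        "TP53\t7157\tBRCA1\t672;999\t0.9\ttwo hybrid\t123\n"
        "TP53\t7157\tXYZ_HUMAN\t1\t0.9\ttwo hybrid\t123\n"
    )
    back = read_interactions(path)
    assert back[0].ambiguous_mapping and not back[0].nonstandard_symbol
    assert back[1].nonstandard_symbol and not back[1].ambiguous_mapping


def test_read_interactions_rejects_bad_confidence(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("symbol_a\tsymbol_b\tconfidence\nA\tB\t1.2\n")
    with pytest.raises(ValueError, match="confidence"):
        read_interactions(path)


def test_read_interactions_rejects_missing_columns(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text("symbol_a\tsymbol_b\nA\tB\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_interactions(path)


# ---------------------------------------------------------------------------
# QC

def test_qc_level_zero_rules():
    records = [
        rec("A", "B", methods=("unspecified",)),            # unspecified-only: out
        rec("C", "D", methods=("Unspecified", "two hybrid")),  # mixed: kept
        rec("E", "E"),                                      # self: out
        rec("F", "G", pmids=()),                            # no publication: out
        rec("H", "I"),
    ]
    kept = qc_level_zero(records)
    assert [(r.symbol_a, r.symbol_b) for r in kept] == [("C", "D"), ("H", "I")]


def test_high_confidence_threshold_inclusive_and_strict():
    records = [rec("A", "B", conf=0.72), rec("C", "D", conf=0.7199)]
    assert [r.pair for r in filter_high_confidence(records)] == [frozenset("AB")]
    assert filter_high_confidence(records, strict_gt=True) == []


def test_high_confidence_removes_ubiquitin_and_flagged():
    records = [
        rec("TP53", "UBC", conf=0.99),
        rec("TP53", "MDM2", conf=0.99, ambiguous_mapping=True),
        rec("TP53", "X1_HUMAN", conf=0.99, nonstandard_symbol=True),
        rec("TP53", "TP53", conf=0.99),
        rec("TP53", "BRCA1", conf=0.99),
    ]
    kept = filter_high_confidence(records)
    assert [r.pair for r in kept] == [frozenset({"TP53", "BRCA1"})]


def test_confidence_threshold_monotonicity():
    rng = np.random.default_rng(0)
    records = [
        rec(f"A{i}", f"B{i}", conf=float(rng.uniform(0, 1))) for i in range(50)
    ]
    sizes = [
        len(filter_high_confidence(records, threshold=t))
        for t in (0.2, 0.5, 0.72, 0.9)
    ]
    assert sizes == sorted(sizes, reverse=True)


# ---------------------------------------------------------------------------
# Bridges

def test_bridge_definition_cases():
    seeds = {"S1", "S2", "S3"}
    unconnected = [rec("X", "S1"), rec("X", "S2")]
    assert find_bridges(seeds, unconnected) == {"X"}
    connected = unconnected + [rec("S1", "S2")]
    assert find_bridges(seeds, connected) == set()


def _brute_force_bridges(seeds, interactions):
    edges = {r.pair for r in interactions if not r.is_self()}
    nodes = set().union(*edges) if edges else set()
    bridges = set()
    for x in nodes - seeds:
        seed_nbrs = {
            next(iter(e - {x}))
            for e in edges
            if x in e and (e - {x}) <= seeds and len(e) == 2
        }
        if any(
            frozenset((s1, s2)) not in edges
            for s1, s2 in combinations(sorted(seed_nbrs), 2)
        ):
            bridges.add(x)
    return bridges


def test_bridges_match_bruteforce_on_random_graphs():
    rng = np.random.default_rng(42)
    for trial in range(25):
        n = int(rng.integers(6, 41))
        labels = [f"N{i}" for i in range(n)]
        seeds = set(rng.choice(labels, size=max(2, n // 3), replace=False))
        records = []
        for a, b in combinations(labels, 2):
            if rng.random() < 0.15:
                records.append(rec(a, b))
        assert find_bridges(seeds, records) == _brute_force_bridges(seeds, records)


# ---------------------------------------------------------------------------
# Level zero / level one

def test_level_zero_component_census():
    seeds = {"A", "B", "C", "D", "E"}
    records = [rec("A", "B"), rec("C", "D"), rec("A", "Z")]  # Z not a seed
    g, report = build_level_zero(seeds, records)
    assert report["component_sizes"] == [2, 2]
    assert report["components"][0] == ["A", "B"]  # ties broken lexicographically
    assert report["isolated_seeds"] == ["E"]


def test_level_zero_no_seed_edges():
    g, report = build_level_zero({"A", "B"}, [rec("A", "X"), rec("B", "Y")])
    assert g.number_of_edges() == 0
    assert report["isolated_seeds"] == ["A", "B"]


def test_level_one_bridge_path():
    seeds = {"S1", "S2"}
    g, report = build_level_one(seeds, [rec("X", "S1"), rec("X", "S2")])
    assert set(g.nodes) == {"S1", "S2", "X"}
    assert g.nodes["X"]["role"] == "bridge"
    assert report["core"] == {"n_nodes": 3, "n_seeds": 2, "n_bridges": 1}


def test_level_one_excludes_nonbridges_and_bridge_bridge_edges():
    seeds = {"S1", "S2", "S3"}
    records = [
        rec("S1", "S2"),
        rec("X", "S1"), rec("X", "S2"),      # X touches a connected pair only
        rec("Y", "S1"), rec("Y", "S3"),      # Y is a bridge
        rec("Y", "Z"), rec("Z", "S1"), rec("Z", "S3"),  # Z bridge; Y-Z dropped
    ]
    g, _ = build_level_one(seeds, records)
    assert "X" not in g.nodes
    assert not g.has_edge("Y", "Z")
    assert g.nodes["Y"]["role"] == "bridge" and g.nodes["Z"]["role"] == "bridge"


def test_level_one_recovers_planted_ground_truth(small_interactome):
    records, truth = small_interactome
    hc = filter_high_confidence(records)
    assert find_bridges(set(truth.seeds), hc) == truth.bridges
    g, report = build_level_one(set(truth.seeds), hc)
    core = largest_component(g)
    assert set(core.nodes) == truth.level1_core_nodes
    assert report["core"]["n_bridges"] == len(truth.bridges)
    # every bridge satisfies the definitional predicate post hoc
    edges = {r.pair for r in hc if not r.is_self()}
    seeds = set(truth.seeds)
    for b in truth.bridges:
        seed_nbrs = sorted(n for n in g.neighbors(b) if n in seeds)
        assert any(
            frozenset(p) not in edges for p in combinations(seed_nbrs, 2)
        )


def test_level_zero_recovers_planted_census(small_interactome):
    records, truth = small_interactome
    g, report = build_level_zero(set(truth.seeds), qc_level_zero(records))
    assert set(report["components"][0]) == truth.core_level0
    pend = {frozenset(p) for p in truth.pendant_pairs}
    assert {frozenset(c) for c in report["components"][1:]} == pend
    assert set(report["isolated_seeds"]) == truth.isolated_seeds


def test_edge_set_invariant_under_row_order_and_swap(small_interactome):
    records, truth = small_interactome
    swapped = [
        Interaction(r.symbol_b, r.symbol_a, r.confidence, r.pubmed_ids,
                    r.detection_methods, r.ambiguous_mapping, r.nonstandard_symbol)
        for r in reversed(records)
    ]
    g1, _ = build_level_one(set(truth.seeds), filter_high_confidence(records))
    g2, _ = build_level_one(set(truth.seeds), filter_high_confidence(swapped))
    assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


# ---------------------------------------------------------------------------
# Hubs

def test_hub_nodes_star_and_empty():
    star = [rec("HUB", f"S{i}") for i in range(20)]
    g, _ = build_level_zero({"HUB", *(f"S{i}" for i in range(20))}, star)
    assert hub_nodes(g, 14) == [("HUB", 20)]
    assert hub_nodes(g, 25) == []


def test_hub_degrees_match_incident_edge_recount(small_interactome):
    records, truth = small_interactome
    g, _ = build_level_one(set(truth.seeds), filter_high_confidence(records))
    for node, degree in hub_nodes(g, min_degree=3):
        assert degree == sum(1 for e in g.edges if node in e)


def test_network_serialization_round_trip(tmp_path, small_interactome):
    records, truth = small_interactome
    g, _ = build_level_one(set(truth.seeds), filter_high_confidence(records))
    edge_path = tmp_path / "net.edges.tsv"
    write_network(g, edge_path, tmp_path / "net.nodes.tsv", tmp_path / "net.graphml")
    back = read_network(edge_path)
    assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
    assert all(back.nodes[n]["role"] == g.nodes[n]["role"] for n in g.nodes)
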