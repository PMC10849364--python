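"""Fast-greedy modularity clustering and cluster QC.

The level-one network is partitioned into density communities by
agglomerative greedy modularity maximization (Clauset–Newman–Moore style
"fast greedy"): starting from singleton communities, the pair of connected
communities with the largest modularity gain dQ is merged until no merge
improves Q.  For an unweighted simple graph with m edges, merging
communities i and j changes Newman–Girvan modularity by

    dQ = e_ij / m - d_i * d_j / (2 m^2)

where e_ij is the number of edges between the two communities and d_i, d_j
their total degrees.  dQ comparisons are made on the exact integer numerator
2*m*e_ij - d_i*d_j, and ties are broken on the lexicographic pair of
community representatives (smallest member), so partitions are
bit-reproducible regardless of node insertion order.

Cluster QC keeps communities that are both large enough and seed-enriched:
n_nodes >= min_nodes and seed:bridge ratio >= 0.7 (a cluster with no bridges
counts as infinitely seed-enriched and passes the ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["Partition", "ClusterReport", "greedy_modularity", "qc_clusters", "modularity"]


@dataclass
class Partition:
    """Disjoint node communities covering the graph, with their modularity."""

    clusters: list[list[str]]  # sorted members; list sorted by (-size, first member)
    modularity_q: float

    def membership(self) -> dict[str, int]:
        return {n: i for i, c in enumerate(self.clusters) for n in c}


@dataclass
class ClusterReport:
    cluster_id: int
    n_nodes: int
    n_seeds: int
    n_bridges: int
    seed_bridge_ratio: float  # inf when n_bridges == 0
    passed_qc: bool


def modularity(g: nx.Graph, clusters: list[list[str]]) -> float:
    """Newman–Girvan modularity of a partition on an unweighted simple graph."""
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for c in clusters:
        cset = set(c)
        intra = sum(1 for a, b in g.edges(cset) if a in cset and b in cset)
        deg = sum(d for _, d in g.degree(cset))
        q += intra / m - (deg / (2 * m)) ** 2
    return q


def greedy_modularity(g: nx.Graph) -> Partition:
    """Partition a simple undirected graph by greedy modularity maximization.

    Isolated nodes end up as singleton clusters.  Raises on an empty graph.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    m = g.number_of_edges()
    nodes = sorted(g.nodes)
    if m == 0:
        clusters = [[n] for n in nodes]
        return Partition(clusters=clusters, modularity_q=0.0)

    # community state keyed by representative = smallest member label
    members: dict[str, set] = {n: {n} for n in nodes}
    degree: dict[str, int] = {n: g.degree(n) for n in nodes}
    # edges between communities, keyed by ordered representative pair
    between: dict[tuple[str, str], int] = {}
    for a, b in g.edges:
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        between[key] = between.get(key, 0) + 1

    while True:
        # best merge by exact integer dQ numerator: 2*m*e_ij - d_i*d_j
        best_key = None
        best_num = 0
        for key in between:
            i, j = key
            num = 2 * m * between[key] - degree[i] * degree[j]
            if num > best_num or (num == best_num and best_num > 0 and key < best_key):
                best_num = num
                best_key = key
        if best_key is None or best_num <= 0:
            break
        i, j = best_key  # i < j; merged community keeps representative i
        members[i] |= members.pop(j)
        degree[i] += degree.pop(j)
        new_between: dict[tuple[str, str], int] = {}
        for (a, b), cnt in between.items():
            if (a, b) == (i, j):
                continue  # now internal
            a2 = i if a == j else a
            b2 = i if b == j else b
            key2 = (a2, b2) if a2 < b2 else (b2, a2)
            new_between[key2] = new_between.get(key2, 0) + cnt
        between = new_between

    clusters = sorted(
        (sorted(c) for c in members.values()), key=lambda c: (-len(c), c[0])
    )
    return Partition(clusters=clusters, modularity_q=modularity(g, clusters))


def qc_clusters(
    partition: Partition,
    roles: dict[str, str],
    min_nodes: int = 10,
    min_ratio: float = 0.7,
) -> list[ClusterReport]:
    """Per-cluster seed/bridge census and QC verdict.

    ``roles`` maps every node to "seed" or "bridge".  A cluster passes when
    it has at least ``min_nodes`` nodes and a seed:bridge ratio of at least
    ``min_ratio`` (ratio is +inf when the cluster has no bridges).
    """
    reports = []
    for cid, cluster in enumerate(partition.clusters):
        missing = [n for n in cluster if n not in roles]
        if missing:
            raise ValueError(f"no role for nodes: {missing}")
        n_seeds = sum(1 for n in cluster if roles[n] == "seed")
        n_bridges = len(cluster) - n_seeds
        ratio = math.inf if n_bridges == 0 else n_seeds / n_bridges
        reports.append(
            ClusterReport(
                cluster_id=cid,
                n_nodes=len(cluster),
                n_seeds=n_seeds,
                n_bridges=n_bridges,
                seed_bridge_ratio=ratio,
                passed_qc=(len(cluster) >= min_nodes and ratio >= min_ratio),
            )
        )
    return reports


def reports_frame(reports: list[ClusterReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_nodes": r.n_nodes,
                "n_seeds": r.n_seeds,
                "n_bridges": r.n_bridges,
                "seed_bridge_ratio": r.seed_bridge_ratio,
                "passed_qc": int(r.passed_qc),
            }
            for r in reports
        ]
    )
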