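"""lncRNA-miRNA-mRNA (ceRNA) network assembly and topology.

Nodes are miRNAs plus transcripts typed by class and role: MT (mRNA
target), LT (lncRNA target), MD (mRNA mimic/decoy), LD (lncRNA
mimic/decoy). A transcript bound as a target of one miRNA and a mimic of
another appears as two typed nodes sharing a base id. Every edge joins a
miRNA to a transcript, so the graph is bipartite.

Topology metrics follow literal count-based definitions: degree; node
betweenness as the *number* of shortest paths between other node pairs
running through the node (each unordered pair counted once, endpoints
excluded — not the Brandes fraction, which is available via a flag);
average shortest path length over reachable nodes; and closeness as the
reciprocal of that average. Hubs are nodes with at least ten partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

NODE_TYPES = ("miRNA", "mRNA_target", "lncRNA_target", "mRNA_mimic", "lncRNA_mimic")
_PREFIX = {"mRNA_target": "MT", "lncRNA_target": "LT",
           "mRNA_mimic": "MD", "lncRNA_mimic": "LD"}


@dataclass
class NodeMetrics:
    node_id: str
    degree: int
    betweenness: float
    closeness: float
    avg_shortest_path: float  # nan for isolated nodes


def build_network(pair_calls: pd.DataFrame) -> nx.Graph:
    """Assemble the typed graph from pair-level interaction calls.

    ``pair_calls`` needs columns mirna_id, transcript_id,
    transcript_class (mRNA | lncRNA), role (TARGET | MIMIC | NONE);
    NONE rows are ignored. Transcript node ids are prefixed MT:/LT:/MD:/LD:
    by class and role; miRNA ids are used as-is.
    """
    g = nx.Graph()
    for _, row in pair_calls.iterrows():
        role = row["role"]
        if role == "NONE":
            continue
        cls = row["transcript_class"]
        if cls not in ("mRNA", "lncRNA"):
            raise ValueError(f"transcript {row['transcript_id']!r} has class "
                             f"{cls!r}; expected mRNA or lncRNA")
        node_type = f"{cls}_{'target' if role == 'TARGET' else 'mimic'}"
        tnode = f"{_PREFIX[node_type]}:{row['transcript_id']}"
        mnode = str(row["mirna_id"])
        g.add_node(mnode, node_type="miRNA", base_id=mnode)
        g.add_node(tnode, node_type=node_type, base_id=str(row["transcript_id"]))
        g.add_edge(mnode, tnode, relation="target" if role == "TARGET" else "mimic")
    return g


def topology_metrics(graph: nx.Graph, betweenness: str = "path-count") -> list[NodeMetrics]:
    """Per-node degree, betweenness, closeness and average shortest path.

    ``betweenness='path-count'`` counts shortest paths through the node
    (sigma_st(i) summed over unordered pairs s<t, endpoints excluded,
    reachable pairs only); ``'fraction'`` uses the standard normalized
    Brandes definition instead. Isolated nodes get closeness 0 and an
    undefined (NaN) average path length.
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for v in nodes:
        i = index[v]
        # BFS counting shortest paths from v
        dist[i, i] = 0
        sigma[i, i] = 1
        frontier = [v]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    k = index[w]
                    if np.isinf(dist[i, k]):
                        dist[i, k] = d + 1
                        nxt.append(w)
                    if dist[i, k] == d + 1:
                        sigma[i, k] += sigma[i, index[u]]
            frontier = nxt
            d += 1

    if betweenness == "fraction":
        bc = nx.betweenness_centrality(graph, normalized=True)
        btw = {v: bc[v] for v in nodes}
    elif betweenness == "path-count":
        btw = {}
        for v in nodes:
            i = index[v]
            through = np.outer(sigma[:, i], sigma[i, :])
            on_path = dist[:, i][:, None] + dist[i, :][None, :] == dist
            valid = np.isfinite(dist)
            count = np.where(on_path & valid, through, 0.0)
            count[i, :] = 0
            count[:, i] = 0
            np.fill_diagonal(count, 0)
            btw[v] = float(count.sum() / 2)  # each unordered pair once
    else:
        raise ValueError(f"unknown betweenness mode {betweenness!r}")

    out = []
    for v in nodes:
        i = index[v]
        reach = np.isfinite(dist[i]) & (np.arange(n) != i)
        if reach.any():
            avg = float(dist[i, reach].mean())
            clo = 1.0 / avg if avg > 0 else 0.0
        else:
            avg = float("nan")
            clo = 0.0
        out.append(NodeMetrics(v, graph.degree[v], btw[v], clo, avg))
    return out


def metrics_table(metrics: list[NodeMetrics], graph: nx.Graph) -> pd.DataFrame:
    return pd.DataFrame([{
        "node_id": m.node_id,
        "node_type": graph.nodes[m.node_id].get("node_type", "unknown"),
        "degree": m.degree,
        "betweenness": m.betweenness,
        "closeness": m.closeness,
        "avg_shortest_path": m.avg_shortest_path,
    } for m in metrics])


def find_hubs(metrics: list[NodeMetrics], graph: nx.Graph,
              min_partners: int = 10) -> dict[str, list[str]]:
    """Nodes with at least ``min_partners`` partners, split by node type."""
    hubs: dict[str, list[str]] = {}
    for m in metrics:
        if m.degree >= min_partners:
            ntype = graph.nodes[m.node_id].get("node_type", "unknown")
            hubs.setdefault(ntype, []).append(m.node_id)
    return {k: sorted(v) for k, v in hubs.items()}
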