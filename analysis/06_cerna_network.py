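"""Assemble the lncRNA-miRNA-mRNA network, export it, and profile its
topology (degree, path-count betweenness, closeness, hubs)."""

from pathlib import Path

import pandas as pd

from hypolnc import core_io
from hypolnc.cerna_network import (build_network, find_hubs, metrics_table,
                                   topology_metrics)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pairs = pd.read_csv(BASE / "interaction_pairs.tsv", sep="\t")
    graph = build_network(pairs)
    core_io.export_network(graph, BASE / "cerna", "sif")
    core_io.export_network(graph, BASE / "cerna", "graphml")
    metrics = topology_metrics(graph)
    tab = metrics_table(metrics, graph)
    tab.to_csv(BASE / "cerna_metrics.tsv", sep="\t", index=False)

    by_type = tab.groupby("node_type")["avg_shortest_path"].mean()
    print(f"network: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges")
    print("mean average-shortest-path by node type:")
    print(by_type.to_string())
    hubs = find_hubs(metrics, graph)
    print("hubs (>= 10 partners):",
          {k: len(v) for k, v in hubs.items()} or "none")


if __name__ == "__main__":
    main()
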