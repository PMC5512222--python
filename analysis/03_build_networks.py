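#!/usr/bin/env python
"""Build the domain co-occurrence and adjacency networks of the corpus.

Full networks (GraphML + edge lists) go under scratch/networks/; a compact
summary with the heaviest edges and their occurrence classes goes under
results/.
"""

import json
from collections import Counter
from pathlib import Path

from polyvalent.architectures import filter_polyvalent, read_architecture_table
from polyvalent.catalog import load_catalog
from polyvalent.networks import (
    build_adjacency_network,
    build_cooccurrence_network,
    classify_edges_and_nodes,
    write_edgelist_tsv,
    write_graphml,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    catalog = load_catalog()
    table = filter_polyvalent(
        read_architecture_table(ROOT / "scratch" / "corpus" / "architectures.tsv", catalog)
    )
    out = ROOT / "scratch" / "networks"
    out.mkdir(parents=True, exist_ok=True)

    summary = {"n_polyvalent_proteins": len(table)}
    for name, builder in (("cooccurrence", build_cooccurrence_network),
                          ("adjacency", build_adjacency_network)):
        net = classify_edges_and_nodes(builder(table))
        write_graphml(net, out / f"{name}.graphml")
        write_edgelist_tsv(net, out / f"{name}.tsv")
        classes = Counter(d["edge_class"] for _, _, d in net.graph.edges(data=True))
        heaviest = sorted(
            net.graph.edges(data=True), key=lambda e: -e[2]["occurrence_count"]
        )[:15]
        summary[name] = {
            "nodes": net.n_nodes,
            "edges": net.n_edges,
            "edge_classes": dict(classes),
            "heaviest_edges": [
                {"edge": f"{u}--{v}" if name == "cooccurrence" else f"{u}->{v}",
                 "count": d["occurrence_count"], "class": d["edge_class"]}
                for u, v, d in heaviest
            ],
        }
        print(f"{name}: {net.n_nodes} nodes, {net.n_edges} edges, classes {dict(classes)}")

    with open(ROOT / "results" / "networks_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)


if __name__ == "__main__":
    main()
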