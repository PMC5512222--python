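#!/usr/bin/env python
"""Network-parameter battery on the corpus domain networks.

Computes the degree distribution and its discrete power-law fit (with
bootstrap p value), the exponential fit to the domains-per-protein
histogram, betweenness, HITS hub/authority scores on the adjacency
network, the largest cliques with their merged subnetwork, and the largest
biconnected subnetwork.  Writes results/network_stats.json.
"""

import json
from collections import Counter
from dataclasses import asdict
from pathlib import Path

from polyvalent.architectures import filter_polyvalent, read_architecture_table
from polyvalent.catalog import load_catalog
from polyvalent.networks import read_edgelist_tsv
from polyvalent.netstats import (
    betweenness,
    degree_sequence,
    fit_exponential_decay,
    fit_power_law,
    hits_scores,
    largest_biconnected,
    maximal_cliques,
    merge_largest_cliques,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
MIN_CLIQUE = 7
BOOTSTRAP = 250


def top(d, k=8):
    return {n: round(v, 4) for n, v in sorted(d.items(), key=lambda kv: -kv[1])[:k]}


def main():
    nets = ROOT / "scratch" / "networks"
    coo = read_edgelist_tsv(nets / "cooccurrence.tsv", directed=False)
    adj = read_edgelist_tsv(nets / "adjacency.tsv", directed=True)
    table = filter_polyvalent(
        read_architecture_table(ROOT / "scratch" / "corpus" / "architectures.tsv",
                                load_catalog())
    )

    degs = degree_sequence(coo, "total")
    pl = fit_power_law(degs, n_bootstrap=BOOTSTRAP, seed=SEED)
    hist = Counter(len(p.hits) for p in table)
    ef = fit_exponential_decay(dict(hist))
    btw = betweenness(coo, normalized=False)
    hub, auth = hits_scores(adj, scale_max=True)
    cliques = maximal_cliques(coo)
    largest = len(cliques[0])
    sub = merge_largest_cliques(coo, MIN_CLIQUE)
    bic = largest_biconnected(coo)

    out = {
        "degree": {"n_nodes": len(degs), "max": degs[0],
                   "nodes_with_more_than_20_connections": sum(1 for d in degs if d > 20)},
        "power_law_fit": asdict(pl),
        "exponential_fit_domains_per_protein": asdict(ef),
        "top_betweenness": top(btw),
        "top_hub_scores": top(hub),
        "top_authority_scores": top(auth),
        "cliques": {"n_maximal": len(cliques), "largest_size": largest,
                    "size_histogram": dict(Counter(len(c) for c in cliques)),
                    "largest_cliques": [c for c in cliques if len(c) == largest]},
        "clique_subnetwork": {"min_clique_size": MIN_CLIQUE, "nodes": len(sub),
                              "edges": sub.number_of_edges()},
        "largest_biconnected": {"nodes": len(bic), "edges": bic.number_of_edges(),
                                "fraction_of_network": round(len(bic) / len(degs), 3)},
    }
    with open(ROOT / "results" / "network_stats.json", "w") as fh:
        json.dump(out, fh, indent=2)

    print(f"power-law fit: alpha={pl.alpha:.2f} xmin={pl.xmin} "
          f"KS={pl.ks_stat:.3f} p={pl.p_value} (n_tail={pl.n_tail})")
    print(f"domains-per-protein exponential fit: r^2={ef.r_squared:.3f} "
          f"slope={ef.slope:.3f} p={ef.p_value:.2e}")
    print(f"{out['degree']['nodes_with_more_than_20_connections']} domains have "
          f">20 connections; top betweenness: {list(top(btw, 5))}")
    print(f"largest cliques have {largest} nodes; merging cliques of size "
          f">= {MIN_CLIQUE} gives a {len(sub)}-node subnetwork")
    print(f"largest biconnected subnetwork: {len(bic)} nodes "
          f"({100 * len(bic) / len(degs):.1f}% of the network)")


if __name__ == "__main__":
    main()
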