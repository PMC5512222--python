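#!/usr/bin/env python
"""Classify the genomic context of every corpus protein and score recovery.

Reads the corpus written by 01_simulate_corpus.py, runs the marker-tag
classifier on each gene neighborhood, and compares the calls against the
generator's ground-truth element classes.
"""

import json
from collections import Counter
from pathlib import Path

from polyvalent.architectures import read_architecture_table
from polyvalent.neighborhoods import classify_context, extract_neighborhood, read_gene_table

ROOT = Path(__file__).resolve().parents[1]
K = 10


def main():
    corpus_dir = ROOT / "scratch" / "corpus"
    table = read_architecture_table(corpus_dir / "architectures.tsv")
    ann = read_gene_table(corpus_dir / "neighborhoods.tsv")
    truth = {p.protein_id: p.element_class for p in table}

    confusion = Counter()
    for rep, genes in ann.items():
        anchor = next(g.gene_id for g in genes if g.gene_id.endswith("_anchor"))
        nb = extract_neighborhood({rep: genes}, anchor, K)
        call = classify_context(nb)
        pid = anchor.removesuffix("_anchor")
        confusion[(truth[pid], call.element_class)] += 1

    n = sum(confusion.values())
    correct = sum(v for (t, c), v in confusion.items() if t == c)
    out = {
        "n_neighborhoods": n,
        "accuracy_percent": 100.0 * correct / n,
        "called_conjugative_percent": 100.0
        * sum(v for (_, c), v in confusion.items() if c == "conjugative") / n,
        "confusion": {f"{t}->{c}": v for (t, c), v in sorted(confusion.items())},
    }
    with open(ROOT / "results" / "context_calls.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(f"classified {n} neighborhoods: {out['accuracy_percent']:.2f}% correct, "
          f"{out['called_conjugative_percent']:.2f}% called conjugative")


if __name__ == "__main__":
    main()
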