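#!/usr/bin/env python
"""Prevalence, conditional co-occurrence and class-sharing statistics.

Computes the percentage battery on the corpus: per-domain prevalence and
multicopy rates, conditional co-occurrence between the calibrated hub
domains, distinct-architecture counts, the class domain-sharing fraction,
and the top of the domain frequency table.  Writes results/cooccurrence.json
and results/domain_frequency.tsv.
"""

import json
from pathlib import Path

from polyvalent.architectures import filter_polyvalent, read_architecture_table
from polyvalent.catalog import load_catalog
from polyvalent.cooccurrence import (
    compute_cooccurrence_report,
    count_distinct_architectures,
    write_frequency_tsv,
)

ROOT = Path(__file__).resolve().parents[1]
HUBS = ["MPTase", "ArdC-N", "MutS-I"]


def main():
    catalog = load_catalog()
    table = filter_polyvalent(
        read_architecture_table(ROOT / "scratch" / "corpus" / "architectures.tsv", catalog)
    )
    pairs = [(x, y) for x in HUBS for y in HUBS if x != y]
    rep = compute_cooccurrence_report(table, top_n=100, conditional_pairs=pairs,
                                      catalog_size=len(catalog))

    out = {
        "n_proteins": len(table),
        "distinct_architectures_total": count_distinct_architectures(table),
        "prevalence_percent": {d: round(rep.prevalence[d], 2) for d in HUBS},
        "multicopy_percent": {d: round(rep.multicopy[d], 2) for d in HUBS},
        "conditional_percent": {f"{y}|{x}": round(v, 2)
                                for (x, y), v in rep.conditional.items()},
        "distinct_architectures_with_domain": {d: rep.distinct_architectures[d]
                                               for d in HUBS},
        "class_shared_percent_union": round(rep.shared_percent, 2),
        "class_shared_percent_of_catalog": round(rep.shared_percent_of_catalog, 2),
        "frequency_table_head": rep.frequency_table[:10],
        "frequency_table_range": [rep.frequency_table[0][1], rep.frequency_table[-1][1]],
    }
    with open(ROOT / "results" / "cooccurrence.json", "w") as fh:
        json.dump(out, fh, indent=2)
    write_frequency_tsv(rep.frequency_table, ROOT / "results" / "domain_frequency.tsv")

    print(f"{len(table)} polyvalent proteins, "
          f"{out['distinct_architectures_total']} distinct architectures")
    for d in HUBS:
        print(f"  {d}: prevalence {out['prevalence_percent'][d]}%, "
              f"multicopy {out['multicopy_percent'][d]}%, "
              f"{out['distinct_architectures_with_domain'][d]} architectures")
    print("conditional co-occurrence:", out["conditional_percent"])
    print(f"domains shared between phage and conjugative classes: "
          f"{out['class_shared_percent_union']}% of the observed union")
    print("frequency table spans", out["frequency_table_range"][0], "to",
          out["frequency_table_range"][1], "distinct proteins (top 100 domains)")


if __name__ == "__main__":
    main()
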