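#!/usr/bin/env python
"""Seed-filtered network analysis: core neighbourhood and modulators.

Cleans the interaction network (duplicates, self-loops, the promiscuous
UBC_SYN node), expands the curated core molecules to their first-order
neighbourhood, intersects with the per-subset DE calls and partitions the
resulting pathway modulators into subset-specific Venn classes.  Writes
results/network/.
"""

import json
from pathlib import Path

import pandas as pd

from subsetnet import network, simulate

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = network.load_and_clean(BASE / "data" / "network.sif",
                                 exclusions=(simulate.UBC_NODE,))
    seeds = network.read_seed_list(BASE / "data" / "core_molecules.txt")
    print(f"cleaned network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges ({simulate.UBC_NODE} removed)")

    expanded = network.first_order_expand(net, seeds)
    network.write_graphml(expanded, OUT / "first_order.graphml")
    print(f"first-order neighbourhood of {len(seeds)} cores: "
          f"{expanded.number_of_nodes()} nodes")

    de_sets = {}
    for s in "AB":
        t = pd.read_csv(BASE / "diffexpr" / f"de_{s}.tsv", sep="\t",
                        index_col="gene_id")
        de_sets[s] = set(t.index[t["call"] != "ns"])
    part = network.find_modulators(expanded, de_sets, seeds)
    with open(OUT / "modulators.json", "w") as fh:
        json.dump(part.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    d = part.venn.as_dict()
    print(f"pathway modulators: A {len(part.modulators['A'])}, "
          f"B {len(part.modulators['B'])}")
    print(f"  subset-specific: {d['pct_a_display']}% of A, "
          f"{d['pct_b_display']}% of B ({d['shared']} shared)")


if __name__ == "__main__":
    main()
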