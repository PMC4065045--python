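#!/usr/bin/env python
"""Hub classification and concordance between the two network analyses.

Classifies nodes of each subset's merged unbiased subnetwork by induced
degree (hub >= 5 interactions, highly-interconnected hub >= 15), then
measures how many of the seed-filtered pathway modulators from step 05
reappear in the unbiased subnetworks.  Writes results/hubs/.
"""

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from subsetnet import hubs, network, simulate
from subsetnet.config import HubConfig

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "hubs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    net = network.load_and_clean(BASE / "data" / "network.sif",
                                 exclusions=(simulate.UBC_NODE,))
    truth = pd.read_csv(BASE / "data" / "truth_genes.tsv", sep="\t",
                        index_col="gene_id")

    subnet_nodes = {}
    for s in "AB":
        mods = json.loads((BASE / "subnetworks" / f"modules_{s}.json").read_text())
        subnet_nodes[s] = sorted({n for m in mods for n in m["members"]})
        table = hubs.classify_hubs(subnet_nodes[s], net, HubConfig(),
                                   core_flags=truth["core"])
        table.to_csv(OUT / f"hubs_{s}.tsv", sep="\t", index_label="node")
        counts = table["hub_class"].value_counts()
        n_core_hub = int((table["is_core"]
                          & (table["hub_class"] != "none")).sum())
        print(f"subset {s}: {counts.get('hub', 0)} hubs, "
              f"{counts.get('super_hub', 0)} highly-interconnected hubs "
              f"({n_core_hub} of them planted cores)")

    part_dict = json.loads((BASE / "network" / "modulators.json").read_text())
    de_sets = {}
    for s in "AB":
        t = pd.read_csv(BASE / "diffexpr" / f"de_{s}.tsv", sep="\t",
                        index_col="gene_id")
        de_sets[s] = set(t.index[t["call"] != "ns"])
    seeds = network.read_seed_list(BASE / "data" / "core_molecules.txt")
    expanded = network.first_order_expand(net, seeds)
    part = network.find_modulators(expanded, de_sets, seeds)
    conc = hubs.concordance(part, {s: set(n) for s, n in subnet_nodes.items()})
    conc.table.to_csv(OUT / "concordance.tsv", sep="\t", index_label="subset")
    for s, row in conc.table.iterrows():
        print(f"subset {s}: {row['n_found']:.0f}/{row['n_modulators']:.0f} "
              f"filtered modulators also in the unbiased subnetwork "
              f"({row['pct']:.0f}%)")


if __name__ == "__main__":
    main()
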