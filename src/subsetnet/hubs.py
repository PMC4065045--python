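"""Hub classification and cross-analysis concordance.

Hubs are nodes with >= 5 interactions, "most highly interconnected" hubs
have >= 15 (inclusive thresholds, configurable).  Degree is computed
within the subnetwork's induced subgraph by default (``degree_scope=
'subnetwork'``); full-network degree is available as the alternative
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from subsetnet.config import HubConfig


def classify_hubs(subnet_nodes, net: nx.Graph, cfg: HubConfig | None = None,
                  core_flags: pd.Series | None = None,
                  fold_changes: pd.Series | None = None,
                  degree_scope: str = "subnetwork") -> pd.DataFrame:
    """Per-node degree and hub class within a discovered subnetwork.

    Returns a DataFrame indexed by node: degree, hub_class in
    {none, hub, super_hub}, is_core, fold_change (if supplied).
    """
    cfg = cfg or HubConfig()
    nodes = list(subnet_nodes)
    if not nodes:
        raise ValueError("empty subnetwork")
    missing = [n for n in nodes if n not in net]
    if missing:
        raise ValueError(f"subnetwork nodes absent from network: {missing[:5]}")
    if degree_scope == "subnetwork":
        deg = dict(net.subgraph(nodes).degree())
    elif degree_scope == "full":
        deg = {n: net.degree(n) for n in nodes}
    else:
        raise ValueError("degree_scope must be 'subnetwork' or 'full'")

    table = pd.DataFrame({"degree": pd.Series(deg)})
    table["hub_class"] = "none"
    table.loc[table["degree"] >= cfg.hub_min_degree, "hub_class"] = "hub"
    table.loc[table["degree"] >= cfg.super_hub_min_degree, "hub_class"] = "super_hub"
    if core_flags is not None:
        table["is_core"] = core_flags.reindex(table.index).fillna(False).astype(bool)
    if fold_changes is not None:
        table["fold_change"] = fold_changes.reindex(table.index)
    return table.sort_values("degree", ascending=False)


@dataclass
class ConcordanceResult:
    """Overlap between the seed-filtered modulator analysis and the
    unbiased subnetwork analysis, per subset."""

    table: pd.DataFrame  # index subset: n_modulators, n_found, pct

    def as_dict(self) -> dict:
        return {
            s: {"n_modulators": int(r["n_modulators"]),
                "n_found": int(r["n_found"]),
                "pct": float(r["pct"]),
                "pct_display": int(round(r["pct"]))}
            for s, r in self.table.iterrows()
        }


def concordance(partition, subnet_nodes_by_subset: dict) -> ConcordanceResult:
    """Fraction of each subset's filtered modulators present in that
    subset's merged unbiased subnetwork node set."""
    rows = {}
    for subset, mods in partition.modulators.items():
        subnet = {n.casefold() for n in subnet_nodes_by_subset.get(subset, ())}
        found = {m for m in mods if m.casefold() in subnet}
        n = len(mods)
        rows[subset] = {
            "n_modulators": n,
            "n_found": len(found),
            "pct": 100.0 * len(found) / n if n else 0.0,
        }
    return ConcordanceResult(pd.DataFrame.from_dict(rows, orient="index"))
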