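"""Interaction-network ingestion, cleaning, expansion and Venn partitioning.

Interactions are treated as an undirected simple graph over gene symbols.
Symbol matching is case-insensitive with a case-preserving display form;
inputs must already share one symbol space (no orthology mapping).
Cleaning removes duplicate edges, self-loops and configured promiscuous
symbols (by default the general ubiquitin, Ubc, whose thousands of
interactions would bias every downstream subnetwork analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from subsetnet.config import FormatError

log = logging.getLogger(__name__)

DEFAULT_EXCLUSIONS = ("Ubc",)

#: Starting seed fixture: canonical TLR4-pathway signalling molecules.  A
#: fuller curated list (the 48 used in the study design this emulates) is
#: user-supplied input data.
DEFAULT_CORE_SEEDS = (
    "Tlr4", "Ticam1", "Ticam2", "Tirap", "Myd88", "Traf6", "Traf3", "Irak1",
    "Ikbke", "Ikbkg", "Irf7", "Nfkb1", "Nfkbia", "Rela", "Fos", "Jun",
    "Mapk1", "Mapk8", "Mapk11", "Map3k7", "Tab2", "Ripk1", "Tollip",
    "Irf3", "Cd14",
)


def read_seed_list(path) -> list:
    """Plain-text seed list, one symbol per line; '#' comments allowed."""
    seeds = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#")[0].strip()
        if sym and sym not in seeds:
            seeds.append(sym)
    if not seeds:
        raise ValueError(f"no seed symbols found in {path}")
    return seeds


def _iter_edge_lines(path):
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) == 2:
            yield lineno, parts[0], parts[1]
        elif len(parts) == 3:  # SIF: source relation target
            yield lineno, parts[0], parts[2]
        else:
            raise FormatError(f"{path}: line {lineno}: expected 2 or 3 fields, "
                              f"got {len(parts)}: {line[:60]!r}")


def load_and_clean(interactions, exclusions=DEFAULT_EXCLUSIONS) -> nx.Graph:
    """Build a clean simple graph from a SIF/TSV path, edge DataFrame or graph.

    Case-insensitive symbol canonicalisation (first-seen casing is kept for
    display), duplicate edges collapsed, self-loops dropped, excluded
    symbols removed with their incident edges.  Idempotent.
    """
    display: dict = {}

    def canon(sym: str) -> str:
        key = str(sym).casefold()
        return display.setdefault(key, str(sym))

    if isinstance(interactions, nx.Graph):
        pairs = [(u, v) for u, v in interactions.edges()]
    elif isinstance(interactions, pd.DataFrame):
        cols = list(interactions.columns[:2])
        pairs = list(zip(interactions[cols[0]], interactions[cols[1]]))
    else:
        pairs = [(a, b) for _ln, a, b in _iter_edge_lines(interactions)]

    net = nx.Graph()
    for a, b in pairs:
        ca, cb = canon(a), canon(b)
        if ca.casefold() == cb.casefold():
            continue
        net.add_edge(ca, cb)

    drop = {e.casefold() for e in exclusions}
    net.remove_nodes_from([n for n in list(net) if n.casefold() in drop])
    return net


def first_order_expand(net: nx.Graph, seeds) -> nx.Graph:
    """Induced subgraph on the seeds and their first-order neighbours.

    Seeds absent from the network are logged, not fatal; zero present
    seeds is an error.
    """
    lookup = {n.casefold(): n for n in net}
    present = [lookup[s.casefold()] for s in seeds if s.casefold() in lookup]
    missing = [s for s in seeds if s.casefold() not in lookup]
    if missing:
        log.warning("%d seed(s) absent from network: %s",
                    len(missing), ", ".join(missing[:8]))
    if not present:
        raise ValueError("none of the seed symbols are present in the network")
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    return net.subgraph(nodes).copy()


@dataclass
class VennPartition:
    """Two-set Venn: disjoint classes covering the union, with per-side
    subset-specific percentages (exact, plus nearest-integer display)."""

    only_a: frozenset
    shared: frozenset
    only_b: frozenset

    @property
    def pct_a(self) -> float:
        tot = len(self.only_a) + len(self.shared)
        return 100.0 * len(self.only_a) / tot if tot else 0.0

    @property
    def pct_b(self) -> float:
        tot = len(self.only_b) + len(self.shared)
        return 100.0 * len(self.only_b) / tot if tot else 0.0

    def counts(self) -> dict:
        return {"only_a": len(self.only_a), "shared": len(self.shared),
                "only_b": len(self.only_b)}

    def as_dict(self) -> dict:
        return {
            **self.counts(),
            "pct_a_specific": self.pct_a,
            "pct_b_specific": self.pct_b,
            "pct_a_display": int(round(self.pct_a)),
            "pct_b_display": int(round(self.pct_b)),
        }


def venn_partition(list_a, list_b) -> VennPartition:
    a, b = set(list_a), set(list_b)
    return VennPartition(frozenset(a - b), frozenset(a & b), frozenset(b - a))


@dataclass
class ModulatorPartition:
    """Subset-specific pathway modulators around a shared signalling core.

    Modulators are DE first-order interactors of the seed molecules; the
    seeds themselves are never reported as modulators.
    """

    modulators: dict        # subset -> set
    venn: VennPartition
    seeds: frozenset

    def as_dict(self) -> dict:
        out = self.venn.as_dict()
        out.update({f"total_{s.lower()}": len(m) for s, m in self.modulators.items()})
        return out


def find_modulators(expanded_net: nx.Graph, de_by_subset: dict,
                    seeds) -> ModulatorPartition:
    """Intersect subset DE sets with the expanded neighbourhood, minus seeds."""
    node_lookup = {n.casefold(): n for n in expanded_net}
    seed_keys = {s.casefold() for s in seeds}
    mods = {}
    for subset, de in de_by_subset.items():
        keys = {g.casefold() for g in de}
        mods[subset] = {node_lookup[k] for k in keys & set(node_lookup)} - \
            {node_lookup[k] for k in seed_keys & set(node_lookup)}
    subsets = list(mods)
    venn = venn_partition(mods[subsets[0]], mods[subsets[1]])
    return ModulatorPartition(modulators=mods, venn=venn, seeds=frozenset(
        node_lookup[k] for k in seed_keys & set(node_lookup)))


def write_edge_tsv(net: nx.Graph, path) -> None:
    pd.DataFrame(sorted(map(sorted, net.edges())),
                 columns=["source", "target"]).to_csv(path, sep="\t", index=False)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)
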