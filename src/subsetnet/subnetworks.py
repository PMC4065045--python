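"""Active-subnetwork discovery by simulated annealing.

Per-gene p-values become z-scores z_i = Phi^-1(1 - p_i); a node set A of
size k scores z_A = (sum z_i) / sqrt(k), calibrated against a Monte-Carlo
background of uniform random k-node sets: s_A = (z_A - mu_k) / sigma_k.
The search anneals over node-inclusion states (single-node toggles,
geometric cooling) and finally reports the highest-scoring connected
components of the included set.  Background sets are NOT constrained to
be connected, matching the original published scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from subsetnet.config import AnnealingConfig

log = logging.getLogger(__name__)

P_CLAMP = 1e-10
SIGMA_FLOOR = 1e-9


def score_nodes(p_values: pd.Series, net: nx.Graph) -> pd.Series:
    """z_i = Phi^-1(1 - p_i) for every network node.

    p is clamped to [1e-10, 1 - 1e-10]; nodes without a measured p receive
    p = 1, i.e. the maximally unfavourable clamped z (~ -6.36), so they
    can still join modules via topology but never drive them.
    """
    p = p_values.reindex(list(net.nodes())).fillna(1.0)
    p = p.clip(P_CLAMP, 1.0 - P_CLAMP)
    return pd.Series(norm.isf(p), index=p.index, name="z")


@dataclass
class CalibrationTable:
    """Background mean and sd of z_A per subnetwork size k (1..k_max)."""

    mu: np.ndarray       # index k-1
    sigma: np.ndarray
    n_draws: int
    seed: int

    @property
    def k_max(self) -> int:
        return len(self.mu)

    def score(self, z_sum: float, k: int) -> float:
        """Calibrated score of a node set with z-sum ``z_sum`` and size k.

        Degenerate (constant) score fields hit the sigma floor; their
        calibrated score is defined as 0.
        """
        z_a = z_sum / math.sqrt(k)
        sd = self.sigma[k - 1]
        if sd <= SIGMA_FLOOR:
            return 0.0
        return (z_a - self.mu[k - 1]) / sd


def calibrate(net: nx.Graph, scores: pd.Series, sizes=None,
              n_draws: int = 200, seed: int = 0) -> CalibrationTable:
    """Monte-Carlo background for every size 1..|V| (or max(sizes)).

    Implementation draws ``n_draws`` random permutations of the node set;
    the k-prefix of a permutation is a uniform k-subset without
    replacement, so one pass calibrates all sizes at once (the per-k
    estimates share permutations but each is unbiased).
    """
    z = scores.reindex(list(net.nodes())).to_numpy(dtype=float)
    n = len(z)
    if n == 0:
        raise ValueError("empty network")
    k_max = int(max(sizes)) if sizes is not None else n
    k_max = min(k_max, n)
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_draws, n)), axis=1)
    cums = np.cumsum(z[perms], axis=1)[:, :k_max]
    z_a = cums / np.sqrt(np.arange(1, k_max + 1))
    mu = z_a.mean(axis=0)
    sigma = z_a.std(axis=0, ddof=1)
    sigma = np.maximum(sigma, 0.0)
    return CalibrationTable(mu=mu, sigma=sigma, n_draws=n_draws, seed=seed)


@dataclass
class Subnetwork:
    """A scored connected node set."""

    nodes: frozenset
    z_score: float          # raw z_A = sum(z)/sqrt(k)
    score: float            # calibrated s_A
    connected: bool = True

    @property
    def size(self) -> int:
        return len(self.nodes)

    def degrees_within(self, net: nx.Graph) -> dict:
        sub = net.subgraph(self.nodes)
        return dict(sub.degree())

    def as_dict(self) -> dict:
        return {"members": sorted(self.nodes), "k": self.size,
                "z_A": self.z_score, "s_A": self.score}


def score_subnetwork(nodes, scores: pd.Series, calib: CalibrationTable,
                     net: nx.Graph | None = None) -> Subnetwork:
    """Recompute a Subnetwork record from its member list (consistency path)."""
    nodes = frozenset(nodes)
    k = len(nodes)
    if k == 0:
        raise ValueError("empty subnetwork")
    z_sum = float(scores.reindex(list(nodes)).sum())
    connected = bool(net is None or nx.is_connected(net.subgraph(nodes)))
    return Subnetwork(nodes=nodes, z_score=z_sum / math.sqrt(k),
                      score=calib.score(z_sum, k), connected=connected)


@dataclass
class AnnealDiagnostics:
    accepted_improving: int = 0
    accepted_worsening: int = 0
    rejected: int = 0


def _candidate_moves(net, comp):
    adds = sorted({u for v in comp for u in net.neighbors(v)} - comp)
    if len(comp) > 1:
        drops = sorted(comp - set(nx.articulation_points(net.subgraph(comp))))
    else:
        drops = []
    return adds, drops


def _refine_component(net: nx.Graph, comp: set, z: dict,
                      calib: CalibrationTable, rng: np.random.Generator,
                      t_start: float = 0.3, t_end: float = 0.02) -> set:
    """Local search over CONNECTED states seeded from one component.

    Moves add a neighbouring node or drop a non-articulation member, so
    every visited state stays a connected subgraph.  A greedy
    best-improvement phase runs first; a Metropolis polish whose budget
    shrinks with instance size (thorough on small graphs, token on large
    ones) then escapes shallow local optima.  The best state seen is
    returned.  Polishes the components extracted from the annealed
    inclusion state, whose global objective ignores connectivity.
    """
    comp = set(comp)
    z_sum = sum(z[v] for v in comp)
    score = calib.score(z_sum, len(comp))

    for _ in range(300):  # greedy phase
        adds, drops = _candidate_moves(net, comp)
        best_move = None
        for u in adds:
            s2 = calib.score(z_sum + z[u], len(comp) + 1)
            if s2 > score and (best_move is None or s2 > best_move[0]):
                best_move = (s2, u, 1)
        for v in drops:
            s2 = calib.score(z_sum - z[v], len(comp) - 1)
            if s2 > score and (best_move is None or s2 > best_move[0]):
                best_move = (s2, v, -1)
        if best_move is None:
            break
        score, node, dk = best_move
        if dk > 0:
            comp.add(node)
            z_sum += z[node]
        else:
            comp.discard(node)
            z_sum -= z[node]

    iterations = int(min(3000, max(0, 60_000 // max(len(net), 1))))
    if iterations < 10:
        return comp
    best = (score, set(comp))
    ratio = t_end / t_start
    adds = drops = None  # candidate cache, valid until the state changes
    for i in range(iterations):
        temp = t_start * ratio ** (i / max(iterations - 1, 1))
        if adds is None:
            adds, drops = _candidate_moves(net, comp)
        moves = len(adds) + len(drops)
        if moves == 0:
            break
        pick = int(rng.integers(moves))
        if pick < len(adds):
            node, dz, dk = adds[pick], z[adds[pick]], 1
        else:
            node = drops[pick - len(adds)]
            dz, dk = -z[node], -1
        s2 = calib.score(z_sum + dz, len(comp) + dk)
        delta = s2 - score
        if delta >= 0 or rng.random() < math.exp(max(delta / temp, -700.0)):
            if dk > 0:
                comp.add(node)
            else:
                comp.discard(node)
            z_sum += dz
            score = s2
            adds = drops = None
            if score > best[0]:
                best = (score, set(comp))
    return best[1]


def anneal_search(net: nx.Graph, scores: pd.Series, calib: CalibrationTable,
                  cfg: AnnealingConfig,
                  diagnostics: AnnealDiagnostics | None = None) -> list:
    """Simulated-annealing search for high-scoring connected subnetworks.

    Each restart anneals a random inclusion state with single-node toggle
    proposals (improvements always accepted, worsenings with probability
    exp(delta/T), geometric cooling from t_start to t_end), then extracts
    the connected components of the induced subgraph of the included set.
    Components are pooled over restarts, deduplicated and ranked by
    calibrated score; the top ``n_modules`` are returned.  Deterministic
    given ``cfg.seed``.
    """
    nodes = list(net.nodes())
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    z = scores.reindex(nodes).to_numpy(dtype=float)
    mu, sigma = calib.mu, calib.sigma
    sqrt_k = np.sqrt(np.arange(1, calib.k_max + 1))

    def state_score(z_sum: float, k: int) -> float:
        if k == 0:
            return -np.inf
        sd = sigma[k - 1]
        if sd <= SIGMA_FLOOR:
            return 0.0
        return (z_sum / sqrt_k[k - 1] - mu[k - 1]) / sd

    rng = np.random.default_rng(cfg.seed)
    # geometric cooling: T_i = t_start * ratio**(i / (iterations - 1))
    if cfg.iterations > 1:
        temps = cfg.t_start * (cfg.t_end / cfg.t_start) ** (
            np.arange(cfg.iterations) / (cfg.iterations - 1))
    else:
        temps = np.array([cfg.t_start])
    components: dict = {}

    for _restart in range(cfg.restarts):
        included = rng.random(n) < 0.5
        if not included.any():
            included[int(rng.integers(n))] = True
        k = int(included.sum())
        z_sum = float(z[included].sum())
        s = state_score(z_sum, k)
        flips = rng.integers(0, n, size=cfg.iterations)
        unif = rng.random(cfg.iterations)
        for i in range(cfg.iterations):
            j = flips[i]
            if included[j]:
                k2, z2 = k - 1, z_sum - z[j]
            else:
                k2, z2 = k + 1, z_sum + z[j]
            s2 = state_score(z2, k2)
            delta = s2 - s
            if delta >= 0:
                accept = True
                if diagnostics:
                    diagnostics.accepted_improving += 1
            else:
                accept = unif[i] < math.exp(max(delta / temps[i], -700.0))
                if diagnostics:
                    if accept:
                        diagnostics.accepted_worsening += 1
                    else:
                        diagnostics.rejected += 1
            if accept:
                included[j] = not included[j]
                k, z_sum, s = k2, z2, s2

        chosen = [nodes[i] for i in range(n) if included[i]]
        if not chosen:
            continue
        z_by_node = dict(zip(nodes, z))
        raw_comps = sorted(
            nx.connected_components(net.subgraph(chosen)),
            key=lambda c: -calib.score(sum(z_by_node[v] for v in c), len(c)))
        # polish only the leading components; the rest cannot be returned
        for rank, raw_comp in enumerate(raw_comps):
            if rank < cfg.n_modules:
                comp = _refine_component(net, raw_comp, z_by_node, calib, rng)
            else:
                comp = set(raw_comp)
            key = frozenset(comp)
            if key not in components:
                zc = float(sum(z_by_node[c] for c in comp))
                components[key] = Subnetwork(
                    nodes=key, z_score=zc / math.sqrt(len(key)),
                    score=calib.score(zc, len(key)))

    ranked = sorted(components.values(), key=lambda m: (-m.score, -m.size,
                                                        sorted(m.nodes)))
    return ranked[: cfg.n_modules]


def merge_modules(modules: list, scores: pd.Series, calib: CalibrationTable,
                  merge_jaccard: float = 0.5) -> list:
    """Greedily merge overlapping modules (node-set Jaccard >= threshold).

    Highest-scoring pairs merge first; the merged score is recomputed from
    the union; repeated to a fixpoint.
    """
    mods = sorted(modules, key=lambda m: -m.score)
    changed = True
    while changed:
        changed = False
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                a, b = mods[i].nodes, mods[j].nodes
                jac = len(a & b) / len(a | b)
                if jac >= merge_jaccard:
                    union = a | b
                    merged = score_subnetwork(union, scores, calib)
                    mods = [m for idx, m in enumerate(mods) if idx not in (i, j)]
                    mods.append(merged)
                    mods.sort(key=lambda m: -m.score)
                    changed = True
                    break
            if changed:
                break
    return mods
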