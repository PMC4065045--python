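"""End-to-end orchestration of the subset-comparison analysis.

Stages: synthetic data (or loaded inputs) -> size factors and blind
dispersion -> per-subset single-replicate DE -> length-bias weighting and
ORA -> network cleaning -> seed-filtered modulator partition -> per-subset
unbiased active subnetworks -> hub classification -> concordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from subsetnet import diffexpr, enrichment, hubs, network, simulate, subnetworks
from subsetnet.config import AnnealingConfig, DEConfig, HubConfig, SimulationConfig
from subsetnet.containers import SUBSETS, AnnotationSets, CountMatrix, GroundTruth

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    counts: CountMatrix
    truth: GroundTruth | None
    factors: pd.Series
    dispersion: diffexpr.DispersionFit
    de: dict                      # subset -> DEResult
    cpm: pd.DataFrame
    weights: dict                 # subset -> WeightingFunction
    ora: pd.DataFrame
    clean_net: nx.Graph
    expanded_net: nx.Graph
    modulators: network.ModulatorPartition
    de_venn: network.VennPartition
    subnet_modules: dict          # subset -> list[Subnetwork] (merged, ranked)
    subnet_nodes: dict            # subset -> set of union-of-module nodes
    hub_tables: dict              # subset -> DataFrame
    concordance: hubs.ConcordanceResult

    def de_sets(self) -> dict:
        return {s: r.de_genes() for s, r in self.de.items()}


def run_synthetic(sim_cfg: SimulationConfig | None = None,
                  de_cfg: DEConfig | None = None,
                  anneal_cfg: AnnealingConfig | None = None,
                  hub_cfg: HubConfig | None = None,
                  exclusions=(simulate.UBC_NODE,)) -> PipelineResult:
    """Generate a synthetic dataset and run the full analysis on it.

    The default DE configuration for the pipeline calls genes at a
    BH-adjusted p <= alpha so that the downstream modulator and subnetwork
    stages work from an error-controlled gene list (raw-p calling remains
    the :class:`DEConfig` default for single comparisons).
    """
    sim_cfg = sim_cfg or SimulationConfig()
    de_cfg = de_cfg or DEConfig(use_adjusted=True)
    counts, truth = simulate.gen_counts(sim_cfg)
    net = simulate.gen_network(sim_cfg, truth)
    ann = simulate.gen_annotations(sim_cfg, truth)
    return run_analysis(
        counts, net, ann, seeds=truth.cores, truth=truth, de_cfg=de_cfg,
        anneal_cfg=anneal_cfg or AnnealingConfig(seed=sim_cfg.seed % 2**31),
        hub_cfg=hub_cfg, exclusions=exclusions,
    )


def run_analysis(counts: CountMatrix, interactions, annotations: AnnotationSets,
                 seeds, truth: GroundTruth | None = None,
                 de_cfg: DEConfig | None = None,
                 anneal_cfg: AnnealingConfig | None = None,
                 hub_cfg: HubConfig | None = None,
                 exclusions=network.DEFAULT_EXCLUSIONS) -> PipelineResult:
    de_cfg = de_cfg or DEConfig(use_adjusted=True)
    anneal_cfg = anneal_cfg or AnnealingConfig()
    hub_cfg = hub_cfg or HubConfig()

    factors = diffexpr.size_factors(counts)
    fit = diffexpr.fit_blind_dispersion(counts, factors)
    de = {s: diffexpr.call_de_subset(counts, s, de_cfg, factors=factors, fit=fit)
          for s in SUBSETS}
    cpm_table = diffexpr.cpm(counts, factors)
    de_sets = {s: r.de_genes() for s, r in de.items()}
    for s in SUBSETS:
        log.info("subset %s: %d DE genes", s, len(de_sets[s]))
    de_venn = network.venn_partition(de_sets["A"], de_sets["B"])

    universe = set(de["A"].table.index)
    weights = {}
    for s in SUBSETS:
        flags = pd.Series(
            [g in de_sets[s] for g in de[s].table.index], index=de[s].table.index)
        try:
            weights[s] = enrichment.fit_weighting(
                flags, counts.lengths.reindex(flags.index))
        except ValueError as exc:
            log.warning("weighting fit skipped for subset %s: %s", s, exc)
            weights[s] = None
    ora = enrichment.run_ora(
        de_sets, annotations, universe,
        weights_by_subset={s: (w.per_gene if w else None)
                           for s, w in weights.items()},
        alpha=de_cfg.alpha,
    )

    clean = network.load_and_clean(interactions, exclusions=exclusions)
    expanded = network.first_order_expand(clean, seeds)
    modulators = network.find_modulators(expanded, de_sets, seeds)

    subnet_modules, subnet_nodes, hub_tables = {}, {}, {}
    core_flags = (truth.genes["core"] if truth is not None else None)
    for s in SUBSETS:
        if not de_sets[s]:
            subnet_modules[s], subnet_nodes[s] = [], set()
            continue
        subset_net = network.first_order_expand(clean, sorted(de_sets[s]))
        scores = subnetworks.score_nodes(de[s].p_values(), subset_net)
        calib = subnetworks.calibrate(
            subset_net, scores, n_draws=200,
            seed=(anneal_cfg.seed * 4 + (0 if s == "A" else 1)) % 2**31)
        sub_cfg = AnnealingConfig(
            iterations=anneal_cfg.iterations, t_start=anneal_cfg.t_start,
            t_end=anneal_cfg.t_end, n_modules=anneal_cfg.n_modules,
            restarts=anneal_cfg.restarts,
            seed=(anneal_cfg.seed * 4 + 2 + (0 if s == "A" else 1)) % 2**31,
            merge_jaccard=anneal_cfg.merge_jaccard)
        modules = subnetworks.anneal_search(subset_net, scores, calib, sub_cfg)
        merged = subnetworks.merge_modules(
            modules, scores, calib, anneal_cfg.merge_jaccard)
        subnet_modules[s] = merged
        subnet_nodes[s] = set().union(*(m.nodes for m in merged)) if merged else set()
        if subnet_nodes[s]:
            hub_tables[s] = hubs.classify_hubs(
                sorted(subnet_nodes[s]), subset_net, hub_cfg,
                core_flags=core_flags,
                fold_changes=de[s].table["fold_change"])

    conc = hubs.concordance(modulators, subnet_nodes)

    return PipelineResult(
        counts=counts, truth=truth, factors=factors, dispersion=fit, de=de,
        cpm=cpm_table, weights=weights, ora=ora, clean_net=clean,
        expanded_net=expanded, modulators=modulators, de_venn=de_venn,
        subnet_modules=subnet_modules, subnet_nodes=subnet_nodes,
        hub_tables=hub_tables, concordance=conc,
    )
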