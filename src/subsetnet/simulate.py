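"""Synthetic data generators with planted ground truth.

Every generator is deterministic given ``SimulationConfig.seed``; each one
draws from its own numpy substream so the outputs are independent of the
order in which generators are called.

The simulated experiment mirrors the pipeline's target design: two cell
subsets (A and B), each measured once at steady state and once after
stimulation; negative-binomial counts sharing a per-gene baseline mean
across subsets; planted shared and subset-specific responders with a
multiplicative fold change; log-normal gene lengths with an optional
length-dependent bias in which genes respond; a scale-free interaction
network whose designated core signalling molecules are wired as
high-degree hubs; planted subset-specific modulators attached to those
cores; and annotation terms that oversample responders with a stated odds.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from subsetnet.config import ConfigurationError, SimulationConfig
from subsetnet.containers import SAMPLES, AnnotationSets, CountMatrix, GroundTruth

log = logging.getLogger(__name__)

UBC_NODE = "UBC_SYN"

_STREAM_COUNTS = 1
_STREAM_NETWORK = 2
_STREAM_ANNOTATIONS = 3
_STREAM_EXONS = 4
_STREAM_ALIGNMENTS = 5


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), stream])


def gene_ids(cfg: SimulationConfig) -> list:
    """Synthetic symbols: reserved core names first, then G-numbered genes."""
    width = max(2, len(str(cfg.n_core)))
    cores = [f"CORE{i + 1:0{width}d}" for i in range(cfg.n_core)]
    rest = [f"G{i + 1:06d}" for i in range(cfg.n_core, cfg.n_genes)]
    return cores + rest


def _weighted_sample_without_replacement(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Successive weighted sampling without replacement (exponential race).

    Equivalent to the noncentral (Wallenius) urn process: at each draw the
    selection probability is proportional to the weight among the items
    still in the urn.
    """
    keys = rng.standard_exponential(len(weights)) / weights
    return np.argpartition(keys, k)[:k]


def gen_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate the 4-sample count matrix and its planted ground truth.

    Planted responder numbers use floor(): ``floor(frac_shared_de*n_genes)``
    shared genes plus ``floor(frac_subset_de*n_genes)`` per subset.  With
    ``fold_change == 1`` nothing is planted and all truth labels are off.
    """
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    ids = gene_ids(cfg)
    n = cfg.n_genes

    lengths = np.round(
        rng.lognormal(math.log(cfg.length_median), cfg.length_log_sd, n)
    ).clip(min=200.0)
    mu = rng.lognormal(math.log(cfg.baseline_mean), cfg.mean_log_sd, n)
    size_factors = rng.uniform(0.7, 1.3, len(SAMPLES))

    de = pd.DataFrame("none", index=ids, columns=["de_A", "de_B"])
    modulator_of = pd.Series("", index=ids)
    core_flag = pd.Series(False, index=ids)
    core_flag.iloc[: cfg.n_core] = True

    n_shared = math.floor(cfg.frac_shared_de * n)
    n_sub = math.floor(cfg.frac_subset_de * n)
    if cfg.fold_change > 1 and (n_shared or n_sub):
        # Cores are deliberately never planted as responders: the design the
        # generator emulates found the core signalling machinery comparably
        # expressed in both subsets.
        eligible = np.arange(cfg.n_core, n)
        need = n_shared + 2 * n_sub
        if need > len(eligible):
            raise ConfigurationError("not enough non-core genes to plant DE")
        logl = np.log(lengths[eligible])
        w = np.exp(cfg.length_bias_strength * (logl - logl.mean()))
        picked = eligible[_weighted_sample_without_replacement(rng, w, need)]
        shared = picked[:n_shared]
        only_a = picked[n_shared: n_shared + n_sub]
        only_b = picked[n_shared + n_sub:]
        direction = np.where(rng.random(need) < cfg.prob_up, "up", "down")
        dir_by_gene = dict(zip(picked, direction))
        for g in shared:
            de.iloc[g, 0] = de.iloc[g, 1] = dir_by_gene[g]
        for g in only_a:
            de.iloc[g, 0] = dir_by_gene[g]
        for g in only_b:
            de.iloc[g, 1] = dir_by_gene[g]

        for subset, pool in (("A", only_a), ("B", only_b)):
            n_mod = min(cfg.n_modulators_per_subset, len(pool))
            if n_mod < cfg.n_modulators_per_subset:
                log.warning(
                    "only %d subset-%s-specific genes available for %d modulators",
                    len(pool), subset, cfg.n_modulators_per_subset,
                )
            mods = rng.choice(pool, size=n_mod, replace=False)
            modulator_of.iloc[mods] = subset

    # Expected counts: mu_gene * s_sample, fold change applied
    # multiplicatively in the stimulated sample of the planted subset(s).
    mean = np.outer(mu, size_factors)
    fc_mult = {"none": 1.0, "up": cfg.fold_change, "down": 1.0 / cfg.fold_change}
    for j, subset in ((1, "A"), (3, "B")):  # stimulated columns
        mult = de[f"de_{subset}"].map(fc_mult).to_numpy()
        mean[:, j] *= mult

    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=list(SAMPLES)),
        lengths=pd.Series(lengths, index=ids, name="length"),
    )
    genes = pd.DataFrame(
        {
            "length": lengths,
            "mu": mu,
            "core": core_flag,
            "de_A": de["de_A"],
            "de_B": de["de_B"],
            "modulator_of": modulator_of,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return cm, GroundTruth(genes=genes)


def gen_network(cfg: SimulationConfig, truth: GroundTruth) -> nx.Graph:
    """Scale-free interaction network with core hubs and attached modulators.

    Construction: a clique over the core molecules seeds preferential
    attachment (``net_attach_m`` edges per new node); modulators of each
    subset are chained into a sparse community and guaranteed at least one
    edge to a core; a promiscuous ``UBC_SYN`` node with degree >=
    ``ubc_degree_frac * n_genes`` is added for cleaning tests.
    """
    ids = gene_ids(cfg)
    if list(truth.genes.index) != ids:
        raise ValueError("gene universe of truth does not match the configuration")
    rng = _rng(cfg.seed, _STREAM_NETWORK)

    m = min(cfg.net_attach_m, cfg.n_core)
    initial = nx.complete_graph(max(cfg.n_core, 2))
    g_int = nx.barabasi_albert_graph(
        cfg.n_genes, m, seed=int(rng.integers(2**31)), initial_graph=initial
    )
    net = nx.relabel_nodes(g_int, dict(enumerate(ids)))

    cores = truth.cores
    for subset in ("A", "B"):
        mods = sorted(truth.modulators(subset))
        for a, b in zip(mods, mods[1:]):  # sparse intra-community chain
            net.add_edge(a, b)
        for mod in mods:
            if not any(net.has_edge(mod, c) for c in cores):
                net.add_edge(mod, cores[int(rng.integers(len(cores)))])

    k_ubc = math.ceil(cfg.ubc_degree_frac * cfg.n_genes)
    partners = rng.choice(cfg.n_genes, size=k_ubc, replace=False)
    net.add_edges_from((UBC_NODE, ids[i]) for i in partners)

    # Guarantee that cores sit at or above the 90th degree percentile (holds
    # by construction at default scale; topped up for tiny toy configs).
    for _ in range(3):
        degs = np.array([d for _, d in net.degree()])
        q90 = float(np.percentile(degs, 90))
        short = [c for c in cores if net.degree(c) < q90]
        if not short:
            break
        non_core = [g for g in ids if g not in set(cores)]
        for c in short:
            while net.degree(c) < q90:
                cand = non_core[int(rng.integers(len(non_core)))]
                if cand != c:
                    net.add_edge(c, cand)
    return net


def gen_annotations(cfg: SimulationConfig, truth: GroundTruth) -> AnnotationSets:
    """Annotation terms with planted enrichment for responders.

    Each configured term of size s is drawn from the gene universe by a
    noncentral urn in which genes responding in either subset carry the
    term's planted odds; odds 1 terms are unbiased nulls.  One extra null
    term (``TERM_LONG``) oversamples long genes to exercise the
    length-bias correction downstream.  Updates ``truth.terms`` in place.
    """
    rng = _rng(cfg.seed, _STREAM_ANNOTATIONS)
    ids = np.array(truth.genes.index)
    de_union = ((truth.genes["de_A"] != "none") | (truth.genes["de_B"] != "none"))
    de_union = de_union.to_numpy()
    sources = ["GO", "Reactome", "TF-target"]

    terms, meta_rows, truth_rows = {}, [], []
    for i, (size, odds) in enumerate(zip(cfg.term_sizes, cfg.term_odds)):
        if size > cfg.n_genes:
            raise ConfigurationError("term size exceeds gene universe")
        name = f"TERM{i + 1:02d}"
        w = np.where(de_union, float(odds), 1.0)
        members = ids[_weighted_sample_without_replacement(rng, w, int(size))]
        terms[name] = set(members)
        meta_rows.append((name, f"synthetic term {i + 1} (odds {odds})", sources[i % 3]))
        truth_rows.append((name, int(size), float(odds), odds > 1))

    logl = np.log(truth.genes["length"].to_numpy())
    w_long = np.exp(2.0 * (logl - logl.mean()) / logl.std())
    size_long = min(50, cfg.n_genes)
    terms["TERM_LONG"] = set(ids[_weighted_sample_without_replacement(rng, w_long, size_long)])
    meta_rows.append(("TERM_LONG", "long-gene-biased null term", "GO"))
    truth_rows.append(("TERM_LONG", size_long, 1.0, False))

    meta = pd.DataFrame(meta_rows, columns=["term", "name", "source"]).set_index("term")
    truth.terms = pd.DataFrame(
        truth_rows, columns=["term", "size", "odds", "enriched"]
    ).set_index("term")
    return AnnotationSets(terms=terms, meta=meta)


def gen_planted_module(seed: int, n_nodes: int = 500, module_size: int = 15,
                       bg_mean_degree: float = 1.0, n_bridges: int = 2):
    """Planted-module instance for active-subnetwork recovery tests.

    The module emulates a signalling scaffold: weakly-changed scaffold
    nodes (largest p within the module) form an interior chain, while the
    strongly-responsive effectors attach to it as leaves -- the structure
    score-and-search subnetwork methods are designed to rescue.  Module
    p-values ~ Beta(0.2, 3); the sparse background (Erdos-Renyi, mean
    degree ``bg_mean_degree``) carries p ~ U(0,1) and is connected to the
    module by ``n_bridges`` edges.  Returns (net, p_values, module_set).
    """
    import networkx as _nx

    rng = np.random.default_rng([int(seed), 6])
    n_bg = n_nodes - module_size
    bg = _nx.gnp_random_graph(n_bg, bg_mean_degree / max(n_bg - 1, 1),
                              seed=int(rng.integers(2**31)))
    net = _nx.relabel_nodes(bg, lambda x: x + module_size)
    p_mod = rng.beta(0.2, 3.0, module_size)
    order = np.argsort(-p_mod)
    n_backbone = max(2, module_size // 3)
    backbone = [int(x) for x in order[:n_backbone]]
    for a, b in zip(backbone, backbone[1:]):
        net.add_edge(a, b)
    for leaf in order[n_backbone:]:
        net.add_edge(int(leaf), backbone[int(rng.integers(n_backbone))])
    for _ in range(n_bridges):
        net.add_edge(int(rng.integers(module_size)),
                     int(rng.integers(module_size, n_nodes)))
    p = pd.Series(rng.uniform(0.0, 1.0, n_nodes), index=range(n_nodes))
    p.iloc[:module_size] = p_mod
    return net, p, set(range(module_size))


# ---------------------------------------------------------------------------
# Toy genome: exon tables and alignment intervals for the counting stage.
# ---------------------------------------------------------------------------

def gen_exon_table(n_genes: int = 30, seed: int = 0) -> pd.DataFrame:
    """Toy exon table (0-based half-open) with structures the counter must face.

    Includes multi-transcript genes with partially overlapping exons, a
    non-protein-coding transcript per ~4th gene, one fully non-coding gene,
    and every 6th gene pair overlapping on the chromosome so that
    gene-ambiguous reads exist.
    """
    rng = np.random.default_rng([seed, _STREAM_EXONS])
    rows = []
    cursor = 1000
    prev_last_exon = None
    for gi in range(n_genes):
        gene = f"TG{gi + 1:04d}"
        if gi % 6 == 5 and prev_last_exon is not None:
            start = prev_last_exon[0] + 50  # overlap previous gene's last exon
        else:
            start = cursor + int(rng.integers(200, 800))
        n_ex = int(rng.integers(2, 6))
        exons = []
        pos = start
        for _ in range(n_ex):
            length = int(rng.integers(100, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(100, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lincRNA" if gi == n_genes - 1 else "protein_coding"
        rows += [(gene, f"{gene}.t1", "chr1", s, e, strand, biotype) for s, e in exons]
        if biotype == "protein_coding" and n_ex >= 3 and rng.random() < 0.5:
            # second transcript: a subset of exons, one shifted to overlap
            sub = exons[: n_ex - 1]
            s0, e0 = sub[0]
            sub[0] = (s0 + 50, e0 + 50)
            rows += [(gene, f"{gene}.t2", "chr1", s, e, strand, biotype) for s, e in sub]
        if gi % 4 == 3:
            s0, e0 = exons[0]
            rows.append((gene, f"{gene}.nc", "chr1", s0 - 60, e0, strand, "lincRNA"))
        prev_last_exon = exons[-1]
        cursor = exons[-1][1]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "biotype"],
    )


def gen_alignments(model, depth: float = 20.0, seed: int = 0,
                   read_len: int = 80) -> tuple[pd.DataFrame, pd.Series]:
    """Alignment intervals with truth labels for the counting stage.

    ``model`` is a :class:`subsetnet.genemodel.ChimericGeneModel`.  Returns
    (records, labels): BED-like records (chrom, start, end, strand, read_id,
    multiplicity) and a read_id-indexed truth label series with values
    ``countable:<gene>``, ``ambiguous``, ``multimapped`` or ``no_feature``.
    Countable reads are placed only in exonic bases exclusive to one gene;
    ambiguous reads are constructed to span exons of two distinct genes.
    """
    rng = np.random.default_rng([seed, _STREAM_ALIGNMENTS])
    rows, labels = [], {}
    rid = 0

    def emit(chrom, s, e, mult, label):
        nonlocal rid
        rid += 1
        name = f"r{rid:06d}"
        rows.append((chrom, int(s), int(e), "+" if rng.random() < 0.5 else "-",
                     name, int(mult)))
        labels[name] = label

    exclusive = model.exclusive_intervals()
    for gene, ivs in exclusive.items():
        chrom = model.chrom(gene)
        usable = [(s, e) for s, e in ivs if e - s >= 20]
        if not usable:
            continue
        lens = np.array([e - s for s, e in usable], dtype=float)
        for _ in range(rng.poisson(depth)):
            s, e = usable[rng.choice(len(usable), p=lens / lens.sum())]
            L = min(read_len, e - s)
            start = s + int(rng.integers(0, e - s - L + 1))
            emit(chrom, start, start + L, 1, f"countable:{gene}")

    for _ga, _gb, chrom, lo, hi, kind in model.overlapping_gene_pairs():
        if kind == "shared":
            # read fully inside the doubly-exonic region: every base maps
            # to both genes
            for _ in range(3):
                L = min(read_len, hi - lo)
                start = lo + int(rng.integers(0, hi - lo - L + 1))
                emit(chrom, start, start + L, 1, "ambiguous")
        elif hi - lo <= 2 * read_len:
            # read covering exclusive bases of both genes across the gap
            for _ in range(3):
                pad = int(rng.integers(1, 10))
                emit(chrom, max(0, lo - pad), hi + pad, 1, "ambiguous")

    genes = list(exclusive)
    for _ in range(max(3, int(depth // 4))):
        gene = genes[int(rng.integers(len(genes)))]
        ivs = [(s, e) for s, e in exclusive[gene] if e - s >= 20]
        if not ivs:
            continue
        s, e = ivs[int(rng.integers(len(ivs)))]
        L = min(read_len, e - s)
        emit(model.chrom(gene), s, s + L, int(rng.integers(2, 4)), "multimapped")
        gaps = model.intron_gaps(gene)
        if gaps:
            gs, ge = gaps[int(rng.integers(len(gaps)))]
            tree = model.tree(model.chrom(gene))
            if ge - gs > read_len + 10 and not tree.overlap(gs + 5, gs + 5 + read_len):
                emit(model.chrom(gene), gs + 5, gs + 5 + read_len, 1, "no_feature")

    records = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "read_id", "multiplicity"]
    )
    return records, pd.Series(labels, name="truth_label")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_alignments_bed(records: pd.DataFrame, path) -> None:
    """BED6 + integer multiplicity column."""
    out = records[["chrom", "start", "end", "read_id"]].copy()
    out["score"] = 0
    out["strand"] = records["strand"]
    out["multiplicity"] = records["multiplicity"]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_alignments_bed(path) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "read_id", "score", "strand", "multiplicity"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return df[["chrom", "start", "end", "strand", "read_id", "multiplicity"]]


def write_network_sif(net: nx.Graph, path, relation: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(map(sorted, net.edges())):
            fh.write(f"{a}\t{relation}\t{b}\n")


def write_dataset(outdir, cfg: SimulationConfig) -> dict:
    """Run every generator and write the full dataset under ``outdir``.

    Returns the in-memory objects as a dict (counts, truth, network,
    annotations).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, truth = gen_counts(cfg)
    net = gen_network(cfg, truth)
    ann = gen_annotations(cfg, truth)

    counts.to_tsv(outdir / "counts.tsv")
    truth.to_tsv(outdir / "truth_genes.tsv")
    truth.terms.to_csv(outdir / "truth_terms.tsv", sep="\t")
    write_network_sif(net, outdir / "network.sif")
    nx.to_pandas_edgelist(net).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    ann.to_gmt(outdir / "annotations.gmt")
    with open(outdir / "core_molecules.txt", "w") as fh:
        fh.write("\n".join(truth.cores) + "\n")
    return {"counts": counts, "truth": truth, "network": net, "annotations": ann}
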