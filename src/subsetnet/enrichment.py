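"""Over-representation analysis with length-bias correction.

Long transcripts accumulate more reads and are therefore more likely to
be called differentially expressed at a fixed effect size; a term full of
long genes would look enriched for purely technical reasons.  The
correction fits a monotone probability-weighting function P(DE | length)
and tests each term under the Wallenius noncentral hypergeometric
distribution with the term's mean-weight odds, reducing to the central
hypergeometric when weights are flat.

The odds ratio reported per term is the odds of a DE gene occurring in
the term divided by the odds of a non-DE gene occurring in the term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression

from subsetnet.containers import AnnotationSets
from subsetnet.diffexpr import bh_adjust

log = logging.getLogger(__name__)

MIN_OBSERVED = 10  # terms with fewer observed DE genes in BOTH subsets are dropped


@dataclass
class WeightingFunction:
    """Monotone non-decreasing map from gene length to selection weight.

    Weights are positive and rescaled to mean 1 over the fitted universe.
    """

    lengths: np.ndarray       # sorted unique support (log scale)
    weights_at: np.ndarray    # fitted weight at each support point
    per_gene: pd.Series       # weight for every gene in the universe

    def __call__(self, length) -> np.ndarray:
        logl = np.log(np.asarray(length, dtype=float))
        return np.interp(logl, self.lengths, self.weights_at)


def fit_weighting(de_flags: pd.Series, lengths: pd.Series,
                  n_bins: int = 40) -> WeightingFunction:
    """Fit P(DE | length) by binned proportions + isotonic smoothing.

    Requires >= 50 genes and both DE and non-DE genes present.
    """
    de_flags = de_flags.astype(bool)
    lengths = lengths.reindex(de_flags.index).astype(float)
    if len(de_flags) < 50:
        raise ValueError("need at least 50 genes to fit the weighting function")
    if de_flags.all() or not de_flags.any():
        raise ValueError("need both DE and non-DE genes to fit length bias")

    logl = np.log(lengths.to_numpy())
    n_bins = min(n_bins, max(2, len(de_flags) // 10))
    edges = np.unique(np.quantile(logl, np.linspace(0, 1, n_bins + 1)))
    idx = np.clip(np.searchsorted(edges, logl, side="right") - 1, 0, len(edges) - 2)
    flags = de_flags.to_numpy()
    centers, props, sizes = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        if mask.any():
            centers.append(logl[mask].mean())
            props.append(flags[mask].mean())
            sizes.append(mask.sum())
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(centers, props, sample_weight=sizes)
    fitted = np.maximum(fitted, 1e-6)

    raw = np.interp(logl, centers, fitted)
    norm = raw.mean()  # rescale so the mean weight over the universe is 1
    return WeightingFunction(
        lengths=np.asarray(centers),
        weights_at=fitted / norm,
        per_gene=pd.Series(raw / norm, index=de_flags.index, name="weight"),
    )


@dataclass
class ORARow:
    term: str
    n_de_in: int
    n_de_out: int
    n_nonde_in: int
    n_nonde_out: int
    odds_ratio: float
    odds_w: float
    p_raw: float


def wallenius_ora(de_set: set, term_genes: set, universe: set,
                  weights: pd.Series | None = None, term: str = "") -> ORARow:
    """Upper-tail Wallenius test of DE over-representation in one term.

    The urn draws the |DE| genes from the universe with odds
    w = mean weight inside the term / mean weight outside; the p-value is
    P(X >= observed DE-in-term).  Degenerate 2x2 tables (an empty row or
    column) give p = 1 and an undefined (NaN) odds ratio.
    """
    uni = set(universe)
    de = set(de_set) & uni
    members = set(term_genes) & uni
    if not members:
        raise ValueError("term does not intersect the universe")
    n = len(uni)
    n_de_in = len(de & members)
    n_de_out = len(de) - n_de_in
    n_nonde_in = len(members) - n_de_in
    n_nonde_out = n - n_de_in - n_de_out - n_nonde_in

    if weights is None:
        odds_w = 1.0
    else:
        w = weights.reindex(sorted(uni)).to_numpy(dtype=float)
        in_mask = np.array([g in members for g in sorted(uni)])
        mean_in = w[in_mask].mean()
        mean_out = w[~in_mask].mean() if (~in_mask).any() else mean_in
        odds_w = float(mean_in / mean_out)

    degenerate = (len(de) == 0 or len(de) == n or len(members) == n)
    if degenerate:
        p = 1.0
        odds_ratio = float("nan")
    else:
        p = float(nchypergeom_wallenius.sf(
            n_de_in - 1, n, len(members), len(de), odds_w))
        with np.errstate(divide="ignore", invalid="ignore"):
            odds_ratio = float(np.float64(n_de_in) / n_de_out
                               / (np.float64(n_nonde_in) / n_nonde_out))
    return ORARow(term, n_de_in, n_de_out, n_nonde_in, n_nonde_out,
                  odds_ratio, odds_w, min(max(p, 0.0), 1.0))


def run_ora(de_sets_by_subset: dict, annotations: AnnotationSets, universe: set,
            weights_by_subset: dict | None = None,
            min_observed: int = MIN_OBSERVED,
            alpha: float = 0.05) -> pd.DataFrame:
    """Side-by-side ORA over two subsets' DE sets.

    Terms in which fewer than ``min_observed`` DE genes are observed in
    BOTH subsets are excluded before testing; BH adjustment runs within
    each (subset, annotation source) family over the retained terms.
    """
    if len(annotations) == 0:
        raise ValueError("empty annotation set")
    subsets = list(de_sets_by_subset)
    ann = annotations.restrict(universe)

    observed = {
        t: {s: len(ann.terms[t] & set(de_sets_by_subset[s])) for s in subsets}
        for t in ann.terms
    }
    retained = [t for t in ann.terms
                if any(observed[t][s] >= min_observed for s in subsets)]
    if not retained:
        log.warning("no annotation term passed the >=%d observed filter", min_observed)

    rows = []
    for t in retained:
        row = {"term": t,
               "name": ann.meta.loc[t, "name"],
               "source": ann.meta.loc[t, "source"],
               "n_term": len(ann.terms[t])}
        for s in subsets:
            r = wallenius_ora(de_sets_by_subset[s], ann.terms[t], universe,
                              None if weights_by_subset is None
                              else weights_by_subset[s], term=t)
            row[f"de_in_{s}"] = r.n_de_in
            row[f"odds_ratio_{s}"] = r.odds_ratio
            row[f"p_raw_{s}"] = r.p_raw
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.set_index("term")
        for s in subsets:
            for src in table["source"].unique():
                fam = table.index[table["source"] == src]
                table.loc[fam, f"p_adj_{s}"] = bh_adjust(table.loc[fam, f"p_raw_{s}"])
            table[f"significant_{s}"] = table[f"p_adj_{s}"] <= alpha
    return table


def write_ora_tsv(table: pd.DataFrame, path, subsets=("A", "B")) -> None:
    """Table-style TSV: per-subset adjusted p and odds ratio, '*' marking
    terms NOT significant in that subset."""
    out = table.copy()
    for s in subsets:
        if f"significant_{s}" in out:
            out[f"flag_{s}"] = np.where(out[f"significant_{s}"], "", "*")
    out.to_csv(path, sep="\t")


@dataclass
class OverlapTestResult:
    universe_size: int
    n_a: int
    n_b: int
    overlap: int
    p: float

    @property
    def inverse_p(self) -> float:
        return 1.0 / self.p

    def as_dict(self) -> dict:
        return {"universe": self.universe_size, "n_a": self.n_a, "n_b": self.n_b,
                "overlap": self.overlap, "p": self.p, "inverse_p": self.inverse_p}


def overlap_test(list_a, list_b, universe) -> OverlapTestResult:
    """Hypergeometric upper-tail significance of the overlap of two lists.

    p = P(X >= k) for X ~ Hypergeom(N, |A|, |B|); symmetric in (A, B).
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    stray = (a | b) - uni
    if stray:
        raise ValueError(f"lists contain genes outside the universe: {sorted(stray)[:10]}")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(uni), len(a), len(b)))
    return OverlapTestResult(len(uni), len(a), len(b), k, min(max(p, 1e-300), 1.0))
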