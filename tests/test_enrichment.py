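"""Length-bias weighting, Wallenius ORA, term filtering, overlap test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from subsetnet import enrichment, simulate
from subsetnet.config import SimulationConfig
from subsetnet.containers import AnnotationSets


def wallenius_recursion_sf(k, n_total, n_white, n_draws, odds):
    """Exact upper-tail Wallenius probability by urn recursion.

    State: probability of having drawn w whites after t draws; each draw
    takes a white with probability proportional to odds * remaining
    whites.  Independent of the implementation under test.
    """
    probs = {0: 1.0}
    for t in range(n_draws):
        nxt = {}
        for w, p in probs.items():
            blacks_left = (n_total - n_white) - (t - w)
            whites_left = n_white - w
            z = odds * whites_left + blacks_left
            if whites_left > 0:
                nxt[w + 1] = nxt.get(w + 1, 0.0) + p * odds * whites_left / z
            if blacks_left > 0:
                nxt[w] = nxt.get(w, 0.0) + p * blacks_left / z
        probs = nxt
    return sum(p for w, p in probs.items() if w >= k)


class TestFitWeighting:
    def _universe(self, n, seed, slope=0.0, base=0.1):
        rng = np.random.default_rng(seed)
        lengths = pd.Series(rng.lognormal(7.3, 0.7, n),
                            index=[f"g{i}" for i in range(n)])
        z = (np.log(lengths) - np.log(lengths).mean()) / np.log(lengths).std()
        prob = 1 / (1 + np.exp(-(math.log(base / (1 - base)) + slope * z)))
        flags = pd.Series(rng.random(n) < prob, index=lengths.index)
        return flags, lengths

    def test_flat_bias_gives_near_unit_weights(self):
        flags, lengths = self._universe(5000, seed=2, slope=0.0)
        w = enrichment.fit_weighting(flags, lengths)
        assert w.per_gene.between(0.8, 1.25).all()
        assert w.per_gene.mean() == pytest.approx(1.0)

    def test_fitted_function_is_monotone(self):
        flags, lengths = self._universe(3000, seed=3, slope=1.0)
        w = enrichment.fit_weighting(flags, lengths)
        assert (np.diff(w.weights_at) >= -1e-12).all()

    def test_planted_slope_direction_recovered(self):
        flags, lengths = self._universe(5000, seed=4, slope=1.0)
        w = enrichment.fit_weighting(flags, lengths)
        short = w(lengths.quantile(0.05))
        long = w(lengths.quantile(0.95))
        assert long > 1.5 * short

    def test_degenerate_inputs_rejected(self):
        flags, lengths = self._universe(200, seed=5)
        with pytest.raises(ValueError, match="50 genes"):
            enrichment.fit_weighting(flags.iloc[:30], lengths.iloc[:30])
        with pytest.raises(ValueError, match="both"):
            enrichment.fit_weighting(pd.Series(True, index=flags.index), lengths)


class TestWalleniusOra:
    def _instance(self, rng):
        n = int(rng.integers(30, 400))
        universe = {f"g{i}" for i in range(n)}
        term = set(rng.choice(sorted(universe), int(rng.integers(1, n // 2)),
                              replace=False))
        de = set(rng.choice(sorted(universe), int(rng.integers(1, n // 2)),
                            replace=False))
        return universe, term, de

    def test_equal_weights_reduce_to_hypergeometric(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            universe, term, de = self._instance(rng)
            row = enrichment.wallenius_ora(de, term, universe, weights=None)
            expect = hypergeom.sf(row.n_de_in - 1, len(universe), len(term),
                                  len(de))
            assert row.p_raw == pytest.approx(float(expect), abs=1e-6)

    def test_matches_exact_urn_recursion(self):
        """Dual route: scipy-backed Wallenius vs an independent urn
        recursion, at odds away from 1."""
        rng = np.random.default_rng(13)
        for odds in (0.5, 2.0, 6.0):
            for _ in range(10):
                n = int(rng.integers(20, 60))
                m = int(rng.integers(2, n - 2))
                dd = int(rng.integers(2, n - 2))
                uni = {f"g{i}" for i in range(n)}
                term = set(sorted(uni)[:m])
                de = set(rng.choice(sorted(uni), dd, replace=False))
                w = pd.Series(1.0, index=sorted(uni))
                w[sorted(term)] = odds
                row = enrichment.wallenius_ora(de, term, uni, weights=w)
                expect = wallenius_recursion_sf(
                    row.n_de_in, n, m, dd, row.odds_w)
                assert row.p_raw == pytest.approx(expect, abs=5e-4)

    def test_odds_ratio_footnote_formula(self):
        # 2x2 table: DE-in 20, DE-out 180, nonDE-in 60, nonDE-out 1740
        universe = {f"g{i}" for i in range(2000)}
        genes = sorted(universe)
        de = set(genes[:200])
        term = set(genes[:20]) | set(genes[200:260])
        row = enrichment.wallenius_ora(de, term, universe)
        assert (row.n_de_in, row.n_de_out, row.n_nonde_in, row.n_nonde_out) \
            == (20, 180, 60, 1740)
        assert row.odds_ratio == pytest.approx((20 / 180) / (60 / 1740))
        assert row.odds_ratio == pytest.approx(3.2222, abs=1e-3)

    def test_cells_sum_to_universe(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            universe, term, de = self._instance(rng)
            row = enrichment.wallenius_ora(de, term, universe)
            assert (row.n_de_in + row.n_de_out + row.n_nonde_in
                    + row.n_nonde_out) == len(universe)

    def test_odds_ratio_direction_equivalence(self):
        """odds_ratio > 1 iff the DE proportion inside the term exceeds the
        proportion outside."""
        rng = np.random.default_rng(19)
        for _ in range(50):
            universe, term, de = self._instance(rng)
            row = enrichment.wallenius_ora(de, term, universe)
            if not np.isfinite(row.odds_ratio):
                continue
            inside = row.n_de_in / (row.n_de_in + row.n_nonde_in)
            outside = row.n_de_out / (row.n_de_out + row.n_nonde_out)
            assert (row.odds_ratio > 1) == (inside > outside) or \
                inside == outside

    def test_degenerate_table_p_one_or_nan(self):
        universe = {f"g{i}" for i in range(50)}
        row = enrichment.wallenius_ora(set(), set(sorted(universe)[:5]), universe)
        assert row.p_raw == 1.0 and math.isnan(row.odds_ratio)


class TestRunOra:
    def _annotations(self, terms):
        meta = pd.DataFrame(
            [(t, t, "GO") for t in terms],
            columns=["term", "name", "source"]).set_index("term")
        return AnnotationSets(terms=terms, meta=meta)

    def test_under_ten_in_both_subsets_excluded(self):
        genes = [f"g{i}" for i in range(400)]
        universe = set(genes)
        # term t9: 9 DE observed in each subset; t12: 9 in A, 12 in B
        de_a = set(genes[:9]) | set(genes[100:109])
        de_b = set(genes[:9]) | set(genes[100:112])
        ann = self._annotations({
            "t9": set(genes[:9]) | set(genes[200:220]),
            "t12": set(genes[100:112]) | set(genes[220:240]),
        })
        table = enrichment.run_ora({"A": de_a, "B": de_b}, ann, universe)
        assert "t9" not in table.index      # < 10 observed in both
        assert "t12" in table.index         # 12 observed in B retains it

    def test_undersized_term_can_never_pass_filter(self, tiny_ann, tiny_data):
        _, truth = tiny_data
        universe = set(truth.genes.index)
        de = {s: truth.de_set(s) for s in "AB"}
        table = enrichment.run_ora(de, tiny_ann, universe, min_observed=5)
        small = truth.terms.index[truth.terms["size"] == 8]
        # size-8 terms hold at most 8 DE genes; with the standard >=10
        # filter they are always excluded
        table10 = enrichment.run_ora(de, tiny_ann, universe)
        assert not set(small) & set(table10.index)

    def test_empty_annotations_rejected(self):
        ann = AnnotationSets(terms={}, meta=pd.DataFrame(
            columns=["name", "source"]))
        with pytest.raises(ValueError, match="empty"):
            enrichment.run_ora({"A": set(), "B": set()}, ann, set())

    def test_planted_terms_recovered(self):
        """At planted odds 6 with a 10% DE universe (500 of 5000), every
        size-50 enriched term is recovered at adjusted p <= 0.05."""
        hits, total = 0, 0
        for seed in (101, 102):
            cfg = SimulationConfig(frac_shared_de=0.08, frac_subset_de=0.01,
                                   seed=seed)
            _, truth = simulate.gen_counts(cfg)
            ann = simulate.gen_annotations(cfg, truth)
            universe = set(truth.genes.index)
            de = {s: truth.de_set(s) for s in "AB"}
            table = enrichment.run_ora(de, ann, universe)
            enriched = truth.terms.index[truth.terms["enriched"]]
            for term in enriched:
                total += 1
                if term in table.index and bool(
                        table.loc[term, ["significant_A", "significant_B"]].any()):
                    hits += 1
            null_flagged = [
                t for t in table.index
                if not truth.terms.loc[t, "enriched"]
                and bool(table.loc[t, ["significant_A", "significant_B"]].any())
            ]
            assert len(null_flagged) <= 1
        assert hits / total >= 0.9


class TestOverlapTest:
    def test_complete_overlap_of_three(self):
        universe = set(range(10))
        res = enrichment.overlap_test({0, 1, 2}, {0, 1, 2}, universe)
        assert res.p == pytest.approx(1 / 120)
        assert res.inverse_p == pytest.approx(120)

    def test_zero_overlap_is_certain(self):
        res = enrichment.overlap_test({0, 1}, {2, 3}, set(range(10)))
        assert res.p == 1.0

    def test_matches_exhaustive_enumeration(self):
        """All placements of list B against a fixed list A on a small
        universe, counted directly."""
        universe = list(range(20))
        a = set(universe[:6])
        n_b = 5
        for k_obs in range(0, 5):
            more_extreme = 0
            total = 0
            for comb in itertools.combinations(universe, n_b):
                total += 1
                if len(a & set(comb)) >= k_obs:
                    more_extreme += 1
            b = set(universe[:k_obs]) | set(universe[10:10 + n_b - k_obs])
            res = enrichment.overlap_test(a, b, set(universe))
            assert res.overlap == k_obs
            assert res.p == pytest.approx(more_extreme / total, rel=1e-9)

    def test_symmetric_in_lists(self):
        rng = np.random.default_rng(23)
        universe = set(range(100))
        for _ in range(20):
            a = set(rng.choice(100, 20, replace=False))
            b = set(rng.choice(100, 35, replace=False))
            p1 = enrichment.overlap_test(a, b, universe).p
            p2 = enrichment.overlap_test(b, a, universe).p
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_stray_genes_reported(self):
        with pytest.raises(ValueError, match="outside the universe"):
            enrichment.overlap_test({"x"}, {"y"}, {"y"})
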