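"""Single-replicate negative-binomial differential expression.

The model follows the classic count-based DE approach for experiments
without replicates: median-of-ratios size factors, a "blind" mean-variance
trend pooled over ALL samples (conditions ignored, so condition effects
inflate the trend and make the test deliberately conservative), and an
exact two-sided test on the observed pair of counts conditional on their
sum, with per-gene empirical variances never overriding the fitted trend
("fit-only" sharing).

Variance parameterisation: v(mu) = mu + (a0 + a1*mu)*mu, i.e. dispersion
d(mu) = a0/mu + a1 so that v = mu + d*mu^2; the raw per-gene dispersion
estimates are fitted by a gamma-family GLM with identity link on
(1, 1/mu).  A lowess fit on the same pairs is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from statsmodels.stats.multitest import multipletests

from subsetnet.config import DEConfig
from subsetnet.containers import CountMatrix

log = logging.getLogger(__name__)

_DISP_FLOOR = 1e-8        # enforces v(mu) >= mu * (1 + eps)
_EXACT_TOTAL = 10_000     # full enumeration below this total
_PRUNE_LOGDROP = 60.0     # beyond, prune where log pmf < max - 60 (mass < 1e-26)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    return multipletests(arr, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios normalisation factors.

    s_j = median over genes g (nonzero in every sample) of
    k_gj / (prod_v k_gv)^(1/m).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    k = df.to_numpy(dtype=float)
    allpos = (k > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; pre-filter the matrix"
        )
    logk = np.log(k[allpos])
    loggeo = logk.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logk - loggeo, axis=0))
    gm = float(np.exp(np.mean(np.log(s))))
    if abs(gm - 1.0) > 0.1:
        log.info("size-factor geometric mean %.3f deviates from 1", gm)
    return pd.Series(s, index=df.columns, name="size_factor")


@dataclass
class DispersionFit:
    """Fitted mean-variance trend, 'fit-only' mode.

    ``dispersion(mu)`` returns d(mu) >= _DISP_FLOOR; ``variance(mu)``
    returns mu + d(mu)*mu^2 (>= mu by construction).
    """

    coef_extra: float      # a0: extra-Poisson term, d = a0/mu + a1
    coef_asympt: float     # a1: asymptotic dispersion
    method: str
    base_means: pd.Series
    _lowess_xy: tuple | None = None

    def dispersion(self, mu):
        mu = np.asarray(mu, dtype=float)
        if self.method == "local" and self._lowess_xy is not None:
            x, y = self._lowess_xy
            d = np.exp(np.interp(np.log(np.maximum(mu, 1e-12)), x, y))
        else:
            d = self.coef_extra / np.maximum(mu, 1e-12) + self.coef_asympt
        return np.maximum(d, _DISP_FLOOR)

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu + self.dispersion(mu) * mu**2


def fit_blind_dispersion(counts: pd.DataFrame | CountMatrix,
                         factors: pd.Series,
                         method: str = "parametric") -> DispersionFit:
    """Pool ALL samples as pseudo-replicates and fit the variance trend.

    Per gene: pooled mean mu_g and empirical variance w_g of the
    normalised counts over ALL samples.  The trend is obtained by a
    gamma-family IRLS regression of w on (mu, mu^2); after removing the
    expected sampling part xi*mu (xi = mean(1/s_j)) the excess maps onto
    d(mu) = a0/mu + a1.  Fitting the variance directly (rather than
    per-gene dispersion estimates, which would have to be truncated at
    zero) keeps the trend unbiased when the data are Poisson-like.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("dispersion fit needs at least two samples")
    s = factors.reindex(df.columns).to_numpy(dtype=float)
    norm = df.to_numpy(dtype=float) / s
    mu = norm.mean(axis=1)
    w = norm.var(axis=1, ddof=1)
    xi = float(np.mean(1.0 / s))
    base_means = pd.Series(mu, index=df.index, name="base_mean")

    use = (mu > 0) & (w > 0)
    if use.sum() < 10:
        log.warning("too few informative genes; Poisson-like trend assumed")
        return DispersionFit(0.0, 0.0, "parametric", base_means)

    x_mu, y_w = mu[use], w[use]
    if method == "local":
        from statsmodels.nonparametric.smoothers_lowess import lowess
        d_raw = (y_w - xi * x_mu) / x_mu**2
        keep = d_raw > 0
        if keep.sum() < 10:
            return DispersionFit(0.0, 0.0, "local", base_means)
        order = np.argsort(x_mu[keep])
        fitted = lowess(np.log(d_raw[keep][order]), np.log(x_mu[keep][order]),
                        frac=0.4, return_sorted=True)
        return DispersionFit(0.0, 0.0, "local", base_means,
                             _lowess_xy=(fitted[:, 0], fitted[:, 1]))

    exog = np.column_stack([x_mu, x_mu**2])
    b1, b2 = _gamma_irls(y_w, exog)
    a0 = max(b1 - xi, 0.0)   # extra-Poisson linear excess
    a1 = max(b2, 0.0)        # asymptotic dispersion
    return DispersionFit(float(a0), float(a1), "parametric", base_means)


def _gamma_irls(y: np.ndarray, exog: np.ndarray) -> tuple[float, float]:
    """Gamma-family IRLS with identity link; falls back to OLS on failure."""
    import statsmodels.api as sm

    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # identity link outside Gamma domain
            model = sm.GLM(y, exog,
                           family=sm.families.Gamma(sm.families.links.Identity()))
            start = np.maximum(np.linalg.lstsq(exog, y, rcond=None)[0], 1e-6)
            res = model.fit(start_params=start, maxiter=100)
        coefs = res.params
    except Exception:  # noqa: BLE001 - any numerical failure
        log.warning("gamma IRLS failed; using least squares for the trend")
        coefs = np.linalg.lstsq(exog, y, rcond=None)[0]
    return float(coefs[0]), float(coefs[1])


def nb_exact_test(k_a: int, k_b: int, fit: DispersionFit,
                  s_a: float, s_b: float) -> float:
    """Exact conditional two-sided test of a single count pair.

    Under the null both samples share the base mean
    mu = (k_a/s_a + k_b/s_b)/2; counts are NB with mean mu*s_j and
    variance mu*s_j + d(mu)*(mu*s_j)^2.  The p-value sums P(a)P(b) over
    all splits a+b = k_a+k_b whose probability does not exceed the
    observed one, normalised by the total.  A zero total returns p = 1.
    """
    k_a, k_b = int(k_a), int(k_b)
    if k_a < 0 or k_b < 0:
        raise ValueError("counts must be non-negative")
    total = k_a + k_b
    if total == 0:
        return 1.0
    mu = 0.5 * (k_a / s_a + k_b / s_b)
    d = float(fit.dispersion(mu))
    mean_a, mean_b = mu * s_a, mu * s_b

    if total <= _EXACT_TOTAL:
        a = np.arange(total + 1)
    else:
        mode = int(total * mean_a / (mean_a + mean_b))
        a = _pruned_support(total, mode, k_a, mean_a, mean_b, d)

    lp = _log_pmf(a, mean_a, d) + _log_pmf(total - a, mean_b, d)
    obs = lp[a == k_a][0]
    den = logsumexp(lp)
    num = logsumexp(lp[lp <= obs + 1e-10])
    return float(min(1.0, np.exp(num - den)))


def _log_pmf(k, mean, d):
    if d <= _DISP_FLOOR * 1.01:
        return poisson.logpmf(k, mean)
    r = 1.0 / d
    return nbinom.logpmf(k, r, r / (r + mean))


def _pruned_support(total, mode, k_obs, mean_a, mean_b, d):
    """Support window around the (unimodal) summand's mode, expanded until
    the boundary log-pmf falls _PRUNE_LOGDROP below the maximum; the
    observed split is always included."""
    step = max(64, int(np.sqrt(total)))
    lo, hi = max(0, mode - step), min(total, mode + step)
    def lp_at(x):
        arr = _log_pmf(np.array([x]), mean_a, d) + _log_pmf(np.array([total - x]), mean_b, d)
        return float(arr[0])

    lp_mode = lp_at(mode)

    while lo > 0 and lp_at(lo) > lp_mode - _PRUNE_LOGDROP:
        lo = max(0, lo - step)
    while hi < total and lp_at(hi) > lp_mode - _PRUNE_LOGDROP:
        hi = min(total, hi + step)
    support = set(range(lo, hi + 1))
    support.add(k_obs)
    support.add(total - k_obs)
    return np.array(sorted(support))


@dataclass
class DEResult:
    """Per-gene DE table for one two-sample comparison."""

    table: pd.DataFrame   # mean_A, mean_B, fold_change, log2fc, p_raw, p_adj, call
    sample_a: str
    sample_b: str
    config: DEConfig

    def de_genes(self) -> set:
        return set(self.table.index[self.table["call"] != "ns"])

    def p_values(self) -> pd.Series:
        return self.table["p_raw"]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def _assign_calls(p: np.ndarray, fc: np.ndarray, cfg: DEConfig) -> np.ndarray:
    """Thresholds are inclusive: p <= alpha and fc >= min_fc (or <= 1/min_fc)."""
    call = np.full(len(p), "ns", dtype=object)
    sig = p <= cfg.alpha
    call[sig & (fc >= cfg.min_fold_change)] = "up"
    call[sig & (fc <= 1.0 / cfg.min_fold_change)] = "down"
    return call


def call_de(counts: CountMatrix, sample_a: str, sample_b: str,
            cfg: DEConfig | None = None,
            factors: pd.Series | None = None,
            fit: DispersionFit | None = None) -> DEResult:
    """Run the single-replicate test for one condition pair.

    Size factors and the blind dispersion trend are estimated from the
    FULL matrix (all samples pooled) unless supplied.  Genes with zero
    counts in every sample are excluded before testing.
    """
    cfg = cfg or DEConfig()
    for c in (sample_a, sample_b):
        if c not in counts.counts.columns:
            raise ValueError(f"sample column {c!r} absent from count matrix")
    if factors is None:
        factors = size_factors(counts)
    if fit is None:
        fit = fit_blind_dispersion(counts, factors)

    df = counts.counts
    testable = df.index[(df > 0).any(axis=1)]
    ka = df.loc[testable, sample_a].to_numpy()
    kb = df.loc[testable, sample_b].to_numpy()
    s_a = float(factors[sample_a])
    s_b = float(factors[sample_b])

    p_raw = np.array([nb_exact_test(a, b, fit, s_a, s_b) for a, b in zip(ka, kb)])
    p_adj = bh_adjust(p_raw)

    mean_a = ka / s_a
    mean_b = kb / s_b
    fc = np.empty_like(mean_a)
    nonzero = (mean_a > 0) & (mean_b > 0)
    fc[nonzero] = mean_b[nonzero] / mean_a[nonzero]
    if (~nonzero).any():
        pos = np.concatenate([mean_a[mean_a > 0], mean_b[mean_b > 0]])
        c = 0.5 * (pos.min() if len(pos) else 1.0)
        fc[~nonzero] = (mean_b[~nonzero] + c) / (mean_a[~nonzero] + c)

    p_eff = p_adj if cfg.use_adjusted else p_raw
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fc,
            "log2fc": np.log2(fc),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": _assign_calls(p_eff, fc, cfg),
        },
        index=testable,
    )
    return DEResult(table=table, sample_a=sample_a, sample_b=sample_b, config=cfg)


def call_de_subset(counts: CountMatrix, subset: str, cfg: DEConfig | None = None,
                   factors: pd.Series | None = None,
                   fit: DispersionFit | None = None) -> DEResult:
    """Steady-state vs stimulated comparison within one subset."""
    a, b = counts.columns_for(subset)
    return call_de(counts, a, b, cfg, factors=factors, fit=fit)


def cpm(counts: CountMatrix | pd.DataFrame,
        factors: pd.Series | None = None) -> pd.DataFrame:
    """Normalised counts per million: k/s rescaled so columns sum to 1e6."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if factors is None:
        factors = size_factors(df)
    norm = df / factors.reindex(df.columns)
    return norm / norm.sum(axis=0) * 1e6
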