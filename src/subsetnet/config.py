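"""Configuration dataclasses shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


class FormatError(ValueError):
    """Raised when an input file record violates the expected format."""


# Default annotation layout: five planted-enriched terms (odds 6, size 50),
# four null terms (size 30), and one undersized term (size 8) that the
# >=10-observed filter must remove downstream.  A long-gene-biased null term
# is added on top by the generator.
_DEFAULT_TERM_SIZES = (50, 50, 50, 50, 50, 30, 30, 30, 30, 8)
_DEFAULT_TERM_ODDS = (6.0, 6.0, 6.0, 6.0, 6.0, 1.0, 1.0, 1.0, 1.0, 1.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-subset stimulation experiment.

    The generator emulates the study design the pipeline targets: two cell
    subsets (A, B), each profiled once at steady state and once after
    stimulation, negative-binomial counts with a shared per-gene baseline,
    planted shared and subset-specific responders, length-dependent
    detection bias, a scale-free interaction network whose designated core
    signalling molecules are high-degree hubs, and annotation terms with
    planted enrichment.

    NB parameterisation: var = mu + dispersion * mu**2.
    """

    n_genes: int = 5000
    n_core: int = 48
    n_modulators_per_subset: int = 30
    baseline_mean: float = 200.0
    dispersion: float = 0.01
    fold_change: float = 4.0
    frac_shared_de: float = 0.02
    frac_subset_de: float = 0.01
    length_bias_strength: float = 0.5
    net_attach_m: int = 2
    term_sizes: tuple = _DEFAULT_TERM_SIZES
    term_odds: tuple = _DEFAULT_TERM_ODDS
    seed: int = 20140620
    # Secondary knobs (fixed defaults; documented in the methods note).
    prob_up: float = 0.8            # planted responders are mostly up-regulated
    mean_log_sd: float = 1.0        # spread of per-gene baseline means
    length_median: float = 1500.0   # median exonic gene length (bp)
    length_log_sd: float = 0.7
    ubc_degree_frac: float = 0.3    # degree of the promiscuous UBC_SYN node

    def __post_init__(self) -> None:
        if self.frac_shared_de < 0 or self.frac_subset_de < 0:
            raise ConfigurationError("DE fractions must be non-negative")
        if self.frac_shared_de + 2 * self.frac_subset_de > 1:
            raise ConfigurationError(
                "frac_shared_de + 2*frac_subset_de must not exceed 1"
            )
        for name in ("n_genes", "n_core", "net_attach_m"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_modulators_per_subset < 0:
            raise ConfigurationError("n_modulators_per_subset must be >= 0")
        if self.fold_change < 1:
            raise ConfigurationError("fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ConfigurationError("baseline_mean > 0 and dispersion >= 0 required")
        if self.length_bias_strength < 0:
            raise ConfigurationError("length_bias_strength must be >= 0")
        if len(self.term_sizes) != len(self.term_odds):
            raise ConfigurationError("term_sizes and term_odds must align")
        if self.n_core + 1 >= self.n_genes:
            raise ConfigurationError("n_genes must exceed n_core + 1")


@dataclass
class DEConfig:
    """Differential-expression calling thresholds.

    ``use_adjusted`` defaults to False (the single-replicate RNA-Seq path
    calls DE at raw p <= alpha); the meta-analysis path uses BH-adjusted
    p with a fold-change cut-off of 2.
    """

    alpha: float = 0.05
    use_adjusted: bool = False
    min_fold_change: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.min_fold_change < 1:
            raise ConfigurationError("min_fold_change must be >= 1")


@dataclass
class AnnealingConfig:
    """Simulated-annealing schedule for active-subnetwork search."""

    iterations: int = 50_000
    t_start: float = 1.0
    t_end: float = 0.01
    n_modules: int = 5
    restarts: int = 3
    seed: int = 0
    merge_jaccard: float = 0.5

    def __post_init__(self) -> None:
        if not self.t_start > self.t_end > 0:
            raise ConfigurationError("need t_start > t_end > 0")
        if self.iterations < 1 or self.restarts < 1 or self.n_modules < 1:
            raise ConfigurationError("iterations, restarts, n_modules must be >= 1")
        if not 0 < self.merge_jaccard <= 1:
            raise ConfigurationError("merge_jaccard must lie in (0, 1]")


@dataclass
class HubConfig:
    """Degree thresholds for hub classification (inclusive)."""

    hub_min_degree: int = 5
    super_hub_min_degree: int = 15

    def __post_init__(self) -> None:
        if not self.super_hub_min_degree >= self.hub_min_degree >= 1:
            raise ConfigurationError("need super_hub_min_degree >= hub_min_degree >= 1")


def config_from_mapping(cls, mapping: dict):
    """Build a config dataclass from a (YAML-loaded) mapping, ignoring extras."""
    known = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in known}
    for k in ("term_sizes", "term_odds"):
        if k in kwargs and isinstance(kwargs[k], list):
            kwargs[k] = tuple(kwargs[k])
    return cls(**kwargs)
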