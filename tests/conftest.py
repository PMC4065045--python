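import warnings

import pytest

from subsetnet import diffexpr, genemodel, simulate
from subsetnet.config import SimulationConfig

warnings.filterwarnings(
    "ignore", message=".*Identity link.*", category=Warning)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimulationConfig:
    """Small but structurally complete synthetic scenario."""
    return SimulationConfig(
        n_genes=300, n_core=8, n_modulators_per_subset=5,
        frac_shared_de=0.05, frac_subset_de=0.03, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_cfg):
    return simulate.gen_counts(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_net(tiny_cfg, tiny_data):
    _, truth = tiny_data
    return simulate.gen_network(tiny_cfg, truth)


@pytest.fixture(scope="session")
def tiny_ann(tiny_cfg, tiny_data):
    _, truth = tiny_data
    return simulate.gen_annotations(tiny_cfg, truth)


@pytest.fixture(scope="session")
def toy_model():
    exons = simulate.gen_exon_table(n_genes=24, seed=3)
    return genemodel.build_chimeric_model(exons)


@pytest.fixture(scope="session")
def toy_alignments(toy_model):
    return simulate.gen_alignments(toy_model, depth=15.0, seed=3)


@pytest.fixture(scope="session")
def default_fit(tiny_data):
    counts, _ = tiny_data
    factors = diffexpr.size_factors(counts)
    return factors, diffexpr.fit_blind_dispersion(counts, factors)
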