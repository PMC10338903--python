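import numpy as np
import pytest

from dpdg.preprocess import preprocess_metric, preprocess_nonmetric
from dpdg.simulate import SimulationConfig, simulate_study


def prepare_blocks(study):
    """Run the standard preprocessing on every simulated block, yielding the
    analysis-ready tables (metric: imputed + size-corrected; nonmetric:
    dichotomized binary)."""
    blocks = {}
    for name, tab in study.blocks.items():
        if tab.mode == "metric":
            blocks[name], _ = preprocess_metric(tab)
        else:
            blocks[name], _ = preprocess_nonmetric(tab, study.breakpoints)
    return blocks


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study shared by fast tests: 10 populations,
    500 loci, modest per-population samples, no missingness."""
    cfg = SimulationConfig(
        n_populations=10,
        n_loci=500,
        n_genomic_per_population=12,
        n_phenotypic_per_population=25,
        missingness=0.0,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_blocks(small_study):
    return prepare_blocks(small_study)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
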