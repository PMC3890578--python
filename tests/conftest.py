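import numpy as np
import pytest

from eqtlqc import synth


@pytest.fixture(scope="session")
def small_bundle():
    """A small clean study: planted effects, mild batch, no defects."""
    cfg = synth.SimulationConfig(
        n_samples=40,
        n_snps=800,
        n_genes=300,
        n_true_eqtls=30,
        n_null_catalog=70,
        seed=101,
    )
    return synth.simulate_all(cfg)


@pytest.fixture(scope="session")
def defect_bundle():
    """A study with one 40%-contaminated sample, one swap (fraction 1.0)
    and one global expression outlier."""
    cfg = synth.SimulationConfig(
        n_samples=30,
        n_snps=900,
        n_genes=250,
        n_true_eqtls=20,
        n_null_catalog=40,
        per_gene_outlier_rate=0.0,
        contaminated_samples=(("S003", "S011", 0.4), ("S007", "S020", 1.0)),
        global_outlier_samples=(("S015", 8.0),),
        seed=77,
    )
    return synth.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
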