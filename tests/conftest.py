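import numpy as np
import pytest

from germtrace import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel_pair():
    """Paired blood/tissue panels from the generator, desk-scale."""
    cfg = sim.DosageSimConfig(n_variants=500, n_samples=3, error_scale=0.1, seed=11)
    truth = sim.simulate_true_genotypes(cfg)
    blood, tissue = sim.simulate_imputed_dosages(truth, cfg)
    return truth, blood, tissue


@pytest.fixture
def noiseless_panel_pair():
    cfg = sim.DosageSimConfig(n_variants=400, n_samples=2, error_scale=0.0, seed=7)
    truth = sim.simulate_true_genotypes(cfg)
    blood, tissue = sim.simulate_imputed_dosages(truth, cfg)
    return truth, blood, tissue
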