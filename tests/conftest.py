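import numpy as np
import pytest

import grnvae as gv


@pytest.fixture(scope="session")
def small_sim():
    """A quick, well-separated synthetic dataset shared across tests."""
    cfg = gv.SimConfig(n_cells=300, n_genes=60, n_tfs=9, n_cell_types=3,
                       edges_per_tf=12, noise_sd=0.3, seed=7)
    return gv.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_prior(small_sim):
    return gv.corrupt_prior(small_sim, 0.2, 0.2, seed=7)


@pytest.fixture(scope="session")
def small_lognorm(small_sim):
    return gv.lognormalize(small_sim.expr)


@pytest.fixture(scope="session")
def small_ulm(small_lognorm, small_prior):
    return gv.ulm_activities(small_lognorm, small_prior)


@pytest.fixture(scope="session")
def small_model_cfg():
    return gv.ModelConfig(latent_dim=16, encoder_widths=(32,), decoder_widths=(16,),
                          gamma_end=1e-3, seed=7)


@pytest.fixture(scope="session")
def small_train_cfg():
    return gv.TrainConfig(max_epochs=20, batch_size=64, seed=7,
                          early_stop_patience=50)


@pytest.fixture(scope="session")
def small_trained(small_lognorm, small_prior, small_ulm, small_model_cfg,
                  small_train_cfg):
    return gv.fit(small_lognorm, small_prior, small_ulm, small_model_cfg,
                  small_train_cfg)
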