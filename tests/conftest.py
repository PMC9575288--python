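import numpy as np
import pytest


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of one array."""
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad

from nerd import SyntheticScenario, TrainingConfig
from nerd.core_data import preprocess_responses
from nerd.network import AutoencoderSpec, Conv1DSpec, FusionSpec, GCNSpec, NetworkSpec
from nerd.synthetic import generate_scenario

TINY_SCENARIO = SyntheticScenario(
    n_drugs=14, n_cells=10, mirna_dim=200, cnv_dim=400,
    label_density=0.8, noise_sd=0.02, latent_rank=3, seed=123)

# small architecture + short schedule for fast structural tests
TINY_CONFIG = TrainingConfig(
    network=NetworkSpec(
        conv=Conv1DSpec(), gcn=GCNSpec(),
        autoencoder=AutoencoderSpec(encoder_hidden=(64, 32), bottleneck=16),
        fusion=FusionSpec(hidden=(32, 16), dropout=0.1)),
    lr=3e-3, epochs=5, batch_size=None, cne_pretrain_epochs=2)


def preprocessed(dataset):
    retained, report = preprocess_responses(dataset.responses)
    dataset.responses = retained
    dataset.label_bounds = report.bounds
    return dataset, report


@pytest.fixture(scope="session")
def tiny_data():
    """A small but fully structured synthetic dataset plus its ground truth."""
    dataset, truth = generate_scenario(TINY_SCENARIO)
    dataset, report = preprocessed(dataset)
    return dataset, truth, report


@pytest.fixture(scope="session")
def tiny_trained(tiny_data):
    """One short training run shared by structural tests."""
    from nerd.train_eval import make_split, train_model

    dataset, _, _ = tiny_data
    split = make_split(dataset, "mixed", seed=0)
    model = train_model(dataset, split, TINY_CONFIG, seed=0)
    return dataset, split, model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
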