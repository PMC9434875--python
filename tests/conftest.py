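import numpy as np
import pytest

from sparseae.sae_core import FeatureTable, SAEConfig, TrainedSAE
from sparseae.synthetic import generate, preset
from sparseae.training import train_sae


@pytest.fixture(scope="session")
def tiny_data():
    """The tiny generator preset (60 x 40, 5 planted features) plus ground truth."""
    return generate(preset("tiny"))


@pytest.fixture(scope="session")
def trained_tiny(tiny_data):
    table, _ = tiny_data
    return train_sae(table, SAEConfig(eta=10.0, epochs=15, seed=0))


@pytest.fixture
def hand_model():
    """A fully hand-set 3 -> 2 -> 2 -> 2 -> 3 network with identity preprocessing."""

    def build(**cfg_kw):
        cfg = SAEConfig(
            lambda_recon=cfg_kw.pop("lambda_recon", 2.0),
            huber_delta=cfg_kw.pop("huber_delta", 1.0),
            standardize=False,
            hidden_width=2,
            **cfg_kw,
        )
        return TrainedSAE(
            W1=np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -1.0]]),
            b1=np.zeros(2),
            W2=np.array([[1.0, -1.0], [0.0, 2.0]]),
            b2=np.array([0.5, 0.0]),
            V1=np.eye(2),
            c1=np.zeros(2),
            V2=np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]]),
            c2=np.zeros(3),
            pre_mean=np.zeros(3),
            pre_scale=np.ones(3),
            config=cfg,
            feature_names=["f0", "f1", "f2"],
        )

    return build


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs: linearly separable toy data."""

    def make(m=100, d=5, gap=6.0, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((m, d))
        y = (np.arange(m) % 2).astype(int)
        X[y == 1, 0] += gap
        X += 10.0  # keep intensities positive-ish like real tables
        return FeatureTable(
            X=X,
            y=y,
            feature_names=[f"MZ {100 + i}.00" for i in range(d)],
            sample_ids=[f"S{i:03d}" for i in range(m)],
        )

    return make
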