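"""Supervised autoencoder: data container, configuration, network and loss.

The model couples a classifier and an autoencoder through a shared latent
space.  An encoder (d -> hidden_width, ReLU -> k) maps each sample to a latent
code of dimension equal to the number of classes; a softmax applied directly to
the latent coordinates yields class probabilities, and a mirror decoder
(k -> hidden_width, ReLU -> d) reconstructs the standardized input.  Training
minimises

    loss(W) = cross_entropy(softmax(Z), y) + lambda * huber(Xhat - X)

subject to an l1,1 constraint ``sum_i ||row_i(W1)||_1 <= eta`` on the first
encoder layer, whose rows correspond one-to-one to input features.  The Huber
(smooth l1) reconstruction loss is quadratic for small residuals and linear for
large ones, making it robust to outlier samples; a squared-error variant is
available for comparison.

Everything here is plain numpy; the network is small enough (one hidden layer)
that explicit forward/backward passes are both simple and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureTable",
    "SAEConfig",
    "TrainedSAE",
    "softmax",
    "classify_logits",
    "encode",
    "decode",
    "huber",
    "total_loss",
]


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """A samples x features intensity matrix with class labels.

    Attributes
    ----------
    X : (m, d) float array of feature intensities.
    y : (m,) int array of class labels in {0..k-1}; every class occurs.
    feature_names : d strings (LC-MS style, e.g. ``"MZ 264.12"``).
    sample_ids : m strings.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        m, d = self.X.shape
        if d < 1:
            raise ValueError("need at least one feature")
        if self.y.shape != (m,):
            raise ValueError("y length must match number of rows of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal number of columns")
        if len(self.sample_ids) != m:
            raise ValueError("sample_ids length must equal number of rows")
        classes = np.unique(self.y)
        k = classes.size
        if not np.array_equal(classes, np.arange(k)):
            raise ValueError("labels must be exactly {0..k-1} with every class present")
        if m < 2 * k:
            raise ValueError("need at least two samples per class on average (m >= 2k)")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return int(self.y.max()) + 1

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset (e.g. a CV fold). Labels must still cover all classes."""
        idx = np.asarray(indices)
        return FeatureTable(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAEConfig:
    """Hyperparameters of one supervised-autoencoder run.

    Parameters
    ----------
    lambda_recon : weight of the reconstruction loss in the composite
        criterion (lambda >= 0); 0 reduces the model to a pure classifier.
    eta : total l1,1 budget of the first encoder layer; ``None`` or ``inf``
        disables the constraint.  Selected by cross-validated accuracy in
        practice (see :func:`sparseae.training.select_eta`).
    hidden_width : neurons in the single hidden layer (default 96).
    latent_dim : latent dimension; must equal the number of classes when
        trained (``None`` means "use the data's k").
    recon_loss : ``"huber"`` (robust, default) or ``"squared"``.
    huber_delta : transition point of the Huber loss, in standardized units.
    epochs : epochs per training phase (the double-descent loop runs two).
    project_every_batch : apply the l1,1 projection after every minibatch
        instead of once per epoch.
    standardize / log_transform : preprocessing fitted on training data only.
    eta_grid : candidate budgets for cross-validated eta selection.
    """

    lambda_recon: float = 1.0
    eta: float | None = 25.0
    hidden_width: int = 96
    latent_dim: int | None = None
    recon_loss: str = "huber"
    huber_delta: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0
    project_every_batch: bool = False
    standardize: bool = True
    log_transform: bool = False
    eta_grid: tuple[float, ...] = (1.0, 5.0, 10.0, 25.0, 50.0, 100.0)

    def __post_init__(self) -> None:
        if self.lambda_recon < 0:
            raise ValueError("lambda_recon must be non-negative")
        if self.eta is not None and self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.hidden_width < 1 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("hidden_width/epochs/batch_size out of range")
        if self.recon_loss not in ("huber", "squared"):
            raise ValueError("recon_loss must be 'huber' or 'squared'")
        if self.huber_delta <= 0 or self.learning_rate <= 0:
            raise ValueError("huber_delta and learning_rate must be positive")

    def with_(self, **kwargs) -> "SAEConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass
class TrainedSAE:
    """Weights, preprocessing parameters and history of a trained run.

    ``W1`` is the constrained first encoder layer (d x hidden_width); its rows
    index input features, so zero rows mark deselected features.  ``pre_mean``
    and ``pre_scale`` are the per-feature standardization parameters fitted on
    the training portion only.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    V1: np.ndarray
    c1: np.ndarray
    V2: np.ndarray
    c2: np.ndarray
    pre_mean: np.ndarray
    pre_scale: np.ndarray
    config: SAEConfig
    feature_names: list[str] = field(default_factory=list)
    history: object | None = None

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W2.shape[1]

    def preprocess(self, X: np.ndarray) -> np.ndarray:
        """Apply the stored (training-fitted) preprocessing to raw intensities."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise ValueError(f"expected {self.d} feature columns, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains missing or non-finite values")
        if self.config.log_transform:
            X = np.log1p(np.maximum(X, 0.0))
        return (X - self.pre_mean) / self.pre_scale


def softmax(Z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, shift-invariant and overflow-safe."""
    Z = np.asarray(Z, dtype=np.float64)
    Zs = Z - Z.max(axis=-1, keepdims=True)
    e = np.exp(Zs)
    return e / e.sum(axis=-1, keepdims=True)


def classify_logits(Z: np.ndarray) -> np.ndarray:
    """Class probabilities from latent coordinates.

    The latent dimension equals the number of classes, so the softmax is
    applied directly to the latent code — the latent space *is* the logit
    space, which is what makes it directly interpretable for diagnosis.
    """
    return softmax(Z)


def encode(model: TrainedSAE, X: np.ndarray) -> np.ndarray:
    """Latent coordinates for raw input rows (preprocessing applied)."""
    Xs = model.preprocess(X)
    H = np.maximum(Xs @ model.W1 + model.b1, 0.0)
    return H @ model.W2 + model.b2


def decode(model: TrainedSAE, Z: np.ndarray) -> np.ndarray:
    """Reconstruction (in preprocessed/standardized space) from latent codes."""
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != model.latent_dim:
        raise ValueError(f"expected latent dimension {model.latent_dim}, got {Z.shape}")
    H = np.maximum(Z @ model.V1 + model.c1, 0.0)
    return H @ model.V2 + model.c2


def huber(r: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise Huber loss: quadratic below delta, linear above."""
    a = np.abs(r)
    return np.where(a <= delta, 0.5 * r * r, delta * (a - 0.5 * delta))


def total_loss(
    X: np.ndarray,
    y: np.ndarray,
    model: TrainedSAE,
    lambda_recon: float | None = None,
    huber_delta: float | None = None,
    recon_loss: str | None = None,
) -> tuple[float, float, float]:
    """Composite loss (total, classification, reconstruction) on raw inputs.

    classification = mean cross-entropy of softmax(encode(X)) against y;
    reconstruction = Huber (or squared-error) loss of decode(encode(X)) - X in
    standardized space, averaged over all observations; total adds them with
    weight lambda on the reconstruction term.
    """
    cfg = model.config
    lam = cfg.lambda_recon if lambda_recon is None else lambda_recon
    delta = cfg.huber_delta if huber_delta is None else huber_delta
    kind = cfg.recon_loss if recon_loss is None else recon_loss
    if lam < 0:
        raise ValueError("lambda_recon must be non-negative")
    y = np.asarray(y, dtype=np.int64)
    if y.min() < 0 or y.max() >= model.latent_dim:
        raise ValueError("labels out of range for the model's latent dimension")
    Xs = model.preprocess(X)
    H = np.maximum(Xs @ model.W1 + model.b1, 0.0)
    Z = H @ model.W2 + model.b2
    P = softmax(Z)
    ce = float(-np.mean(np.log(P[np.arange(len(y)), y] + 1e-300)))
    Hd = np.maximum(Z @ model.V1 + model.c1, 0.0)
    Xhat = Hd @ model.V2 + model.c2
    R = Xhat - Xs
    if kind == "huber":
        rec = float(np.mean(huber(R, delta)))
    else:
        rec = float(np.mean(0.5 * R * R))
    return ce + lam * rec, ce, rec
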