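"""Model interpretation: confidence-scored predictions, latent-space diagnosis,
feature ranking, weight-matrix export and correlation analysis.

Because the latent dimension equals the number of classes, each sample's latent
coordinates are directly its class logits: the softmax of the latent code gives
a probability vector whose maximum is the *confidence score* reported to the
clinician, and the latent scatter of the training cohort gives the visual
context in which a new patient can be judged (is the patient at the heart of a
class cloud, or near the boundary?).

Feature importance comes in two flavours: the l1 norm of each feature's row in
the constrained first-layer weight matrix (the direct product of the l1,1
projection — zero rows are deselected features), and a gradient x input
attribution of the predicted-class probability averaged over samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .sae_core import FeatureTable, SAEConfig, TrainedSAE, softmax
from .training import train_sae

__all__ = [
    "Prediction",
    "FeatureRanking",
    "HoldoutResult",
    "predict_with_confidence",
    "holdout_simulation",
    "rank_features_sae",
    "export_weight_matrix",
    "correlation_matrix",
]


@dataclass
class Prediction:
    """One sample's diagnosis: class, probabilities, confidence, latent position."""

    sample_id: str
    predicted_class: int
    probabilities: np.ndarray
    confidence: float
    latent: np.ndarray


@dataclass
class FeatureRanking:
    """Features ordered by non-increasing importance score.

    ``method`` tags the scoring rule (row_norm | attribution | loading | gini |
    coefficient).  ``selected`` is the set of features with nonzero score —
    for row_norm ranking this is exactly the set of nonzero rows of the
    constrained layer.
    """

    features: list[str]
    scores: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0):
            raise ValueError("importance scores must be non-negative")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("ranking must be sorted by non-increasing score")

    @property
    def selected(self) -> set[str]:
        return {f for f, s in zip(self.features, self.scores) if s > 0}

    def top(self, n: int) -> list[str]:
        return self.features[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.features, "score": self.scores})


def predict_with_confidence(
    model: TrainedSAE, X_new: np.ndarray, sample_ids=None
) -> list[Prediction]:
    """Diagnose new samples: label, softmax probabilities, confidence, latent coords."""
    from .sae_core import encode

    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    Z = encode(model, X_new)
    P = softmax(Z)
    if sample_ids is None:
        sample_ids = [f"new{i}" for i in range(len(X_new))]
    out = []
    for i in range(len(X_new)):
        c = int(P[i].argmax())
        out.append(
            Prediction(
                sample_id=str(sample_ids[i]),
                predicted_class=c,
                probabilities=P[i],
                confidence=float(P[i, c]),
                latent=Z[i],
            )
        )
    return out


def _discriminant_direction(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unit vector along which class clouds separate in the latent space."""
    means = np.stack([Z[y == c].mean(axis=0) for c in np.unique(y)])
    if means.shape[0] == 2:
        v = means[1] - means[0]
    else:
        centered = means - means.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        v = vt[0]
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.eye(Z.shape[1])[0]


@dataclass
class HoldoutResult:
    """Output of the held-out-patient simulation."""

    predictions: list[Prediction]
    held_out_ids: list[str]
    true_labels: np.ndarray
    train_latent: pd.DataFrame
    direction: np.ndarray
    densities: dict = field(default_factory=dict)
    model: TrainedSAE | None = None


def holdout_simulation(
    data: FeatureTable, config: SAEConfig, seed: int = 0
) -> HoldoutResult:
    """Clinical-diagnosis simulation: withhold one patient per class, retrain,
    and place the withheld patients in the training cohort's latent space.

    Returns the k held-out predictions, the latent coordinates of all training
    samples, and per-class Gaussian kernel density estimates of the latent
    cloud projected on the class-discriminant axis.
    """
    rng = np.random.default_rng(seed)
    held = []
    for c in range(data.k):
        members = np.flatnonzero(data.y == c)
        if members.size < 2:
            raise ValueError(f"class {c} has fewer than 2 members")
        held.append(int(rng.choice(members)))
    held = np.asarray(held)
    train_idx = np.setdiff1d(np.arange(data.m), held)
    model = train_sae(data.subset(train_idx), config.with_(seed=seed))

    from .sae_core import encode

    Z = encode(model, data.X[train_idx])
    ytr = data.y[train_idx]
    direction = _discriminant_direction(Z, ytr)
    proj = Z @ direction
    grid = np.linspace(proj.min() - 1.0, proj.max() + 1.0, 256)
    densities = {}
    for c in range(data.k):
        vals = proj[ytr == c]
        if np.ptp(vals) < 1e-9:  # degenerate cloud; KDE needs spread
            vals = vals + 1e-6 * rng.standard_normal(vals.size)
        densities[c] = (grid, gaussian_kde(vals)(grid))

    latent_df = pd.DataFrame(Z, columns=[f"z{j}" for j in range(Z.shape[1])])
    latent_df.insert(0, "sample_id", [data.sample_ids[i] for i in train_idx])
    latent_df["label"] = ytr

    preds = predict_with_confidence(
        model, data.X[held], sample_ids=[data.sample_ids[i] for i in held]
    )
    return HoldoutResult(
        predictions=preds,
        held_out_ids=[data.sample_ids[i] for i in held],
        true_labels=data.y[held],
        train_latent=latent_df,
        direction=direction,
        densities=densities,
        model=model,
    )


def rank_features_sae(
    model: TrainedSAE, data: FeatureTable | None = None, method: str = "row_norm"
) -> FeatureRanking:
    """Rank input features by importance to the trained SAE.

    ``row_norm`` (default): l1 norm of each feature's row in the projected
    first-layer matrix; zero rows score 0 and are unselected.
    ``attribution``: mean |gradient x input| of the predicted-class probability
    over the provided samples, computed in preprocessed space.
    """
    names = model.feature_names or [f"f{i}" for i in range(model.d)]
    if method == "row_norm":
        scores = np.abs(model.W1).sum(axis=1).astype(float)
    elif method == "attribution":
        if data is None:
            raise ValueError("attribution ranking needs data samples")
        Xs = model.preprocess(data.X)
        H1 = Xs @ model.W1 + model.b1
        A1 = np.maximum(H1, 0.0)
        Z = A1 @ model.W2 + model.b2
        P = softmax(Z)
        c = P.argmax(axis=1)
        pc = P[np.arange(len(P)), c][:, None]
        GZ = -pc * P
        GZ[np.arange(len(P)), c] += pc[:, 0]
        GH = (GZ @ model.W2.T) * (H1 > 0)
        GX = GH @ model.W1.T
        scores = np.mean(np.abs(GX * Xs), axis=0)
    else:
        raise ValueError("method must be 'row_norm' or 'attribution'")
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        features=[names[i] for i in order], scores=scores[order], method=method
    )


def export_weight_matrix(model: TrainedSAE, path) -> None:
    """Write the constrained first-layer weight matrix as TSV.

    Rows are labelled with feature names, columns with hidden-neuron indices —
    the heatmap-ready form of the features-vs-hidden-layer connection matrix
    whose zero rows visualise the structured sparsity pattern.
    """
    names = model.feature_names or [f"f{i}" for i in range(model.d)]
    df = pd.DataFrame(
        model.W1,
        index=names,
        columns=[f"h{j}" for j in range(model.W1.shape[1])],
    )
    df.to_csv(path, sep="\t", index_label="feature", float_format="%.9g")


def correlation_matrix(
    data: FeatureTable, features
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of a feature subset across all samples.

    ``features`` may be names or column indices.  Zero-variance features are
    excluded with a warning.  Returns the symmetric unit-diagonal matrix and a
    long-form pairwise table sorted by |r|.
    """
    if len(features) < 2:
        raise ValueError("need at least two features")
    name_to_idx = {n: i for i, n in enumerate(data.feature_names)}
    idx = [name_to_idx[f] if isinstance(f, str) else int(f) for f in features]
    names = [data.feature_names[i] for i in idx]
    sub = data.X[:, idx]
    var = sub.var(axis=0)
    keep = var > 1e-24
    if not np.all(keep):
        dropped = [n for n, k_ in zip(names, keep) if not k_]
        warnings.warn(f"excluding zero-variance features: {dropped}", stacklevel=2)
        sub = sub[:, keep]
        names = [n for n, k_ in zip(names, keep) if k_]
    if sub.shape[1] < 2:
        raise ValueError("fewer than two features with nonzero variance")
    C = np.corrcoef(sub, rowvar=False)
    np.fill_diagonal(C, 1.0)
    mat = pd.DataFrame(C, index=names, columns=names)
    pairs = [
        {"feature_a": names[i], "feature_b": names[j], "pearson_r": float(C[i, j])}
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    table = pd.DataFrame(pairs).sort_values(
        "pearson_r", key=np.abs, ascending=False, ignore_index=True
    )
    return mat, table
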