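"""Projected double-descent training of the supervised autoencoder.

The optimisation alternates ADAM minibatch steps on the composite loss with an
l1,1 projection of the first encoder layer (projected gradient descent on the
constraint set).  Training runs in two phases:

* **Phase 1** trains all weights; after every epoch (or every minibatch if
  configured) the first layer is projected onto the l1,1 ball of radius eta,
  which drives whole rows — features — to exactly zero.
* **Phase 2** ("double descent", a prune-and-retrain scheme with thresholding
  replaced by the projection) freezes the rows that were zero at the end of
  phase 1, resets the optimiser, and retrains the surviving weights with the
  projection still active.  Frozen rows receive zero gradients and a fresh
  ADAM state, so they can never be revived.

Projection radii are recomputed from the current (post-gradient-step) weights
at every application.  All arithmetic is float32, mirroring standard deep
learning practice; constraint checks therefore use a 1e-5 absolute tolerance.
Runs are bit-for-bit reproducible given a fixed seed: weight initialisation and
batch shuffling draw from independent, deterministically derived streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projections import l1_norm_rows, project_l11
from .sae_core import FeatureTable, SAEConfig, TrainedSAE, softmax

__all__ = ["TrainingHistory", "train_sae", "train_nn_baseline", "select_eta"]

_INF = float("inf")


@dataclass
class TrainingHistory:
    """Per-epoch observability of a training run."""

    records: list[dict] = field(default_factory=list)
    weight_snapshots: list[dict] = field(default_factory=list)

    def log(self, **kw) -> None:
        self.records.append(kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


def _init_linear(rng: np.random.Generator, fan_in: int, fan_out: int):
    """Uniform fan-in initialisation, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
    b = rng.uniform(-bound, bound, size=fan_out).astype(np.float32)
    return W, b


class _Adam:
    """Minimal ADAM optimiser over a dict of named float32 arrays."""

    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            params[k] -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(
                np.float32
            )


def _fit_preprocessing(data: FeatureTable, config: SAEConfig):
    X = data.X
    if config.log_transform:
        X = np.log1p(np.maximum(X, 0.0))
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
    else:
        mean = np.zeros(data.d)
        scale = np.ones(data.d)
    return mean, scale, (X - mean) / scale


def _forward_backward(params, Xb, yb, k, lam, delta, kind, with_decoder):
    """One composite-loss evaluation with gradients. Returns (grads, total, ce, rec)."""
    b = Xb.shape[0]
    W1, b1, W2, b2 = params["W1"], params["b1"], params["W2"], params["b2"]
    H1 = Xb @ W1 + b1
    A1 = np.maximum(H1, 0.0)
    Z = A1 @ W2 + b2
    # softmax + cross-entropy
    Zs = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Zs)
    P = E / E.sum(axis=1, keepdims=True)
    ce = float(-np.mean(np.log(P[np.arange(b), yb] + np.float32(1e-30))))
    dZ = P.copy()
    dZ[np.arange(b), yb] -= 1.0
    dZ /= np.float32(b)

    grads = {}
    rec = 0.0
    if with_decoder and lam > 0:
        V1, c1, V2, c2 = params["V1"], params["c1"], params["V2"], params["c2"]
        H2 = Z @ V1 + c1
        A2 = np.maximum(H2, 0.0)
        Xhat = A2 @ V2 + c2
        R = Xhat - Xb
        aR = np.abs(R)
        if kind == "huber":
            rec = float(
                np.mean(np.where(aR <= delta, 0.5 * R * R, delta * (aR - 0.5 * delta)))
            )
            dR = np.where(aR <= delta, R, delta * np.sign(R)).astype(np.float32)
        else:
            rec = float(np.mean(0.5 * R * R))
            dR = R
        dR = dR * np.float32(lam / R.size)
        grads["V2"] = A2.T @ dR
        grads["c2"] = dR.sum(axis=0)
        dA2 = dR @ V2.T
        dH2 = np.where(H2 > 0, dA2, 0.0).astype(np.float32)
        grads["V1"] = Z.T @ dH2
        grads["c1"] = dH2.sum(axis=0)
        dZ = dZ + dH2 @ V1.T

    grads["W2"] = A1.T @ dZ
    grads["b2"] = dZ.sum(axis=0)
    dA1 = dZ @ W2.T
    dH1 = np.where(H1 > 0, dA1, 0.0).astype(np.float32)
    grads["W1"] = Xb.T @ dH1
    grads["b1"] = dH1.sum(axis=0)
    return grads, ce + lam * rec, ce, rec


def _run_loop(
    data: FeatureTable,
    config: SAEConfig,
    with_decoder: bool,
    record_weights: bool = False,
) -> TrainedSAE:
    k = data.k
    latent = config.latent_dim if config.latent_dim is not None else k
    if latent != k:
        raise ValueError(f"latent_dim ({latent}) must equal the number of classes ({k})")
    eta = config.eta if config.eta is not None else _INF
    if eta < 0:
        raise ValueError("eta must be non-negative")
    project = np.isfinite(eta)

    mean, scale, Xs = _fit_preprocessing(data, config)
    Xs = Xs.astype(np.float32)
    y = data.y
    m, d = Xs.shape
    h = config.hidden_width
    batch = min(config.batch_size, m)

    # independent deterministic streams: encoder init, decoder init, shuffling
    ss = np.random.SeedSequence(config.seed)
    enc_rng, dec_rng, shuf_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    W1, b1 = _init_linear(enc_rng, d, h)
    W2, b2 = _init_linear(enc_rng, h, latent)
    params = {"W1": W1, "b1": b1, "W2": W2, "b2": b2}
    if with_decoder:
        V1, c1 = _init_linear(dec_rng, latent, h)
        V2, c2 = _init_linear(dec_rng, h, d)
        params.update({"V1": V1, "c1": c1, "V2": V2, "c2": c2})

    history = TrainingHistory()
    lam = config.lambda_recon if with_decoder else 0.0
    delta = np.float32(config.huber_delta)
    mask = None  # phase-2 row mask on W1 (True = trainable)

    def run_phase(phase: int) -> None:
        nonlocal mask
        opt = _Adam(params, config.learning_rate)
        for epoch in range(config.epochs):
            perm = shuf_rng.permutation(m)
            tot_s = ce_s = rec_s = 0.0
            nb = 0
            for start in range(0, m, batch):
                idx = perm[start : start + batch]
                grads, tot, ce, rec = _forward_backward(
                    params, Xs[idx], y[idx], k, lam, delta, config.recon_loss, with_decoder
                )
                if mask is not None:
                    grads["W1"][~mask] = 0.0
                opt.step(params, grads)
                if project and config.project_every_batch:
                    params["W1"] = project_l11(params["W1"], eta)
                tot_s += tot
                ce_s += ce
                rec_s += rec
                nb += 1
            if project and not config.project_every_batch:
                params["W1"] = project_l11(params["W1"], eta)
            norms = l1_norm_rows(params["W1"])
            history.log(
                phase=phase,
                epoch=epoch,
                total=tot_s / nb,
                classification=ce_s / nb,
                reconstruction=rec_s / nb,
                nnz_rows=int(np.count_nonzero(norms)),
                l11_norm=float(norms.sum()),
            )
            if record_weights:
                history.weight_snapshots.append(
                    {n: params[n].copy() for n in ("W1", "b1", "W2", "b2")}
                )

    run_phase(1)
    # double descent: freeze eliminated rows, reset optimiser, retrain survivors
    mask = l1_norm_rows(params["W1"]) > 0
    run_phase(2)

    zeros = lambda *s: np.zeros(s, dtype=np.float32)  # noqa: E731
    return TrainedSAE(
        W1=params["W1"],
        b1=params["b1"],
        W2=params["W2"],
        b2=params["b2"],
        V1=params.get("V1", zeros(latent, h)),
        c1=params.get("c1", zeros(h)),
        V2=params.get("V2", zeros(h, d)),
        c2=params.get("c2", zeros(d)),
        pre_mean=mean,
        pre_scale=scale,
        config=config,
        feature_names=list(data.feature_names),
        history=history,
    )


def train_sae(
    data: FeatureTable, config: SAEConfig, record_weights: bool = False
) -> TrainedSAE:
    """Train the supervised autoencoder with the l1,1-projected double-descent loop.

    Deterministic given ``config.seed``.  The returned model's first layer
    satisfies ``sum_i ||row_i(W1)||_1 <= eta`` (1e-5 tolerance in float32).
    """
    return _run_loop(data, config, with_decoder=True, record_weights=record_weights)


def train_nn_baseline(
    data: FeatureTable, config: SAEConfig, record_weights: bool = False
) -> TrainedSAE:
    """Train the plain neural-network comparator.

    Identical encoder + softmax architecture, optimiser and schedule, but
    trained on cross-entropy alone: no decoder, no reconstruction term, no
    sparsity projection.  With lambda = 0, eta = None and the same seed, the
    SAE's encoder follows exactly the same parameter trajectory.
    """
    cfg = config.with_(lambda_recon=0.0, eta=None)
    return _run_loop(data, cfg, with_decoder=False, record_weights=record_weights)


def predict_proba(model: TrainedSAE, X: np.ndarray) -> np.ndarray:
    """Class probabilities for raw input rows."""
    from .sae_core import encode

    return softmax(encode(model, X))


def select_eta(
    data: FeatureTable,
    config: SAEConfig,
    n_folds: int = 4,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose the sparsity budget eta by cross-validated accuracy.

    Every eta in ``config.eta_grid`` is scored by stratified ``n_folds``-fold
    cross-validation on ``data`` (the training portion of an outer split, to
    avoid leakage); the eta with maximal mean accuracy wins, ties broken toward
    the smallest (sparsest) value.  Returns the chosen eta and the per-eta
    accuracy table.
    """
    from .evaluation import make_folds

    grid = list(config.eta_grid)
    if not grid:
        raise ValueError("eta_grid must be non-empty")
    if any(e < 0 for e in grid):
        raise ValueError("eta_grid values must be non-negative")
    folds = make_folds(data, n_folds, seed)
    rows = []
    for eta in grid:
        accs = []
        for fold, (train_idx, test_idx) in enumerate(folds):
            model = train_sae(data.subset(train_idx), config.with_(eta=eta, seed=seed))
            proba = predict_proba(model, data.X[test_idx])
            acc = float(np.mean(proba.argmax(axis=1) == data.y[test_idx]))
            accs.append(acc)
            rows.append({"eta": eta, "fold": fold, "accuracy": acc})
        rows.append({"eta": eta, "fold": "mean", "accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    means = table[table["fold"] == "mean"].set_index("eta")["accuracy"]
    best = means.max()
    chosen = float(min(e for e in grid if means[e] >= best - 1e-12))
    return chosen, table
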