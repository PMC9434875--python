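"""Sparsity-inducing projection operators for network weight matrices.

The central operator is :func:`project_l11`, the two-stage projection onto the
l1,1 ball ``{W : sum_i ||row_i(W)||_1 <= eta}`` used to constrain the first
encoder layer during training.  Because the budget ``eta`` is first distributed
across *rows* (one row per input feature) and rows whose budget is zero are
zeroed entirely, the constraint performs feature selection: a zero row
disconnects its feature from the whole network.

The unstructured comparator :func:`project_l1_matrix` (a plain Euclidean l1
projection of the vectorised matrix, i.e. global soft-thresholding) is provided
so the sparsity-pattern contrast between the two constraints can be reproduced:
at matched total l1 norm the structured projection concentrates the budget on
few rows while the unstructured one scatters zeros across all of them.

All operators are pure functions on float arrays and support both float32
(training-time) and float64 inputs; computations are carried out in the input
dtype's precision or better.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "l1_norm_rows",
    "project_l1_ball",
    "compute_row_radii",
    "project_l11",
    "project_l1_matrix",
]


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must contain only finite values")


def l1_norm_rows(W: np.ndarray) -> np.ndarray:
    """Per-row l1 norms of a 2-D weight matrix.

    Parameters
    ----------
    W : ndarray of shape (d_rows, n_cols)

    Returns
    -------
    ndarray of shape (d_rows,) with entry i equal to ``sum(|W[i, :]|)``.
    """
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    _check_finite(W, "W")
    return np.abs(W).sum(axis=1)


def project_l1_ball(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection of a vector onto the l1 ball of a given radius.

    Uses the exact sort-based algorithm: sort ``|v|`` in decreasing order,
    locate the largest support size ``rho`` with positive soft-threshold, and
    shrink every coordinate by the resulting threshold.  O(n log n).

    If ``||v||_1 <= radius`` the input is returned unchanged (exact fixpoint).
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    v = np.asarray(v)
    _check_finite(v, "v")
    av = np.abs(v)
    if av.sum() <= radius:
        return v.copy()
    if radius == 0:
        return np.zeros_like(v)
    u = np.sort(av)[::-1]
    css = np.cumsum(u, dtype=np.float64)
    j = np.arange(1, u.size + 1)
    # >= (not >) keeps the support index well-defined when a tiny radius
    # rounds away in css - radius; at exact ties the projection is unchanged
    rho = np.nonzero(u * j >= css - radius)[0][-1]
    theta = (css[rho] - radius) / (rho + 1.0)
    return (np.sign(v) * np.maximum(av - theta, 0)).astype(v.dtype, copy=False)


def compute_row_radii(row_norms: np.ndarray, eta: float) -> np.ndarray:
    """Distribute a total l1 budget ``eta`` over rows given their l1 norms.

    The vector of per-row radii ``t`` is the l1-ball projection of the row-norm
    vector onto radius ``eta``, clipped at zero (row norms are non-negative, so
    the projection preserves non-negativity up to rounding).  Rows with small
    norms receive ``t_i = 0`` — those rows will be eliminated entirely by the
    second stage, which is how the constraint deselects features.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    row_norms = np.asarray(row_norms)
    t = project_l1_ball(row_norms, eta)
    return np.maximum(t, 0)


def _project_rows_batch(W: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Project every row i of W onto the l1 ball of radius radii[i] (vectorised)."""
    av = np.abs(W)
    norms = av.sum(axis=1)
    out = W.copy()
    # zero-radius rows are eliminated outright (the sort formula needs r > 0)
    dead = (radii <= 0) & (norms > 0)
    out[dead] = 0
    # rows already feasible (incl. radii >= norm) stay untouched
    need = (norms > radii) & ~dead
    if not np.any(need):
        return out
    sub = av[need]
    r = radii[need]
    u = np.sort(sub, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1, dtype=np.float64)
    j = np.arange(1, sub.shape[1] + 1)
    cond = u * j >= css - r[:, None]
    # last column index where cond holds; cond always holds at column 0 here
    rho = cond.shape[1] - 1 - np.argmax(cond[:, ::-1], axis=1)
    theta = (css[np.arange(sub.shape[0]), rho] - r) / (rho + 1.0)
    shrunk = np.sign(W[need]) * np.maximum(sub - theta[:, None], 0)
    out[need] = shrunk.astype(W.dtype, copy=False)
    return out


def project_l11(W: np.ndarray, eta: float) -> np.ndarray:
    """Two-stage l1,1 projection of a weight matrix.

    Stage 1 computes per-row radii ``t_i`` by projecting the vector of row l1
    norms onto the l1 ball of radius ``eta``; stage 2 projects each row onto
    the l1 ball of its adaptive radius ``t_i``.  The result satisfies
    ``sum_i ||row_i||_1 <= eta``, zeroes every row whose radius is zero, is
    idempotent, and fixes feasible inputs exactly.

    This is deliberately *not* the Euclidean projection onto the set
    ``{W : sum|W_ij| <= eta}`` (plain soft-thresholding): the row-wise budget
    allocation is what produces whole-row (feature-level) sparsity.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    _check_finite(W, "W")
    norms = l1_norm_rows(W)
    if norms.sum() <= eta:
        return W.copy()
    t = compute_row_radii(norms, eta)
    return _project_rows_batch(W, t)


def project_l1_matrix(W: np.ndarray, eta: float) -> np.ndarray:
    """Euclidean projection of the vectorised matrix onto the l1 ball.

    The unstructured comparator: a single global soft-threshold applied to all
    entries, with no notion of rows.  It zeroes individual weights rather than
    whole features.
    """
    if eta < 0:
        raise ValueError("eta must be non-negative")
    W = np.asarray(W)
    if W.ndim != 2:
        raise ValueError("W must be a 2-D matrix")
    flat = project_l1_ball(W.ravel(), eta)
    return flat.reshape(W.shape)
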