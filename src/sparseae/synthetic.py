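"""Synthetic LC-MS-like feature tables with known ground truth.

The generator emulates the statistical structure of clinical metabolomics
intensity matrices: non-negative, log-normally distributed intensities whose
per-feature baselines span several decades; a small planted set of
class-informative features (a standardized mean shift on the log scale);
blocks of highly correlated columns mimicking adduct/isotope groups of a single
metabolite (a shared Gaussian factor per block); and a fraction of outlier
samples carrying heavy-tailed (Student-t) noise, the situation that motivates a
robust reconstruction loss.

On the log scale, features are Gaussian with standard deviation
``log_sigma`` (default 0.25) around feature-specific baselines, so the
configured within-block correlations survive exponentiation nearly unchanged
and "effect size" has its usual standardized meaning.  Presets reproduce the
shapes of three published clinical datasets (urine lung-cancer screening,
breast-tumor ER status, glial-tumor IDH status) plus a tiny shape for fast
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sae_core import FeatureTable

__all__ = ["SyntheticSpec", "generate", "preset", "PRESETS"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth description of one synthetic feature table.

    adduct_groups is a list of (group_size, within-group Pearson correlation)
    pairs; each group occupies a contiguous block of feature columns.
    effect_size is the class shift on informative features in units of the
    log-scale standard deviation.  outlier_fraction of samples receive
    additive Student-t noise with noise_df degrees of freedom on every feature.
    """

    m: int = 200
    d: int = 500
    k: int = 2
    n_informative: int = 10
    effect_size: float = 1.5
    adduct_groups: tuple[tuple[int, float], ...] = ((4, 0.8), (4, 0.8), (3, 0.8))
    outlier_fraction: float = 0.05
    noise_df: float = 3.0
    log_sigma: float = 0.25
    imbalance: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_informative <= self.d):
            raise ValueError("n_informative must be in [1, d]")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        for size, rho in self.adduct_groups:
            if not (0 <= rho < 1):
                raise ValueError("within-group correlation must be in [0, 1)")
            if size < 2:
                raise ValueError("adduct groups need at least 2 features")
        if sum(size for size, _ in self.adduct_groups) > self.d:
            raise ValueError("adduct groups do not fit into d features")
        if self.m < 2 * self.k:
            raise ValueError("need m >= 2k samples")
        if self.noise_df <= 0 or self.log_sigma <= 0:
            raise ValueError("noise_df and log_sigma must be positive")


PRESETS: dict[str, SyntheticSpec] = {
    # shapes of the three clinical cohorts the method was designed around
    "lung_like": SyntheticSpec(m=1005, d=2944, seed=0),
    "breast_like": SyntheticSpec(m=271, d=161, seed=0),
    "brain_like": SyntheticSpec(m=88, d=7022, seed=0),
    "tiny": SyntheticSpec(
        m=60, d=40, n_informative=5, adduct_groups=((3, 0.8),), seed=0
    ),
}


def preset(name: str) -> SyntheticSpec:
    """Named generator presets; 'tiny' (60 x 40) is the fast default for tests."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None


def _balanced_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.imbalance is not None:
        w = np.asarray(spec.imbalance, dtype=float)
        if w.size != spec.k or np.any(w <= 0):
            raise ValueError("imbalance must give a positive weight per class")
        counts = np.maximum(np.round(spec.m * w / w.sum()).astype(int), 1)
        while counts.sum() > spec.m:
            counts[counts.argmax()] -= 1
        while counts.sum() < spec.m:
            counts[counts.argmin()] += 1
    else:
        counts = np.full(spec.k, spec.m // spec.k)
        counts[: spec.m % spec.k] += 1
    y = np.repeat(np.arange(spec.k), counts)
    rng.shuffle(y)
    return y


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray]:
    """Draw one feature table; returns (table, indices of informative features).

    Deterministic given ``spec.seed``.  Intensities are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    m, d, k = spec.m, spec.d, spec.k
    y = _balanced_labels(spec, rng)

    # unit-variance Gaussian base on the log scale; adduct blocks share a factor
    Zbase = rng.standard_normal((m, d))
    col = 0
    group_slices = []
    for size, rho in spec.adduct_groups:
        f = rng.standard_normal((m, 1))
        Zbase[:, col : col + size] = (
            np.sqrt(rho) * f + np.sqrt(1.0 - rho) * Zbase[:, col : col + size]
        )
        group_slices.append(slice(col, col + size))
        col += size

    # planted class signal: standardized mean shift on informative features,
    # drawn from the columns outside the correlated blocks when possible
    free = np.arange(col, d)
    if free.size >= spec.n_informative:
        informative = np.sort(rng.choice(free, size=spec.n_informative, replace=False))
    else:
        informative = np.sort(
            rng.choice(np.arange(d), size=spec.n_informative, replace=False)
        )
    # centered, equally spaced class shifts: adjacent classes differ by effect_size
    shifts = spec.effect_size * (np.arange(k) - (k - 1) / 2.0)
    Zbase[:, informative] += shifts[y][:, None]

    # heavy-tailed outlier samples (the Huber-loss motivation)
    n_out = int(round(spec.outlier_fraction * m))
    if n_out > 0:
        out_idx = rng.choice(m, size=n_out, replace=False)
        Zbase[out_idx] += rng.standard_t(spec.noise_df, size=(n_out, d))

    # log-normal intensities: per-feature baseline spans decades of dynamic range
    baseline = rng.uniform(2.0, 9.0, size=d)
    X = np.exp(baseline + spec.log_sigma * Zbase)

    mz = np.sort(rng.uniform(70.0, 1000.0, size=d))
    feature_names = [f"MZ {v:.2f}" for v in mz]
    # de-duplicate names that collide at 2 decimals
    seen: dict[str, int] = {}
    for i, name in enumerate(feature_names):
        if name in seen:
            seen[name] += 1
            feature_names[i] = f"{name}#{seen[name]}"
        else:
            seen[name] = 0
    sample_ids = [f"S{i:04d}" for i in range(m)]
    table = FeatureTable(X=X, y=y, feature_names=feature_names, sample_ids=sample_ids)
    return table, informative
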