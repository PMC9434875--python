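"""Feature-table I/O, run configuration and manifests.

Feature tables are plain CSV/TSV files: one header row, one row per sample,
numeric feature columns (typically named like ``"MZ 264.12"``) plus one label
column.  Labels may be arbitrary strings; they are mapped to integer codes
0..k-1 in lexicographic order and the mapping is recorded so it can be echoed
into the run manifest.  Missing values are rejected by default; optional
half-minimum imputation (each missing cell replaced by half the feature's
observed minimum, a metabolomics convention for values below the detection
limit) is available.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .sae_core import FeatureTable, SAEConfig

__all__ = [
    "load_feature_table",
    "write_feature_table",
    "load_run_config",
    "write_manifest",
]


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_feature_table(
    path,
    label_column: str = "label",
    impute: str | None = None,
) -> tuple[FeatureTable, dict]:
    """Read a samples x features table; returns (table, label mapping).

    ``impute`` is None (reject missing values, the default) or ``"half_min"``.
    An optional ``sample_id`` column supplies sample identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    labels = df[label_column].astype(str)
    df = df.drop(columns=[label_column])
    if "sample_id" in df.columns:
        sample_ids = df["sample_id"].astype(str).tolist()
        df = df.drop(columns=["sample_id"])
    else:
        sample_ids = [f"S{i:04d}" for i in range(len(df))]

    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad}")
    X = df.to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        if impute == "half_min":
            for j in range(X.shape[1]):
                col = X[:, j]
                miss = np.isnan(col)
                if miss.all():
                    raise ValueError(f"feature {df.columns[j]!r} is entirely missing")
                col[miss] = 0.5 * np.nanmin(col)
        else:
            i, j = np.argwhere(np.isnan(X))[0]
            raise ValueError(
                f"missing value at row {sample_ids[i]!r}, column {df.columns[j]!r} "
                "(pass impute='half_min' to impute)"
            )
    const = np.flatnonzero(X.std(axis=0) < 1e-24)
    if const.size:
        import warnings

        warnings.warn(
            f"{const.size} all-constant feature(s), e.g. {df.columns[const[0]]!r}",
            stacklevel=2,
        )
    classes = sorted(labels.unique())
    mapping = {c: i for i, c in enumerate(classes)}
    y = labels.map(mapping).to_numpy()
    table = FeatureTable(
        X=X, y=y, feature_names=list(df.columns), sample_ids=sample_ids
    )
    return table, mapping


def write_feature_table(
    table: FeatureTable, path, labels: dict | None = None
) -> None:
    """Write a FeatureTable to CSV/TSV (full float precision, round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(table.X, columns=table.feature_names)
    df.insert(0, "sample_id", table.sample_ids)
    inv = {v: k for k, v in (labels or {}).items()}
    df["label"] = [inv.get(int(c), str(c)) for c in table.y]
    df.to_csv(path, sep=_delimiter_for(path), index=False, float_format="%.17g")


def load_run_config(path) -> dict:
    """Read a YAML or JSON run configuration; the 'sae' block maps to SAEConfig."""
    path = Path(path)
    with open(path) as fh:
        cfg = (
            json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        ) or {}
    if "sae" in cfg:
        cfg["sae"] = SAEConfig(**cfg["sae"])
    return cfg


def write_manifest(out_dir, command: str, config, seed: int, extra: dict | None = None):
    """Record everything needed to reproduce a run (config echo, seed, versions)."""
    import sklearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
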