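"""Shared numeric helpers: normalization and group summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

CP_TARGET = 1e4  # counts-per-10k normalization target, shared by all modules


def to_dense(X) -> np.ndarray:
    """Return a dense float array view of a (possibly sparse) matrix."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def normalize_log1p(X, target: float = CP_TARGET) -> np.ndarray:
    """Depth-normalize counts per cell to `target` and log1p-transform.

    Rows are cells. Cells with zero total are left at zero.
    """
    D = to_dense(X)
    tot = D.sum(axis=1)
    scale = np.divide(target, tot, out=np.zeros_like(tot, dtype=float), where=tot > 0)
    return np.log1p(D * scale[:, None])


def normalize_cp(X, target: float = CP_TARGET) -> np.ndarray:
    """Depth-normalize counts per cell to `target` (no log)."""
    D = to_dense(X)
    tot = D.sum(axis=1)
    scale = np.divide(target, tot, out=np.zeros_like(tot, dtype=float), where=tot > 0)
    return D * scale[:, None]


def group_indices(labels) -> dict[str, np.ndarray]:
    """Map each label to the (sorted-label order) array of row indices."""
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in sorted(pd.unique(labels))}


def group_mean_frame(values: np.ndarray, labels, columns) -> pd.DataFrame:
    """Per-group column means as a (feature x group) DataFrame."""
    out = {}
    for g, idx in group_indices(labels).items():
        out[g] = values[idx].mean(axis=0)
    return pd.DataFrame(out, index=list(columns))


def detection_fraction_frame(X, labels, columns) -> pd.DataFrame:
    """Per-group fraction of cells with a nonzero count (feature x group)."""
    D = to_dense(X)
    out = {}
    for g, idx in group_indices(labels).items():
        out[g] = (D[idx] > 0).mean(axis=0)
    return pd.DataFrame(out, index=list(columns))
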