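"""Bias-corrected per-cell motif accessibility deviations.

For motif m and cell j, let X_mj be the cell's total counts over the motif's
hit peaks, t_j the cell's total counts and f_m the fraction of all counts
falling in the hit peaks. The expectation under no motif effect is
E_mj = f_m * t_j and the raw deviation (X - E)/E; depth normalization is
therefore built into the expectation. Each of n_iter background iterations
replaces every hit peak with a random peak drawn from its k nearest
neighbors in standardized (GC fraction, log1p mean accessibility) space and
recomputes the same statistic; the bias-corrected deviation subtracts the
background mean and the deviation Z-score additionally divides by the
background standard deviation. Entries with E = 0 are reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.neighbors import NearestNeighbors

from ._utils import group_indices, to_dense
from .synthetic import MotifHits

DEFAULT_K = 50
DEFAULT_N_ITER = 50


def sample_background_peaks(peaks: pd.DataFrame, atac, n_iter: int = DEFAULT_N_ITER,
                            k: int = DEFAULT_K, seed: int = 0) -> np.ndarray:
    """(n_peaks, n_iter) integer array of GC/accessibility-matched backgrounds.

    Backgrounds are drawn with replacement from each peak's k nearest
    neighbors in z-scored (GC, log1p mean accessibility) space; a peak never
    selects itself.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = len(peaks)
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} peaks, got {n}")
    mean_acc = np.log1p(np.asarray(to_dense(atac.X).mean(axis=0)).ravel())
    feats = np.column_stack([peaks.gc.to_numpy(dtype=float), mean_acc])
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(feats)
    _, nbr = nn.kneighbors(feats)
    # drop self wherever it appears; keep k neighbors
    cleaned = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = nbr[i][nbr[i] != i][:k]
        cleaned[i] = row
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, k, size=(n, n_iter))
    return cleaned[np.arange(n)[:, None], draws]


@dataclass
class DeviationMatrix:
    """Cells x motifs bias-corrected deviations and Z-scores."""

    deviations: pd.DataFrame
    z: pd.DataFrame
    n_background: int


def _raw_deviation(A: np.ndarray, M: np.ndarray, tot: np.ndarray,
                   colsum: np.ndarray, grand: float) -> np.ndarray:
    X = A @ M
    f = (colsum @ M) / grand
    E = np.outer(tot, f)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(E > 0, X / E - 1.0, np.nan)
    return raw


def raw_deviations(atac, motifs: MotifHits) -> pd.DataFrame:
    """Uncorrected deviations (X - E)/E per cell and motif."""
    A = to_dense(atac.X)
    M = to_dense(motifs.matrix)
    tot = A.sum(axis=1)
    colsum = A.sum(axis=0)
    raw = _raw_deviation(A, M, tot, colsum, colsum.sum())
    return pd.DataFrame(raw, index=list(atac.obs_names), columns=motifs.motif_ids)


def compute_deviations(atac, motifs: MotifHits, backgrounds: np.ndarray,
                       n_iter: int | None = None) -> DeviationMatrix:
    """Bias-corrected deviations and Z-scores for every cell and motif."""
    A = to_dense(atac.X)
    M = to_dense(motifs.matrix)
    n_peaks, n_motifs = M.shape
    if A.shape[1] != n_peaks:
        raise ValueError("ATAC matrix and motif hits disagree on peak count")
    if backgrounds.shape[0] != n_peaks:
        raise ValueError("background array does not cover all peaks")
    if n_iter is None:
        n_iter = backgrounds.shape[1]
    tot = A.sum(axis=1)
    colsum = A.sum(axis=0)
    grand = colsum.sum()
    raw = _raw_deviation(A, M, tot, colsum, grand)
    bg = np.empty((n_iter, A.shape[0], n_motifs))
    hit_rows, hit_cols = M.nonzero()
    hit_vals = M[hit_rows, hit_cols]
    for i in range(n_iter):
        mapped = backgrounds[hit_rows, i]
        Mi = np.zeros_like(M)
        np.add.at(Mi, (mapped, hit_cols), hit_vals)
        bg[i] = _raw_deviation(A, Mi, tot, colsum, grand)
    bg_mean = np.nanmean(bg, axis=0)
    bg_sd = np.nanstd(bg, axis=0, ddof=1)
    dev = raw - bg_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(bg_sd > 0, dev / bg_sd, np.nan)
    cells = list(atac.obs_names)
    return DeviationMatrix(
        deviations=pd.DataFrame(dev, index=cells, columns=motifs.motif_ids),
        z=pd.DataFrame(z, index=cells, columns=motifs.motif_ids),
        n_background=n_iter,
    )


def differential_tf_activity(dev: DeviationMatrix, labels, score: str = "z",
                             delta_cut: float = 1.0,
                             alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest differential TF activity.

    ``score`` selects the matrix tested: deviation Z-scores (default, the
    scale on which the activity gates delta > 1 / delta > 4 are meaningful)
    or bias-corrected ``"deviation"`` values. The reported ``activity_delta``
    is the difference of group means (fold change is ill-defined for signed
    scores); two-sided Wilcoxon p-values are Bonferroni-corrected over
    motifs x groups. Missing entries are excluded from means and tests.
    """
    if score not in ("z", "deviation"):
        raise ValueError("score must be 'z' or 'deviation'")
    V = (dev.z if score == "z" else dev.deviations).to_numpy()
    motif_ids = list(dev.deviations.columns)
    groups = group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g, idx in groups.items():
        if len(idx) < 3 or V.shape[0] - len(idx) < 3:
            import warnings
            warnings.warn(f"group {g!r} has fewer than 3 cells; skipped")
            continue
        mask = np.zeros(V.shape[0], dtype=bool)
        mask[idx] = True
        with np.errstate(all="ignore"):
            res = mannwhitneyu(V[mask], V[~mask], axis=0,
                               alternative="two-sided", nan_policy="omit")
        p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
        delta = np.nanmean(V[mask], axis=0) - np.nanmean(V[~mask], axis=0)
        rows.append(pd.DataFrame({
            "motif": motif_ids, "group": g, "activity_delta": delta, "p": p,
        }))
    table = pd.concat(rows, ignore_index=True)
    table["p_adj"] = np.minimum(table.p * len(table), 1.0)
    table["significant"] = (table.activity_delta > delta_cut) & (table.p_adj < alpha)
    table.attrs["score"] = score
    table.attrs["delta_convention"] = "difference of group means (avg-diff)"
    return table
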