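"""Intratumoral NMF expression programs and cross-sample meta-programs.

Per sample, the relative expression matrix of tumor cells (log-normalized,
gene-centered, negatives clamped to zero) is factorized by NMF at k = 2..6
with 30 random restarts per rank. The rank is chosen where the cophenetic
coefficient of the consensus cell-clustering begins its maximum drop; each
retained program is represented by its 30 highest-loading genes. Programs are
consolidated across samples by scoring every program on every sample's tumor
cells, averaging per-sample Pearson correlation matrices of program scores,
Ward-clustering 1 - avg_corr, cutting the dendrogram at its largest
merge-height gap, and keeping clusters whose members span at least half of
the samples; a meta-program's signature is the 30 genes with the highest
average (L2-normalized) loading over its member programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .cre import score_gene_module

DEFAULT_K_RANGE = (2, 6)
DEFAULT_NRUN = 30
TOP_N = 30


@dataclass
class NmfProgram:
    sample: str
    k: int
    index: int
    loadings: pd.Series  # gene -> non-negative loading
    top_genes: list[str]
    degenerate: bool = False


@dataclass
class MetaProgram:
    members: list[tuple[str, int]]  # (sample, program index)
    samples: list[str]
    signature: list[str]


def prepare_relative_expression(log_expr: np.ndarray) -> np.ndarray:
    """Gene-centered log-normalized expression with negatives clamped to 0.

    ``log_expr`` is cells x genes for one sample's tumor cells (>= 20 cells).
    Constant genes become all-zero columns.
    """
    X = np.asarray(log_expr, dtype=float)
    if X.shape[0] < 20:
        raise ValueError("need at least 20 tumor cells")
    return np.clip(X - X.mean(axis=0, keepdims=True), 0.0, None)


def _consensus_cophenetic(assignments: np.ndarray) -> float:
    """Cophenetic coefficient of the consensus matrix of cell assignments.

    ``assignments`` is (nrun, n_cells) of argmax program labels per run.
    """
    n = assignments.shape[1]
    consensus = np.zeros((n, n))
    for run in assignments:
        consensus += (run[:, None] == run[None, :])
    consensus /= assignments.shape[0]
    dis = 1.0 - consensus
    np.fill_diagonal(dis, 0.0)
    condensed = squareform(dis, checks=False)
    Z = linkage(condensed, method="average")
    if np.allclose(condensed, condensed[0]):
        return 1.0 if condensed.size and condensed[0] == 0 else 0.0
    c, _ = cophenet(Z, condensed)
    return float(c) if np.isfinite(c) else 1.0


def run_nmf_range(matrix: np.ndarray, k_min: int = DEFAULT_K_RANGE[0],
                  k_max: int = DEFAULT_K_RANGE[1], nrun: int = DEFAULT_NRUN,
                  seed: int = 0, max_iter: int = 500) -> dict[int, dict]:
    """Randomly restarted NMF over a rank range with consensus diagnostics.

    ``matrix`` is non-negative cells x genes. For each k, ``nrun`` seeded
    random-init factorizations are run; the best-reconstruction run is
    retained (W: cells x k usage, H: k x genes loadings) together with the
    cophenetic coefficient of the consensus co-assignment matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("matrix must be non-negative")
    results: dict[int, dict] = {}
    for k in range(k_min, k_max + 1):
        if k >= min(X.shape):
            warnings.warn(f"rank {k} >= min(matrix dims); skipped")
            continue
        best = None
        assignments = np.empty((nrun, X.shape[0]), dtype=int)
        for r in range(nrun):
            model = NMF(n_components=k, init="random",
                        random_state=seed + 1000 * k + r, solver="mu",
                        max_iter=max_iter, tol=1e-4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = model.fit_transform(X)
            H = model.components_
            err = model.reconstruction_err_
            assignments[r] = W.argmax(axis=1)
            if best is None or err < best["error"]:
                best = {"W": W, "H": H, "error": float(err)}
        best["cophenetic"] = _consensus_cophenetic(assignments)
        results[k] = best
    if not results:
        raise ValueError("no feasible rank in the requested range")
    return results


def select_k_by_cophenetic_drop(coph: dict[int, float]) -> int:
    """Rank preceding the largest cophenetic drop (fallback: argmax)."""
    ks = sorted(coph)
    if len(ks) < 2:
        return ks[0]
    drops = {k: coph[k] - coph[k2] for k, k2 in zip(ks, ks[1:])}
    best_k = min(drops, key=lambda k: (-drops[k], k))
    if drops[best_k] <= 0:
        return min(ks, key=lambda k: (-coph[k], k))
    return best_k


def extract_programs(H: np.ndarray, gene_ids, sample: str, k: int,
                     top_n: int = TOP_N) -> list[NmfProgram]:
    """Programs at the selected rank, each with its top-loading gene list.

    Genes are ranked by loading with lexicographic gene-id tie-breaks; a
    program whose top list had to include zero-loading genes, or whose
    loadings are all tied, is flagged degenerate.
    """
    gene_ids = list(gene_ids)
    programs = []
    for i in range(H.shape[0]):
        s = pd.Series(H[i], index=gene_ids, name=f"{sample}_p{i}")
        ranked = s.sort_index().sort_values(ascending=False, kind="stable")
        top = list(ranked.index[:top_n])
        degenerate = bool((ranked.iloc[:top_n] <= 0).any()
                          or ranked.iloc[0] == ranked.iloc[-1])
        programs.append(NmfProgram(sample=sample, k=k, index=i, loadings=s,
                                   top_genes=top, degenerate=degenerate))
    return programs


MAX_MERGE_DISTANCE = 0.3  # 1 - corr; members of a meta-program must be
# highly correlated (avg score correlation >= 0.7, the conventional bar for a
# strong correlation), so the dynamic cut never admits merges of weakly
# coupled programs however large the gap above them


def _largest_gap_clusters(Z: np.ndarray, n_leaves: int) -> np.ndarray:
    """Flat clusters after cutting at the largest merge-height gap.

    The cut is capped at ``MAX_MERGE_DISTANCE``: on a 1 - correlation
    distance, merges above the cap join programs that are not highly
    correlated and therefore never belong to one consolidated meta-program,
    regardless of the gap structure higher up the dendrogram.
    """
    heights = Z[:, 2]
    if len(heights) == 1:
        cut = heights[0] / 2
    else:
        gaps = np.diff(heights)
        i = int(np.argmax(gaps))
        cut = (heights[i] + heights[i + 1]) / 2.0
    return fcluster(Z, t=min(cut, MAX_MERGE_DISTANCE), criterion="distance")


def derive_meta_programs(programs: list[NmfProgram],
                         log_expr_by_sample: dict[str, tuple[np.ndarray, list]],
                         min_coverage_fraction: float = 0.5,
                         seed: int = 0) -> list[MetaProgram]:
    """Consolidate per-sample programs into cross-sample meta-programs.

    ``log_expr_by_sample`` maps sample -> (log-normalized tumor-cell matrix,
    gene ids). Every program's top-gene set is scored on every sample's tumor
    cells; per-sample Pearson correlation matrices of the score vectors are
    averaged elementwise over the samples where scoring is defined, then
    Ward-clustered on 1 - avg_corr with a largest-gap dendrogram cut.
    Clusters spanning < ``min_coverage_fraction`` of samples are dropped.
    """
    samples = sorted(log_expr_by_sample)
    if len(samples) < 2:
        raise ValueError("need programs from at least 2 samples")
    P = len(programs)
    if P < 2:
        raise ValueError("need at least 2 programs")
    corr_sum = np.zeros((P, P))
    corr_n = np.zeros((P, P))
    for s in samples:
        X, gene_ids = log_expr_by_sample[s]
        gene_set_ok = []
        scores = []
        avail = set(gene_ids)
        for prog in programs:
            usable = [g for g in prog.top_genes if g in avail]
            if not usable:
                continue
            scores.append(score_gene_module(X, gene_ids, usable, seed=seed))
            gene_set_ok.append(True)
        if len(scores) < 2:
            continue
        sc = np.vstack(scores)
        sd = sc.std(axis=1)
        sd[sd == 0] = 1.0
        scn = (sc - sc.mean(axis=1, keepdims=True)) / sd[:, None]
        C = (scn @ scn.T) / sc.shape[1]
        np.fill_diagonal(C, 1.0)
        corr_sum += C
        corr_n += 1
    with np.errstate(invalid="ignore"):
        avg_corr = np.where(corr_n > 0, corr_sum / np.maximum(corr_n, 1), 0.0)
    np.fill_diagonal(avg_corr, 1.0)
    dist = 1.0 - (avg_corr + avg_corr.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(np.clip(dist, 0, None), checks=False), method="ward")
    flat = _largest_gap_clusters(Z, P)
    metas: list[MetaProgram] = []
    n_samples = len(samples)
    for c in sorted(set(flat)):
        members = [programs[i] for i in np.flatnonzero(flat == c)]
        covered = sorted({m.sample for m in members})
        if len(covered) / n_samples < min_coverage_fraction:
            continue
        all_genes = sorted({g for m in members for g in m.loadings.index})
        avg = pd.Series(0.0, index=all_genes)
        for m in members:
            v = m.loadings.reindex(all_genes).fillna(0.0)
            norm = np.linalg.norm(v)
            avg += v / (norm if norm > 0 else 1.0)
        avg /= len(members)
        ranked = avg.sort_index().sort_values(ascending=False, kind="stable")
        metas.append(MetaProgram(
            members=[(m.sample, m.index) for m in members],
            samples=covered,
            signature=list(ranked.index[:TOP_N]),
        ))
    return metas
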