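"""Cis-regulatory element linkage, TF target identification and regulatory
networks.

Co-accessibility between peaks is estimated on pooled metacells with a
graphical-lasso sparse inverse covariance in overlapping genomic windows,
using an elementwise penalty that grows with genomic distance; the
co-accessibility score of a peak pair is the negative rescaled partial
correlation -Theta_ij / sqrt(Theta_ii * Theta_jj), averaged over the windows
containing the pair. A candidate cis-regulatory link requires one peak of a
co-accessible pair (score >= 0.2) to sit within 1 kb of a gene's TSS; the
other peak's per-cell-type mean accessibility is then correlated (Pearson)
with the gene's per-cell-type mean expression, with Benjamini-Hochberg
control across candidate links.

The graphical lasso is implemented here (Friedman block-coordinate descent)
because an elementwise penalty matrix is required; it reduces to the standard
estimator when the penalty is constant.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import group_indices, normalize_log1p, to_dense
from .features import promoter_gene_map
from .synthetic import MotifHits

DEFAULT_WINDOW = 500_000
DEFAULT_COACCESS_CUTOFF = 0.2
DEFAULT_BASE_PENALTY = 0.2


# --------------------------------------------------------------------- pooling

def aggregate_to_metacells(atac, labels, group_size: int = 10, seed: int = 0):
    """Pool cells within each cell type into seeded random groups.

    Cells of a type are randomly partitioned into pools of ``group_size``;
    the remainder is merged into the last pool, and a type with fewer cells
    than ``group_size`` forms a single pool. Returns ``(counts, meta_labels)``
    where counts is a dense metacell x peak array of pooled sums (total counts
    conserved) and meta_labels the cell type of each metacell.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    A = to_dense(atac.X)
    rng = np.random.default_rng(seed)
    rows, meta_labels = [], []
    for g, idx in group_indices(labels).items():
        shuffled = rng.permutation(idx)
        n_pools = max(1, len(shuffled) // group_size)
        pools = [shuffled[k * group_size:(k + 1) * group_size]
                 for k in range(n_pools)]
        pools[-1] = shuffled[(n_pools - 1) * group_size:]
        for pool in pools:
            rows.append(A[pool].sum(axis=0))
            meta_labels.append(g)
    return np.vstack(rows), meta_labels


# ---------------------------------------------------- matrix-penalty glasso

def _lasso_cd(W11, s12, rho12, beta, max_iter=200, tol=1e-6):
    """Coordinate-descent lasso for one glasso column update."""
    p = len(s12)
    diag = np.diag(W11).copy()
    diag[diag <= 0] = 1e-12
    for _ in range(max_iter):
        delta = 0.0
        for k in range(p):
            r = s12[k] - W11[k] @ beta + diag[k] * beta[k]
            new = np.sign(r) * max(abs(r) - rho12[k], 0.0) / diag[k]
            delta = max(delta, abs(new - beta[k]))
            beta[k] = new
        if delta < tol:
            break
    return beta


def graphical_lasso_matrix(S: np.ndarray, Rho: np.ndarray, max_iter: int = 100,
                           tol: float = 1e-4) -> np.ndarray:
    """Sparse inverse covariance with an elementwise L1 penalty matrix.

    Friedman block-coordinate descent; ``Rho`` must be symmetric with zero
    (or small) diagonal. Returns the precision matrix Theta.
    """
    p = S.shape[0]
    if p == 1:
        return np.array([[1.0 / max(S[0, 0], 1e-12)]])
    W = S.copy()
    np.fill_diagonal(W, np.diag(S) + np.diag(Rho))
    B = np.zeros((p, p))
    offdiag = np.mean(np.abs(S - np.diag(np.diag(S)))) or 1.0
    for _ in range(max_iter):
        W_prev = W.copy()
        for j in range(p):
            idx = np.arange(p) != j
            beta = _lasso_cd(W[np.ix_(idx, idx)], S[idx, j], Rho[idx, j],
                             B[idx, j].copy())
            B[idx, j] = beta
            w12 = W[np.ix_(idx, idx)] @ beta
            W[idx, j] = w12
            W[j, idx] = w12
        if np.mean(np.abs(W - W_prev)) < tol * offdiag:
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        idx = np.arange(p) != j
        denom = W[j, j] - W[idx, j] @ B[idx, j]
        theta_jj = 1.0 / max(denom, 1e-12)
        Theta[j, j] = theta_jj
        Theta[idx, j] = -B[idx, j] * theta_jj
    return (Theta + Theta.T) / 2.0


def _partial_correlations(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(Theta), 1e-12, None))
    return -Theta / np.outer(d, d)


# ------------------------------------------------------------- co-accessibility

def compute_coaccessibility(metacells: np.ndarray, meta_peaks: pd.DataFrame,
                            window: int = DEFAULT_WINDOW,
                            coaccess_cutoff: float = DEFAULT_COACCESS_CUTOFF,
                            base_penalty: float = DEFAULT_BASE_PENALTY) -> pd.DataFrame:
    """Co-accessibility scores for same-chromosome peak pairs.

    Windows of ``window`` bp advance by window/2 (50% overlap) along each
    chromosome; within a window, standardized log1p metacell accessibility
    enters a graphical lasso whose elementwise penalty is
    ``base_penalty * (1 + (distance/window)^2)``. Pair scores are negative
    rescaled partial correlations averaged over windows; pairs with score >=
    ``coaccess_cutoff`` are returned as (peak_a, peak_b, score, distance).
    """
    if metacells.shape[0] < 5:
        raise ValueError("need at least 5 metacells")
    Y = np.log1p(metacells)
    mid = ((meta_peaks.start + meta_peaks.end) // 2).to_numpy()
    peak_ids = np.asarray(meta_peaks.index)
    chroms = meta_peaks.chrom.to_numpy()
    acc: dict[tuple[str, str], list[float]] = {}
    dist: dict[tuple[str, str], int] = {}
    step = window // 2
    for chrom in sorted(pd.unique(chroms)):
        on = np.flatnonzero(chroms == chrom)
        lo, hi = mid[on].min(), mid[on].max()
        start = (lo // step) * step
        for w0 in range(int(start), int(hi) + 1, step):
            inwin = on[(mid[on] >= w0) & (mid[on] < w0 + window)]
            if len(inwin) < 2:
                continue
            sub = Y[:, inwin]
            sd = sub.std(axis=0)
            keep = sd > 0
            if keep.sum() < 2:
                warnings.warn(f"window {chrom}:{w0} degenerate; skipped")
                continue
            inwin = inwin[keep]
            Z = (sub[:, keep] - sub[:, keep].mean(axis=0)) / sd[keep]
            S = (Z.T @ Z) / Z.shape[0]
            d = np.abs(mid[inwin][:, None] - mid[inwin][None, :])
            Rho = base_penalty * (1.0 + (d / window) ** 2)
            np.fill_diagonal(Rho, 0.0)
            Theta = graphical_lasso_matrix(S, Rho)
            P = _partial_correlations(Theta)
            for a in range(len(inwin)):
                for b in range(a + 1, len(inwin)):
                    key = (peak_ids[inwin[a]], peak_ids[inwin[b]])
                    acc.setdefault(key, []).append(P[a, b])
                    dist[key] = int(d[a, b])
    rows = [(a, b, float(np.mean(v)), dist[(a, b)])
            for (a, b), v in sorted(acc.items())]
    out = pd.DataFrame(rows, columns=["peak_a", "peak_b", "score", "distance"])
    return out[out.score >= coaccess_cutoff].reset_index(drop=True)


# ------------------------------------------------------------------- linkage

def type_mean_matrix(X, labels, feature_ids, log_normalize: bool = True) -> pd.DataFrame:
    """Feature x cell-type matrix of per-type mean (log1p-normalized) values."""
    V = normalize_log1p(X) if log_normalize else to_dense(X)
    cols = {g: V[idx].mean(axis=0) for g, idx in group_indices(labels).items()}
    return pd.DataFrame(cols, index=list(feature_ids))


def link_ccres(pairs: pd.DataFrame, peaks: pd.DataFrame, genes: pd.DataFrame,
               atac_type_means: pd.DataFrame, rna_type_means: pd.DataFrame,
               q_cut: float = 0.05) -> pd.DataFrame:
    """Gene-linked candidate cis-regulatory elements.

    For every co-accessible pair with exactly one promoter-side peak
    (midpoint within 1 kb of a TSS), the other peak's accessibility type
    means are correlated with each promoter gene's expression type means
    (Pearson, two-sided t-test with n_types - 2 df); q-values are
    Benjamini-Hochberg over all candidate links, retained at q < ``q_cut``.
    """
    common = [t for t in atac_type_means.columns if t in rna_type_means.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 shared cell types for correlation")
    prom = promoter_gene_map(peaks, genes)
    cand = []
    for _, row in pairs.iterrows():
        a_prom = row.peak_a in prom
        b_prom = row.peak_b in prom
        if a_prom == b_prom:  # neither, or both promoter-side
            continue
        prom_peak, distal_peak = ((row.peak_a, row.peak_b) if a_prom
                                  else (row.peak_b, row.peak_a))
        acc = atac_type_means.loc[distal_peak, common].to_numpy(dtype=float)
        for gene in prom[prom_peak]:
            if gene not in rna_type_means.index:
                continue
            expr = rna_type_means.loc[gene, common].to_numpy(dtype=float)
            if acc.std() == 0 or expr.std() == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(acc, expr)
            cand.append((distal_peak, gene, prom_peak, float(row.score),
                         float(r), float(p)))
    out = pd.DataFrame(cand, columns=["distal_peak", "gene", "promoter_peak",
                                      "coaccess", "pearson_r", "p"])
    if len(out) == 0:
        out["q"] = []
        return out
    out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out[out.q < q_cut].sort_values(["gene", "distal_peak"]).reset_index(drop=True)


# ------------------------------------------------------------------ TF targets

def identify_tf_targets(motif_id: str, motifs: MotifHits, links: pd.DataFrame,
                        peaks: pd.DataFrame, genes: pd.DataFrame,
                        detection_by_type: pd.DataFrame, cell_type: str,
                        min_detection: float = 0.05) -> pd.DataFrame:
    """Candidate target genes of one TF in one cell type.

    A gene is a target when (a) one of its promoter peaks is accessible in
    the cell type (detected in >= ``min_detection`` of its cells) and carries
    the motif (evidence ``promoter_motif``), or (b) a cis-regulatory element
    linked to the gene is accessible and carries the motif (evidence
    ``linked_ccre``). ``detection_by_type`` is a peak x cell-type detection
    fraction table.
    """
    if motif_id not in motifs.motif_ids:
        raise KeyError(f"unknown motif {motif_id!r}")
    if cell_type not in detection_by_type.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    hit_set = set(motifs.hit_peaks(motif_id))
    det = detection_by_type[cell_type]
    accessible = set(det.index[det >= min_detection])
    prom = promoter_gene_map(peaks, genes)
    records = []
    for p, gs in prom.items():
        if p in hit_set and p in accessible:
            for g in gs:
                records.append((motif_id, g, "promoter_motif", p))
    for _, row in links.iterrows():
        if row.distal_peak in hit_set and row.distal_peak in accessible:
            records.append((motif_id, row.gene, "linked_ccre", row.distal_peak))
    out = pd.DataFrame(records, columns=["tf", "target", "evidence", "peak"])
    return out.drop_duplicates().sort_values(
        ["target", "evidence", "peak"]).reset_index(drop=True)


def build_network(tf_target_pairs: pd.DataFrame, deg_flags=()) -> nx.DiGraph:
    """Directed TF -> target network with per-edge evidence and DEG flags.

    Duplicate (TF, target) rows collapse to one edge carrying every distinct
    evidence record; node attribute ``is_deg`` marks genes in ``deg_flags``.
    """
    G = nx.DiGraph()
    deg_set = set(deg_flags)
    for _, row in tf_target_pairs.iterrows():
        ev = (row.evidence, row.get("peak", None))
        if G.has_edge(row.tf, row.target):
            if ev not in G[row.tf][row.target]["evidence"]:
                G[row.tf][row.target]["evidence"].append(ev)
        else:
            G.add_edge(row.tf, row.target, evidence=[ev])
    for n in G.nodes:
        G.nodes[n]["is_deg"] = n in deg_set
    return G


# --------------------------------------------------------------- module score

def score_gene_module(log_expr: np.ndarray, gene_ids, gene_set,
                      n_bins: int = 24, n_ctrl: int = 100,
                      seed: int = 0) -> np.ndarray:
    """Per-cell module score: mean over the gene set minus the mean over
    expression-bin-matched control genes.

    Genes are binned into ``n_bins`` groups by mean expression; for each set
    gene, ``n_ctrl`` control genes are drawn (with replacement, seeded) from
    its bin. Operates on log-normalized expression (cells x genes).
    """
    gene_ids = list(gene_ids)
    gene_set = [g for g in gene_set]
    if len(gene_set) == 0:
        raise ValueError("gene set is empty")
    pos = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in gene_set if g not in pos]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    X = np.asarray(log_expr, dtype=float)
    means = X.mean(axis=0)
    order = np.argsort(means, kind="stable")
    bins = np.empty(len(gene_ids), dtype=int)
    bins[order] = (np.arange(len(gene_ids)) * n_bins) // len(gene_ids)
    rng = np.random.default_rng(seed)
    set_idx = np.array([pos[g] for g in gene_set])
    ctrl_idx = []
    for gi in set_idx:
        pool = np.flatnonzero(bins == bins[gi])
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
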