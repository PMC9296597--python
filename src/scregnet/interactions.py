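"""Ligand-receptor interaction inference via cluster-label permutation tests.

A (pair, source cluster, target cluster) triple is testable when the ligand
has a nonzero count in at least ``min_frac`` of source cells and the receptor
in at least ``min_frac`` of target cells. The interaction strength is the
average of the two cluster means of log-normalized expression; significance
comes from shuffling cluster labels and recomputing the statistic, with the
add-one estimator p = (1 + #{permuted >= observed}) / (1 + n_perm), which is
conservative and never returns zero. Significant triples require p < 0.05
and mean strength >= 1. Multi-subunit complexes are out of scope: the pair
table is flat gene-gene pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import group_indices, normalize_log1p, to_dense

MIN_CLUSTER_CELLS = 10


def compute_interaction_means(expr, labels, pairs: pd.DataFrame,
                              min_frac: float = 0.1) -> pd.DataFrame:
    """Testable (pair, source, target) triples with observed mean strength.

    ``expr`` holds raw counts (cells x genes, AnnData or array-with-names via
    ``expr.var_names``); ``pairs`` has columns (ligand, receptor). Clusters
    with fewer than 10 cells are excluded with a warning.
    """
    gene_ids = list(expr.var_names)
    pos = {g: i for i, g in enumerate(gene_ids)}
    raw = to_dense(expr.X)
    logn = normalize_log1p(raw)
    groups = {g: idx for g, idx in group_indices(labels).items()}
    small = [g for g, idx in groups.items() if len(idx) < MIN_CLUSTER_CELLS]
    for g in small:
        warnings.warn(f"cluster {g!r} has fewer than {MIN_CLUSTER_CELLS} "
                      "cells; excluded")
        groups.pop(g)
    clusters = sorted(groups)
    expr_frac = {g: (raw[idx] > 0).mean(axis=0) for g, idx in groups.items()}
    mean_log = {g: logn[idx].mean(axis=0) for g, idx in groups.items()}
    rows = []
    for pi, pair in pairs.iterrows():
        lig, rec = pair.ligand, pair.receptor
        if lig not in pos or rec not in pos:
            warnings.warn(f"pair ({lig}, {rec}) absent from matrix; skipped")
            continue
        li, ri = pos[lig], pos[rec]
        pair_id = pair.get("pair_id", f"{lig}_{rec}")
        for src in clusters:
            if expr_frac[src][li] < min_frac:
                continue
            for tgt in clusters:
                if expr_frac[tgt][ri] < min_frac:
                    continue
                mean = 0.5 * (mean_log[src][li] + mean_log[tgt][ri])
                rows.append((pair_id, lig, rec, src, tgt, float(mean)))
    return pd.DataFrame(rows, columns=["pair_id", "ligand", "receptor",
                                       "source", "target", "mean"])


def permutation_test(expr, labels, triples: pd.DataFrame, n_perm: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Add-one permutation p-value for every testable triple.

    Cluster labels are shuffled ``n_perm`` times (cluster sizes preserved);
    for each triple, p = (1 + #{permuted mean >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(triples) == 0:
        out = triples.copy()
        out["p"] = []
        return out
    gene_ids = list(expr.var_names)
    pos = {g: i for i, g in enumerate(gene_ids)}
    logn = normalize_log1p(to_dense(expr.X))
    labels = np.asarray(labels)
    clusters = sorted(pd.unique(labels))
    c_index = {c: i for i, c in enumerate(clusters)}
    used_genes = sorted({*triples.ligand, *triples.receptor})
    g_index = {g: i for i, g in enumerate(used_genes)}
    sub = logn[:, [pos[g] for g in used_genes]]
    lig_col = triples.ligand.map(g_index).to_numpy()
    rec_col = triples.receptor.map(g_index).to_numpy()
    src_idx = triples.source.map(c_index).to_numpy()
    tgt_idx = triples.target.map(c_index).to_numpy()
    onehot = np.zeros((len(clusters), len(labels)))
    for c, i in c_index.items():
        onehot[i, labels == c] = 1.0
    onehot /= onehot.sum(axis=1, keepdims=True)
    # observed statistic through the identical code path as the permutations,
    # so exact ties (e.g. constant expression) compare as equal
    means0 = onehot @ sub
    observed = 0.5 * (means0[src_idx, lig_col] + means0[tgt_idx, rec_col])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(triples), dtype=int)
    perm = np.arange(len(labels))
    for _ in range(n_perm):
        rng.shuffle(perm)
        means = onehot @ sub[perm]  # clusters x used genes
        stat = 0.5 * (means[src_idx, lig_col] + means[tgt_idx, rec_col])
        exceed += stat >= observed
    out = triples.copy()
    out["p"] = (1.0 + exceed) / (1.0 + n_perm)
    return out


def select_significant(results: pd.DataFrame, p_cut: float = 0.05,
                       mean_cut: float = 1.0):
    """Flag significant triples (p < p_cut and mean >= mean_cut) and count
    them per (source, target) cluster pair.

    Returns ``(flagged results, count matrix)``; the count matrix rows are
    source clusters, columns target clusters.
    """
    out = results.copy()
    out["significant"] = (out.p < p_cut) & (out["mean"] >= mean_cut)
    clusters = sorted(set(out.source) | set(out.target))
    counts = pd.DataFrame(0, index=clusters, columns=clusters)
    sig = out[out.significant]
    for (src, tgt), sub in sig.groupby(["source", "target"]):
        counts.loc[src, tgt] = len(sub)
    return out, counts
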