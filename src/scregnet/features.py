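"""Gene-activity scores, peak annotation, differential features and the
DAR-DEG association summary.

Gene activity sums ATAC counts over peaks whose midpoint falls in the gene
body extended 2 kb upstream of the TSS (strand-aware). Peaks are annotated as
promoter (midpoint within 1 kb of a TSS, takes precedence), gene_body, or
distal. Differential features use a one-vs-rest two-sided Wilcoxon rank-sum
test on depth-normalized (counts-per-10k, log1p) values with Bonferroni
correction over every (feature, group) test; the reported log2 fold change is
log2((m_in + 1)/(m_out + 1)) on group means of the counts-per-10k scale, so a
pseudocount of one stabilizes sparse means. The rank-sum test stands in for
the hurdle-model test sometimes used for droplet RNA data; the thresholds
(adjusted P < 0.05, log2FC > 0.25), not the test family, carry the procedure.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._utils import group_indices, normalize_cp, normalize_log1p, to_dense

UPSTREAM_BP = 2000
PROMOTER_BP = 1000


def _check_strands(genes: pd.DataFrame) -> None:
    bad = set(genes.strand) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbol(s): {sorted(bad)}")


def gene_regions(genes: pd.DataFrame) -> pd.DataFrame:
    """[lo, hi) activity region per gene: body plus 2 kb upstream of the TSS."""
    _check_strands(genes)
    lo = np.where(genes.strand == "+", genes.start - UPSTREAM_BP, genes.start)
    hi = np.where(genes.strand == "+", genes.end, genes.end + UPSTREAM_BP)
    return pd.DataFrame({"chrom": genes.chrom, "lo": lo, "hi": hi},
                        index=genes.index)


def gene_activity_scores(atac, peaks: pd.DataFrame, genes: pd.DataFrame):
    """Cells x genes activity matrix from peak counts.

    A peak contributes its full counts to every gene whose activity region
    contains the peak midpoint. Total activity is bounded by total ATAC counts
    times the maximum number of genes any peak is assigned to (one, for
    non-overlapping gene regions).
    """
    import anndata as ad

    regions = gene_regions(genes)
    mid = ((peaks.start + peaks.end) // 2).to_numpy()
    pchrom = peaks.chrom.to_numpy()
    rows, cols = [], []
    for j, (g, reg) in enumerate(regions.iterrows()):
        mask = (pchrom == reg.chrom) & (mid >= reg.lo) & (mid < reg.hi)
        idx = np.flatnonzero(mask)
        rows.extend(idx)
        cols.extend([j] * len(idx))
    ind = sp.csr_matrix((np.ones(len(rows)), (rows, cols)),
                        shape=(len(peaks), len(genes)))
    X = sp.csr_matrix(atac.X) @ ind
    return ad.AnnData(X=sp.csr_matrix(X), obs=atac.obs.copy(),
                      var=pd.DataFrame(index=genes.index.copy()))


def annotate_peak(chrom: str, midpoint: int, genes: pd.DataFrame) -> str:
    """Category of one peak midpoint: promoter > gene_body > distal."""
    sub = genes[genes.chrom == chrom]
    if (np.abs(sub.tss - midpoint) <= PROMOTER_BP).any():
        return "promoter"
    if ((sub.start <= midpoint) & (midpoint < sub.end)).any():
        return "gene_body"
    return "distal"


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Vectorized promoter/gene_body/distal category per peak."""
    mid = (peaks.start + peaks.end) // 2
    out = []
    for p in peaks.index:
        out.append(annotate_peak(peaks.loc[p, "chrom"], int(mid.loc[p]), genes))
    return pd.Series(out, index=peaks.index, name="category")


def promoter_gene_map(peaks: pd.DataFrame, genes: pd.DataFrame) -> dict[str, list[str]]:
    """peak id -> genes whose TSS is within 1 kb of the peak midpoint."""
    mid = ((peaks.start + peaks.end) // 2).to_numpy()
    out: dict[str, list[str]] = {}
    for i, p in enumerate(peaks.index):
        sub = genes[(genes.chrom == peaks.chrom.iloc[i])
                    & (np.abs(genes.tss - mid[i]) <= PROMOTER_BP)]
        if len(sub):
            out[p] = list(sub.index)
    return out


def body_gene_map(peaks: pd.DataFrame, genes: pd.DataFrame) -> dict[str, list[str]]:
    """peak id -> genes whose body contains the peak midpoint."""
    mid = ((peaks.start + peaks.end) // 2).to_numpy()
    out: dict[str, list[str]] = {}
    for i, p in enumerate(peaks.index):
        sub = genes[(genes.chrom == peaks.chrom.iloc[i])
                    & (genes.start <= mid[i]) & (mid[i] < genes.end)]
        if len(sub):
            out[p] = list(sub.index)
    return out


def find_differential_features(X, feature_ids, labels, min_log2fc: float = 0.25,
                               alpha: float = 0.05,
                               return_all: bool = False) -> pd.DataFrame:
    """One-vs-rest differential features (Wilcoxon rank-sum, Bonferroni).

    Returns rows with columns (feature, group, log2fc, p, p_adj, direction);
    by default only up-regulated significant rows (p_adj < alpha and
    log2fc > min_log2fc) are returned, `return_all` disables the gate.
    """
    feature_ids = list(feature_ids)
    groups = group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    logn = normalize_log1p(X)
    cp = normalize_cp(X)
    n = logn.shape[0]
    tested = []
    for g, idx in groups.items():
        if len(idx) < 3 or n - len(idx) < 3:
            warnings.warn(f"group {g!r} has fewer than 3 cells on one side; skipped")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        with np.errstate(all="ignore"):
            res = mannwhitneyu(logn[mask], logn[~mask], axis=0,
                               alternative="two-sided")
        p = np.nan_to_num(res.pvalue, nan=1.0)
        m_in = cp[mask].mean(axis=0)
        m_out = cp[~mask].mean(axis=0)
        lfc = np.log2((m_in + 1.0) / (m_out + 1.0))
        tested.append(pd.DataFrame({
            "feature": feature_ids, "group": g, "log2fc": lfc, "p": p,
        }))
    if not tested:
        return pd.DataFrame(columns=["feature", "group", "log2fc", "p",
                                     "p_adj", "direction"])
    table = pd.concat(tested, ignore_index=True)
    table["p_adj"] = np.minimum(table.p * len(table), 1.0)
    table["direction"] = np.where(table.log2fc >= 0, "up", "down")
    if not return_all:
        table = table[(table.p_adj < alpha) & (table.log2fc > min_log2fc)]
    return table.reset_index(drop=True)


def dar_deg_association(dars: pd.DataFrame, degs: pd.DataFrame,
                        peaks: pd.DataFrame, genes: pd.DataFrame,
                        ccre_links=()) -> dict:
    """Per-group proportion of DARs associated with a same-group DEG.

    A DAR is associated when its peak is a promoter or gene-body peak of a
    same-group DEG, or is linked to such a gene by a candidate cis-regulatory
    element (``ccre_links``: iterable of (peak id, gene id)). Returns
    ``{"per_group": Series, "mean": float, "sd": float}`` (SD over groups,
    ddof=1; NaN with a single group).
    """
    prom = promoter_gene_map(peaks, genes)
    body = body_gene_map(peaks, genes)
    link_map: dict[str, set] = {}
    for p, g in ccre_links:
        link_map.setdefault(p, set()).add(g)
    deg_by_group = {g: set(sub.feature) for g, sub in degs.groupby("group")}
    props = {}
    for g, sub in dars.groupby("group"):
        deg_set = deg_by_group.get(g, set())
        n_assoc = 0
        for p in sub.feature:
            linked = set(prom.get(p, [])) | set(body.get(p, [])) | link_map.get(p, set())
            if linked & deg_set:
                n_assoc += 1
        props[g] = n_assoc / len(sub) if len(sub) else 0.0
    per_group = pd.Series(props, dtype=float).sort_index()
    mean = float(per_group.mean()) if len(per_group) else float("nan")
    sd = float(per_group.std(ddof=1)) if len(per_group) > 1 else float("nan")
    return {"per_group": per_group, "mean": mean, "sd": sd}
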