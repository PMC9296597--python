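"""Tumor-specific TF selection (double-MAD variability gate + specificity
thresholds) and the perturbation-Z-score drug screen.

A TF's variability is the population SD, across cell types, of its per-type
mean bias-corrected deviation. Because the distribution of these SDs is
asymmetric, the outlier threshold uses the upper side of the double-MAD
scheme: threshold = median + multiplier x median(|x - median| for x >=
median), with no normal-consistency constant. Candidates must additionally
be strongly and exclusively active in the target group (activity_delta >
fc_in with adjusted P < alpha there, and < fc_out_max in every other group).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import group_indices
from .deviation import DeviationMatrix
from .synthetic import DrugGeneZ


def tf_variability(dev: DeviationMatrix, labels) -> pd.DataFrame:
    """Per-motif group means of bias-corrected deviations and their SD.

    Returns a DataFrame indexed by motif with one ``mean_<group>`` column per
    group and ``sd_across_groups`` (population SD over the group means).
    """
    groups = group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups to compute variability")
    D = dev.deviations.to_numpy()
    cols = {}
    for g, idx in groups.items():
        cols[f"mean_{g}"] = np.nanmean(D[idx], axis=0)
    out = pd.DataFrame(cols, index=dev.deviations.columns)
    out["sd_across_groups"] = out.to_numpy().std(axis=1, ddof=0)
    out.index.name = "motif"
    return out


def double_mad_threshold(values, multiplier: float = 4.0) -> float:
    """Upper-tail double-MAD outlier threshold.

    m = median(values); right-MAD = median(|x - m| for x >= m);
    threshold = m + multiplier * right-MAD. Even-length medians are the mean
    of the central pair; no consistency constant is applied.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("values must be non-empty")
    m = float(np.median(x))
    right = np.abs(x[x >= m] - m)
    return m + multiplier * float(np.median(right))


def select_specific_tfs(diff: pd.DataFrame, variab: pd.DataFrame,
                        target_group: str, fc_in: float = 4.0,
                        fc_out_max: float = 1.0, alpha: float = 1e-4,
                        multiplier: float = 4.0,
                        return_table: bool = False):
    """Motifs passing the variability gate and the in/out specificity gates.

    The variability threshold is computed over ALL motifs' SDs. A motif is
    selected when (i) sd_across_groups > threshold, (ii) activity_delta >
    fc_in with p_adj < alpha in ``target_group`` and (iii) activity_delta <
    fc_out_max in every other group. With ``return_table`` the full candidate
    table (per-gate pass flags) is returned alongside the selected list.
    """
    if target_group not in set(diff.group):
        raise ValueError(f"target group {target_group!r} absent from "
                         "differential table")
    sds = variab.sd_across_groups
    thr = double_mad_threshold(sds.to_numpy(), multiplier=multiplier)
    wide_delta = diff.pivot(index="motif", columns="group",
                            values="activity_delta")
    wide_padj = diff.pivot(index="motif", columns="group", values="p_adj")
    motifs = wide_delta.index
    others = [g for g in wide_delta.columns if g != target_group]
    table = pd.DataFrame(index=motifs)
    table["sd"] = sds.reindex(motifs)
    table["sd_threshold"] = thr
    table["pass_variability"] = table.sd > thr
    table["delta_in"] = wide_delta[target_group]
    table["p_adj_in"] = wide_padj[target_group]
    table["pass_in"] = (table.delta_in > fc_in) & (table.p_adj_in < alpha)
    table["max_delta_out"] = wide_delta[others].max(axis=1) if others else -np.inf
    table["pass_out"] = table.max_delta_out < fc_out_max
    table["selected"] = (table.pass_variability & table.pass_in & table.pass_out)
    table.attrs["mad_multiplier"] = multiplier
    table.attrs["mad_consistency_constant"] = "none (raw right-sided MAD)"
    selected = sorted(table.index[table.selected])
    return (selected, table) if return_table else selected


def screen_drugs(z: DrugGeneZ, tf_gene: str, z_cut: float = -2.0) -> list[str]:
    """Approved drugs that down-regulate ``tf_gene`` (Z < z_cut strictly),
    sorted by ascending Z (strongest down-regulation first)."""
    if tf_gene not in z.z.columns:
        raise KeyError(f"gene {tf_gene!r} not in the perturbation matrix")
    col = z.z[tf_gene]
    approved = set(z.approved)
    hits = col[(col < z_cut) & col.index.isin(approved)]
    return list(hits.sort_values().index)
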