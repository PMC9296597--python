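"""Per-cell quality-control gates and cross-annotation consistency.

RNA cells are kept when 200 <= detected genes <= 6000, UMI > 1000 and
mitochondrial fraction <= 0.10; ATAC cells when 1000 < peak-region fragments
< 20000, FRiP > 0.15, blacklist ratio < 0.05, nucleosome signal < 4 and TSS
enrichment > 3. The gene-number bounds are inclusive; every other gate is a
strict inequality. High-mitochondrial cells are excluded (low-quality-cell
removal); the gate boundary itself (exactly 0.10) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RNA_GATES = ("gene_number_low", "gene_number_high", "umi_count", "mito_fraction")
ATAC_GATES = ("fragments_low", "fragments_high", "frip", "blacklist_ratio",
              "nucleosome_signal", "tss_enrichment")


@dataclass
class RnaQcMetrics:
    cell_id: str
    n_genes: int
    n_umi: int
    mito_fraction: float


@dataclass
class AtacQcMetrics:
    cell_id: str
    peak_region_fragments: int
    frip: float
    blacklist_ratio: float
    nucleosome_signal: float
    tss_enrichment: float


def _as_frame(metrics, fields) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        if "cell_id" in metrics.columns:
            return metrics.set_index("cell_id")
        return metrics
    rows = [[getattr(m, f) for f in fields] for m in metrics]
    return pd.DataFrame(rows, columns=list(fields)).set_index("cell_id")


def rna_qc_audit(metrics) -> pd.DataFrame:
    """Boolean pass table per cell, one column per RNA gate plus 'kept'."""
    df = _as_frame(metrics, ("cell_id", "n_genes", "n_umi", "mito_fraction"))
    audit = pd.DataFrame({
        "gene_number_low": df.n_genes >= 200,
        "gene_number_high": df.n_genes <= 6000,
        "umi_count": df.n_umi > 1000,
        "mito_fraction": df.mito_fraction <= 0.10,
    }, index=df.index)
    audit["kept"] = audit.all(axis=1)
    return audit


def filter_rna_cells(metrics) -> list[str]:
    """Kept cell ids after the RNA QC gates, input order preserved."""
    audit = rna_qc_audit(metrics)
    return list(audit.index[audit.kept])


def atac_qc_audit(metrics) -> pd.DataFrame:
    """Boolean pass table per cell, one column per ATAC gate plus 'kept'."""
    df = _as_frame(metrics, ("cell_id", "peak_region_fragments", "frip",
                             "blacklist_ratio", "nucleosome_signal",
                             "tss_enrichment"))
    audit = pd.DataFrame({
        "fragments_low": df.peak_region_fragments > 1000,
        "fragments_high": df.peak_region_fragments < 20000,
        "frip": df.frip > 0.15,
        "blacklist_ratio": df.blacklist_ratio < 0.05,
        "nucleosome_signal": df.nucleosome_signal < 4,
        "tss_enrichment": df.tss_enrichment > 3,
    }, index=df.index)
    audit["kept"] = audit.all(axis=1)
    return audit


def filter_atac_cells(metrics) -> list[str]:
    """Kept cell ids after the ATAC QC gates, input order preserved."""
    audit = atac_qc_audit(metrics)
    return list(audit.index[audit.kept])


def jaccard_index(labels_a: dict, labels_b: dict) -> pd.DataFrame:
    """Jaccard consistency matrix between two labelings of one cell universe.

    Entry (x, y) = |cells(a=x) & cells(b=y)| / |cells(a=x) | cells(b=y)|.
    """
    cells_a, cells_b = set(labels_a), set(labels_b)
    if not cells_a & cells_b:
        raise ValueError("label maps share no cells")
    sets_a: dict[str, set] = {}
    for c, lab in labels_a.items():
        sets_a.setdefault(lab, set()).add(c)
    sets_b: dict[str, set] = {}
    for c, lab in labels_b.items():
        sets_b.setdefault(lab, set()).add(c)
    rows = sorted(sets_a)
    cols = sorted(sets_b)
    out = np.zeros((len(rows), len(cols)))
    for i, x in enumerate(rows):
        for j, y in enumerate(cols):
            inter = len(sets_a[x] & sets_b[y])
            union = len(sets_a[x] | sets_b[y])
            out[i, j] = inter / union if union else 0.0
    return pd.DataFrame(out, index=rows, columns=cols)
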