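"""Readers and writers for the standard on-disk formats.

Count matrices are exchanged as Matrix Market (.mtx) with sidecar
``barcodes.tsv`` / ``features.tsv`` label files (cells are matrix rows);
peaks as 6-column BED plus a ``gc.tsv`` sidecar; gene models, annotation and
result tables as TSV; ground truth as JSON.
"""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .synthetic import GroundTruth, MotifHits


def write_counts(prefix: str, adata: ad.AnnData) -> None:
    """Write cells x features counts as <prefix>.mtx + barcode/feature TSVs."""
    scipy.io.mmwrite(prefix + ".mtx", sp.coo_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(prefix + ".barcodes.tsv",
                                      index=False, header=False)
    pd.Series(adata.var_names).to_csv(prefix + ".features.tsv",
                                      index=False, header=False)


def read_counts(prefix: str) -> ad.AnnData:
    X = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    obs = pd.read_csv(prefix + ".barcodes.tsv", header=None)[0].astype(str)
    var = pd.read_csv(prefix + ".features.tsv", header=None)[0].astype(str)
    if X.shape != (len(obs), len(var)):
        raise ValueError(f"{prefix}: matrix shape {X.shape} does not match "
                         f"label files ({len(obs)} x {len(var)})")
    return ad.AnnData(X=X, obs=pd.DataFrame(index=obs.to_numpy()),
                      var=pd.DataFrame(index=var.to_numpy()))


def write_peaks(path_bed: str, peaks: pd.DataFrame) -> None:
    """Write peaks as 6-column BED; GC fractions go to a <bed>.gc.tsv sidecar."""
    bed = pd.DataFrame({
        "chrom": peaks.chrom, "start": peaks.start, "end": peaks.end,
        "name": peaks.index, "score": 0, "strand": ".",
    })
    bed.to_csv(path_bed, sep="\t", index=False, header=False)
    peaks[["gc"]].to_csv(path_bed + ".gc.tsv", sep="\t")


def read_peaks(path_bed: str) -> pd.DataFrame:
    bed = pd.read_csv(path_bed, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    peaks = bed.set_index("name")[["chrom", "start", "end"]]
    peaks.index.name = "peak_id"
    gc_path = path_bed + ".gc.tsv"
    if os.path.exists(gc_path):
        gc = pd.read_csv(gc_path, sep="\t", index_col=0)
        peaks["gc"] = gc["gc"].reindex(peaks.index).to_numpy()
    return peaks


def write_motif_hits(prefix: str, motifs: MotifHits) -> None:
    scipy.io.mmwrite(prefix + ".mtx", sp.coo_matrix(motifs.matrix))
    pd.Series(motifs.peak_ids).to_csv(prefix + ".peaks.tsv",
                                      index=False, header=False)
    pd.Series(motifs.motif_ids).to_csv(prefix + ".motifs.tsv",
                                       index=False, header=False)


def read_motif_hits(prefix: str) -> MotifHits:
    X = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx")).astype(np.int8)
    peak_ids = pd.read_csv(prefix + ".peaks.tsv", header=None)[0].tolist()
    motif_ids = pd.read_csv(prefix + ".motifs.tsv", header=None)[0].tolist()
    return MotifHits(matrix=X, peak_ids=peak_ids, motif_ids=motif_ids)


def write_truth(path: str, truth: GroundTruth) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def read_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_json(fh.read())
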