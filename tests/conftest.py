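import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from scregnet.synthetic import MotifHits, SyntheticConfig, generate_multiome

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_multiome():
    """One full-scale synthetic multiome shared across read-only tests."""
    return generate_multiome(SyntheticConfig(seed=1))


def small_config(seed=3, **overrides):
    base = dict(
        n_samples=2, n_cell_types=3, cells_per_type_per_sample=50,
        n_genes=150, n_peaks=120, markers_per_type=5, n_planted_ccres=8,
        n_lr_pairs=8, n_planted_lr=3, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_multiome():
    return generate_multiome(small_config())


def make_adata(counts, cell_ids=None, feature_ids=None):
    counts = np.asarray(counts)
    cells = cell_ids or [f"c{i}" for i in range(counts.shape[0])]
    feats = feature_ids or [f"f{j}" for j in range(counts.shape[1])]
    return ad.AnnData(X=sp.csr_matrix(counts.astype(float)),
                      obs=pd.DataFrame(index=cells),
                      var=pd.DataFrame(index=feats))


def make_motifs(hit_matrix, peak_ids=None, motif_ids=None):
    hit_matrix = np.asarray(hit_matrix)
    peaks = peak_ids or [f"P{i}" for i in range(hit_matrix.shape[0])]
    motifs = motif_ids or [f"M{j}" for j in range(hit_matrix.shape[1])]
    return MotifHits(matrix=sp.csr_matrix(hit_matrix.astype(np.int8)),
                     peak_ids=list(peaks), motif_ids=list(motifs))
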