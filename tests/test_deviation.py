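"""Motif deviation scores: closed form, background matching, differential."""

import numpy as np
import pandas as pd
import pytest

from scregnet.deviation import (compute_deviations, differential_tf_activity,
                                raw_deviations, sample_background_peaks)

from conftest import make_adata, make_motifs


def brute_force_deviations(A, M, backgrounds, n_iter):
    """Independent loop-based implementation of the deviation statistic."""
    A = np.asarray(A, dtype=float)
    n_cells, n_peaks = A.shape
    n_motifs = M.shape[1]
    grand = A.sum()
    tot = A.sum(axis=1)
    dev = np.zeros((n_cells, n_motifs))
    z = np.zeros((n_cells, n_motifs))

    def raw_for(peak_multiset):
        out = np.zeros(n_cells)
        f = sum(A[:, p].sum() for p in peak_multiset) / grand
        for j in range(n_cells):
            X = sum(A[j, p] for p in peak_multiset)
            E = f * tot[j]
            out[j] = X / E - 1.0 if E > 0 else np.nan
        return out

    for m in range(n_motifs):
        hits = [p for p in range(n_peaks) if M[p, m]]
        raw = raw_for(hits)
        bg = np.array([raw_for([backgrounds[p, i] for p in hits])
                       for i in range(n_iter)])
        dev[:, m] = raw - bg.mean(axis=0)
        z[:, m] = (raw - bg.mean(axis=0)) / bg.std(axis=0, ddof=1)
    return dev, z


def test_hand_computed_closed_form():
    # 2 cells, 3 peaks, motif on peaks {0, 1}; c1=(6,0,2), c2=(0,0,4)
    atac = make_adata([[6, 0, 2], [0, 0, 4]])
    motifs = make_motifs([[1], [1], [0]])
    raw = raw_deviations(atac, motifs).to_numpy().ravel()
    # f = 0.5, E = (4, 2), raw = (6/4-1, 0/2-1) = (+0.5, -1.0)
    assert raw == pytest.approx([0.5, -1.0])


def test_proportional_cells_have_zero_raw_deviation():
    base = np.array([3.0, 1.0, 5.0, 2.0])
    atac = make_adata(np.vstack([base, 2 * base, 5 * base]))
    motifs = make_motifs([[1, 0], [1, 1], [0, 1], [0, 0]])
    raw = raw_deviations(atac, motifs).to_numpy()
    assert np.allclose(raw, 0.0, atol=1e-12)


def test_self_backgrounds_cancel_exactly():
    rng = np.random.default_rng(0)
    atac = make_adata(rng.poisson(5, size=(6, 8)))
    motifs = make_motifs(rng.integers(0, 2, size=(8, 3)) | 0)
    identity = np.tile(np.arange(8)[:, None], (1, 4))
    dev = compute_deviations(atac, motifs, identity)
    assert np.allclose(np.nan_to_num(dev.deviations.to_numpy()), 0.0)


def test_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    A = rng.poisson(6, size=(3, 4)).astype(float) + 1
    M = np.array([[1, 0], [1, 1], [0, 1], [1, 0]])
    backgrounds = rng.integers(0, 4, size=(4, 5))
    got = compute_deviations(make_adata(A), make_motifs(M), backgrounds)
    want_dev, want_z = brute_force_deviations(A, M, backgrounds, 5)
    assert np.abs(got.deviations.to_numpy() - want_dev).max() < 1e-12
    assert np.abs(got.z.to_numpy() - want_z).max() < 1e-12


def test_raw_deviation_depth_invariance():
    """Uniform depth rescaling leaves raw deviations untouched exactly;
    rescaling one cell of many changes its own deviation only through the
    (small) shift in the aggregate expectation."""
    rng = np.random.default_rng(1)
    A = rng.poisson(5, size=(100, 6)).astype(float) + 1
    motifs = make_motifs(rng.integers(0, 2, size=(6, 2)) | 0)
    base = raw_deviations(make_adata(A), motifs).to_numpy()
    uniform = raw_deviations(make_adata(A * 13.0), motifs).to_numpy()
    assert np.allclose(base, uniform, atol=1e-12)
    A2 = A.copy()
    A2[2] *= 10  # one cell of 100 sequenced 10x deeper
    scaled = raw_deviations(make_adata(A2), motifs).to_numpy()
    assert np.allclose(base[2], scaled[2], atol=0.1)


class TestBackgroundSampling:
    def _peaks(self, gc):
        n = len(gc)
        return pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * 1000,
                             "end": np.arange(n) * 1000 + 500,
                             "gc": gc},
                            index=[f"P{i}" for i in range(n)])

    def test_fixed_seed_is_deterministic_and_never_self(self):
        rng = np.random.default_rng(0)
        gc = rng.beta(6, 6, 300)
        atac = make_adata(rng.poisson(5, size=(20, 300)))
        peaks = self._peaks(gc)
        a = sample_background_peaks(peaks, atac, n_iter=10, k=30, seed=3)
        b = sample_background_peaks(peaks, atac, n_iter=10, k=30, seed=3)
        assert np.array_equal(a, b)
        assert (a != np.arange(300)[:, None]).all()

    def test_background_gc_tracks_peak_gc(self):
        rng = np.random.default_rng(7)
        n = 2000
        gc = rng.uniform(0.2, 0.8, n)
        atac = make_adata(rng.poisson(5, size=(10, n)))
        peaks = self._peaks(gc)
        bg = sample_background_peaks(peaks, atac, n_iter=20, k=50, seed=1)
        mean_bg_gc = gc[bg].mean(axis=1)
        r = np.corrcoef(gc, mean_bg_gc)[0, 1]
        assert r > 0.9

    def test_too_few_peaks_fail(self):
        rng = np.random.default_rng(0)
        peaks = self._peaks(rng.beta(6, 6, 10))
        atac = make_adata(rng.poisson(5, size=(4, 10)))
        with pytest.raises(ValueError, match="k\\+1"):
            sample_background_peaks(peaks, atac, k=50)


class TestDifferentialActivity:
    def _dev(self, values, cells, motifs=("M0",)):
        df = pd.DataFrame(values, index=cells, columns=list(motifs))
        from scregnet.deviation import DeviationMatrix
        return DeviationMatrix(deviations=df, z=df.copy(), n_background=10)

    def test_two_group_antisymmetry(self):
        rng = np.random.default_rng(0)
        cells = [f"c{i}" for i in range(30)]
        dev = self._dev(rng.normal(size=(30, 1)), cells)
        labels = ["A"] * 15 + ["B"] * 15
        out = differential_tf_activity(dev, labels, score="deviation")
        dA = out[out.group == "A"].activity_delta.iloc[0]
        dB = out[out.group == "B"].activity_delta.iloc[0]
        assert dA == pytest.approx(-dB)

    def test_identically_distributed_groups_not_significant(self):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(60)]
        dev = self._dev(rng.normal(size=(60, 1)), cells)
        out = differential_tf_activity(dev, ["A"] * 30 + ["B"] * 30)
        assert not out.significant.any()
        assert out.activity_delta.abs().max() < 1.0


def test_random_subset_motif_has_zero_mean_deviation():
    """Motifs hitting uniform random peak subsets are unbiased: the mean
    bias-corrected deviation across cells stays within 3 SE of zero."""
    means = []
    for seed in range(6):
        rng = np.random.default_rng(100 + seed)
        A = rng.poisson(8, size=(40, 120)).astype(float)
        M = (rng.random((120, 1)) < 0.15).astype(int)
        if M.sum() == 0:
            M[0, 0] = 1
        peaks = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(120) * 1000,
                              "end": np.arange(120) * 1000 + 500,
                              "gc": rng.beta(6, 6, 120)},
                             index=[f"P{i}" for i in range(120)])
        atac = make_adata(A)
        bg = sample_background_peaks(peaks, atac, n_iter=20, k=30, seed=seed)
        dev = compute_deviations(atac, make_motifs(M), bg)
        means.append(np.nanmean(dev.deviations.to_numpy()))
    means = np.array(means)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean()) < 3 * se
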