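"""Gene activity regions, peak annotation, differential features, DAR-DEG."""

import numpy as np
import pandas as pd
import pytest

from scregnet.features import (annotate_peak, dar_deg_association,
                               find_differential_features,
                               gene_activity_scores)

from conftest import make_adata


def toy_genes():
    return pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "strand": ["+", "-"],
         "tss": [5000, 28000], "start": [5000, 25000], "end": [8000, 28000]},
        index=["gplus", "gminus"])


def toy_peaks(mids):
    return pd.DataFrame({"chrom": "chr1",
                         "start": [m - 250 for m in mids],
                         "end": [m + 250 for m in mids]},
                        index=[f"P{i}" for i in range(len(mids))])


class TestGeneActivity:
    def test_strand_aware_regions(self):
        # + gene region [3000, 8000); - gene region [25000, 30000)
        peaks = toy_peaks([3500, 2900, 29500, 31000])
        atac = make_adata([[2, 3, 5, 7]], feature_ids=list(peaks.index))
        act = gene_activity_scores(atac, peaks, toy_genes())
        got = np.asarray(act.X.todense()).ravel()
        assert got[0] == 2          # only the 3500-midpoint peak upstream of +
        assert got[1] == 5          # 29500 lies in the - gene's 2 kb upstream
        assert act.var_names.tolist() == ["gplus", "gminus"]

    def test_unknown_strand_fails(self):
        genes = toy_genes()
        genes.loc["gplus", "strand"] = "?"
        with pytest.raises(ValueError, match="strand"):
            gene_activity_scores(make_adata([[1]]), toy_peaks([3500]), genes)

    def test_mass_conservation_on_synthetic_genome(self, default_multiome):
        _, atac, peaks, _, genes, _, _ = default_multiome
        act = gene_activity_scores(atac, peaks, genes)
        assert act.X.sum() <= atac.X.sum()


@pytest.mark.parametrize("mid,expected", [
    (5400, "promoter"),    # 400 bp from a TSS; promoter takes precedence
    (7000, "gene_body"),
    (150000, "distal"),
])
def test_annotate_peak(mid, expected):
    assert annotate_peak("chr1", mid, toy_genes()) == expected


class TestDifferential:
    def _toy(self, rng=None):
        rng = rng or np.random.default_rng(0)
        X = rng.poisson(5, size=(40, 6)).astype(float)
        X[:20, 0] = rng.poisson(40, 20)  # feature f0 up in group A
        X[:, 3] = 7.0                    # identical in both groups
        # equalize cell depths so depth normalization leaves f3 constant
        X[:, 5] = 120.0 - X[:, :5].sum(axis=1)
        assert (X[:, 5] >= 0).all()
        labels = ["A"] * 20 + ["B"] * 20
        return X, labels

    def test_all_vs_none_feature_is_significant(self):
        X = np.ones((40, 3))
        X[:, 1] = 0.0
        X[:20, 1] = 9.0  # nonzero only in group A
        out = find_differential_features(X, ["f0", "f1", "f2"],
                                         ["A"] * 20 + ["B"] * 20)
        hit = out[(out.feature == "f1") & (out.group == "A")]
        assert len(hit) == 1 and hit.p_adj.iloc[0] < 0.05

    def test_identical_feature_not_returned(self):
        X, labels = self._toy()
        out = find_differential_features(X, [f"f{i}" for i in range(6)], labels,
                                         return_all=True)
        row = out[(out.feature == "f3")]
        assert np.allclose(row.log2fc, 0.0)
        gated = find_differential_features(X, [f"f{i}" for i in range(6)], labels)
        assert "f3" not in set(gated.feature)

    def test_bonferroni_inflates_p(self):
        X, labels = self._toy()
        out = find_differential_features(X, [f"f{i}" for i in range(6)], labels,
                                         return_all=True)
        assert (out.p_adj >= out.p - 1e-15).all()
        assert (out.p_adj <= 1.0).all()

    def test_invariant_to_feature_order_and_depth_rescaling(self):
        X, labels = self._toy()
        feats = [f"f{i}" for i in range(6)]
        base = find_differential_features(X, feats, labels, return_all=True)
        perm = [3, 1, 5, 0, 2, 4]
        shuffled = find_differential_features(X[:, perm],
                                              [feats[i] for i in perm], labels,
                                              return_all=True)
        merged = base.merge(shuffled, on=["feature", "group"],
                            suffixes=("", "_s"))
        assert np.allclose(merged.log2fc, merged.log2fc_s)
        assert np.allclose(merged.p, merged.p_s)
        scaled = find_differential_features(X * 7.0, feats, labels,
                                            return_all=True)
        assert np.allclose(base.p, scaled.p)
        assert np.allclose(base.log2fc, scaled.log2fc)

    def test_small_group_skipped_with_warning(self):
        X = np.ones((23, 2))
        labels = ["A"] * 2 + ["B"] * 21
        with pytest.warns(UserWarning, match="fewer than 3"):
            find_differential_features(X, ["f0", "f1"], labels)


class TestDarDegAssociation:
    def _frame(self, pairs):
        return pd.DataFrame(pairs, columns=["feature", "group"])

    def test_no_degs_gives_zero(self):
        peaks = toy_peaks([5400, 150000])
        out = dar_deg_association(
            self._frame([("P0", "A"), ("P1", "A")]),
            self._frame([]), peaks, toy_genes())
        assert (out["per_group"] == 0).all()

    def test_all_promoter_dars_of_degs_give_one(self):
        peaks = toy_peaks([5400])
        out = dar_deg_association(self._frame([("P0", "A")]),
                                  self._frame([("gplus", "A")]),
                                  peaks, toy_genes())
        assert out["per_group"]["A"] == 1.0

    def test_matches_brute_force_on_explicit_sets(self):
        # P0 promoter of gplus; P1 body of gplus; P2 distal but cCRE-linked
        # to gminus; P3 distal unlinked.
        peaks = toy_peaks([5400, 7000, 150000, 180000])
        dars = self._frame([("P0", "A"), ("P1", "A"), ("P2", "A"),
                            ("P3", "A"), ("P0", "B")])
        degs = self._frame([("gplus", "A"), ("gminus", "A")])
        links = [("P2", "gminus")]
        out = dar_deg_association(dars, degs, peaks, toy_genes(), links)
        # brute force: A has 4 DARs, 3 associated (P0, P1, P2); B: P0's gene
        # gplus is not a B-group DEG
        assert out["per_group"]["A"] == pytest.approx(3 / 4)
        assert out["per_group"]["B"] == 0.0
        assert out["mean"] == pytest.approx((0.75 + 0.0) / 2)
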