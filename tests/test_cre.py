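"""Metacell pooling, co-accessibility, cCRE linkage, TF targets, module score."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.covariance import graphical_lasso as sklearn_glasso

from scregnet.cre import (aggregate_to_metacells, build_network,
                          compute_coaccessibility, graphical_lasso_matrix,
                          identify_tf_targets, link_ccres, score_gene_module,
                          type_mean_matrix)

from conftest import make_adata, make_motifs


def peak_frame(mids, chrom="chr1"):
    chroms = [chrom] * len(mids) if isinstance(chrom, str) else chrom
    return pd.DataFrame({"chrom": chroms,
                         "start": [m - 250 for m in mids],
                         "end": [m + 250 for m in mids]},
                        index=[f"P{i}" for i in range(len(mids))])


class TestMetacells:
    def test_count_conservation_and_pool_sizes(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(4, size=(10, 6))
        meta, labels = aggregate_to_metacells(make_adata(X), ["A"] * 10,
                                              group_size=5, seed=1)
        assert meta.shape == (2, 6)
        assert np.allclose(meta.sum(axis=0), X.sum(axis=0))
        assert labels == ["A", "A"]

    def test_small_type_forms_single_pool(self):
        X = np.ones((3, 4))
        meta, labels = aggregate_to_metacells(make_adata(X), ["A"] * 3,
                                              group_size=10, seed=0)
        assert meta.shape[0] == 1 and np.allclose(meta[0], 3.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(4, size=(23, 5))
        labels = ["A"] * 11 + ["B"] * 12
        a, _ = aggregate_to_metacells(make_adata(X), labels, 4, seed=9)
        b, _ = aggregate_to_metacells(make_adata(X), labels, 4, seed=9)
        assert np.array_equal(a, b)


class TestGraphicalLasso:
    def test_matches_sklearn_at_constant_penalty(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(200, 8))
        A[:, 1] += 0.8 * A[:, 0]
        A[:, 3] += 0.5 * A[:, 2]
        S = np.corrcoef(A.T)
        for alpha in (0.1, 0.2):
            _, want = sklearn_glasso(S, alpha=alpha)
            Rho = np.full((8, 8), alpha)
            np.fill_diagonal(Rho, 0.0)
            got = graphical_lasso_matrix(S, Rho, max_iter=300, tol=1e-8)
            assert np.abs(got - want).max() < 1e-4


class TestCoaccessibility:
    def test_identical_peaks_score_near_one(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(8, size=30).astype(float)
        noise = rng.poisson(8, size=(30, 3)).astype(float)
        meta = np.column_stack([v, v, noise])
        pairs = compute_coaccessibility(meta, peak_frame([1000, 3000, 9000,
                                                          15000, 22000]),
                                        window=50_000)
        twin = pairs[(pairs.peak_a == "P0") & (pairs.peak_b == "P1")]
        assert len(twin) == 1 and twin.score.iloc[0] > 0.6
        assert twin.score.iloc[0] == pairs.score.max()

    def test_cross_chromosome_peaks_never_pair(self):
        rng = np.random.default_rng(1)
        meta = rng.poisson(5, size=(20, 4)).astype(float)
        peaks = peak_frame([1000, 2000, 1000, 2000],
                           chrom=["chr1", "chr1", "chr2", "chr2"])
        pairs = compute_coaccessibility(meta, peaks, window=50_000,
                                        coaccess_cutoff=-9)
        seen = set(zip(pairs.peak_a, pairs.peak_b))
        assert ("P0", "P2") not in seen and ("P1", "P3") not in seen

    def test_independent_peaks_rarely_exceed_cutoff(self):
        rng = np.random.default_rng(2)
        meta = rng.poisson(6, size=(60, 30)).astype(float)
        peaks = peak_frame(list(range(2000, 2000 + 30 * 8000, 8000)))
        pairs = compute_coaccessibility(meta, peaks, window=500_000,
                                        coaccess_cutoff=-9)
        frac_small = (pairs.score.abs() < 0.2).mean()
        assert frac_small >= 0.95

    def test_too_few_metacells_fail(self):
        with pytest.raises(ValueError):
            compute_coaccessibility(np.ones((3, 4)), peak_frame([1, 2, 3, 4]))


class TestLinkCcres:
    def _genes(self):
        return pd.DataFrame({"chrom": ["chr1"], "strand": ["+"],
                             "tss": [5000], "start": [5000], "end": [8000]},
                            index=["g1"])

    def test_collinear_type_means_link(self):
        peaks = peak_frame([5100, 60000])  # P0 promoter of g1, P1 distal
        pairs = pd.DataFrame({"peak_a": ["P0"], "peak_b": ["P1"],
                              "score": [0.5], "distance": [54900]})
        types = [f"T{i}" for i in range(6)]
        acc = pd.DataFrame(np.vstack([np.arange(6), np.arange(6) * 2.0]),
                           index=["P0", "P1"], columns=types)
        expr = pd.DataFrame([np.arange(6) * 3.0 + 1], index=["g1"],
                            columns=types)
        links = link_ccres(pairs, peaks, self._genes(), acc, expr)
        assert len(links) == 1
        assert links.pearson_r.iloc[0] == pytest.approx(1.0)
        assert links.distal_peak.iloc[0] == "P1"
        assert links.promoter_peak.iloc[0] == "P0"

    def test_no_promoter_side_no_candidate(self):
        peaks = peak_frame([60000, 90000])
        pairs = pd.DataFrame({"peak_a": ["P0"], "peak_b": ["P1"],
                              "score": [0.9], "distance": [30000]})
        types = [f"T{i}" for i in range(4)]
        acc = pd.DataFrame(np.ones((2, 4)), index=["P0", "P1"], columns=types)
        expr = pd.DataFrame(np.ones((1, 4)), index=["g1"], columns=types)
        links = link_ccres(pairs, peaks, self._genes(), acc, expr, q_cut=1.1)
        assert len(links) == 0

    def test_fewer_than_three_types_fail(self):
        peaks = peak_frame([5100, 60000])
        pairs = pd.DataFrame({"peak_a": ["P0"], "peak_b": ["P1"],
                              "score": [0.5], "distance": [1]})
        acc = pd.DataFrame(np.ones((2, 2)), index=["P0", "P1"],
                           columns=["T0", "T1"])
        expr = pd.DataFrame(np.ones((1, 2)), index=["g1"], columns=["T0", "T1"])
        with pytest.raises(ValueError):
            link_ccres(pairs, peaks, self._genes(), acc, expr)


class TestTfTargets:
    def _setup(self):
        # P0: promoter of g1 carrying the motif; P1: distal cCRE linked to g2
        # carrying the motif; P2: promoter of g2 without motif.
        peaks = peak_frame([5100, 60000, 25100])
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "strand": ["+", "+"],
             "tss": [5000, 25000], "start": [5000, 25000],
             "end": [8000, 28000]}, index=["g1", "g2"])
        motifs = make_motifs([[1], [1], [0]],
                             peak_ids=["P0", "P1", "P2"], motif_ids=["MX"])
        links = pd.DataFrame({"distal_peak": ["P1"], "gene": ["g2"],
                              "promoter_peak": ["P2"], "coaccess": [0.5],
                              "pearson_r": [0.99], "p": [1e-4], "q": [1e-3]})
        return peaks, genes, motifs, links

    def test_promoter_and_linked_ccre_evidence(self):
        peaks, genes, motifs, links = self._setup()
        det = pd.DataFrame({"tumor": [0.5, 0.4, 0.3]},
                           index=["P0", "P1", "P2"])
        out = identify_tf_targets("MX", motifs, links, peaks, genes, det,
                                  "tumor")
        by_gene = {(r.target, r.evidence) for r in out.itertuples()}
        assert ("g1", "promoter_motif") in by_gene
        assert ("g2", "linked_ccre") in by_gene

    def test_accessibility_gate(self):
        peaks, genes, motifs, links = self._setup()
        det = pd.DataFrame({"tumor": [0.01, 0.4, 0.3]},
                           index=["P0", "P1", "P2"])  # promoter in 1% of cells
        out = identify_tf_targets("MX", motifs, links, peaks, genes, det,
                                  "tumor")
        assert "g1" not in set(out.target)

    def test_matches_brute_force_rule(self):
        peaks, genes, motifs, links = self._setup()
        rng = np.random.default_rng(5)
        det = pd.DataFrame({"tumor": rng.random(3)}, index=["P0", "P1", "P2"])
        out = identify_tf_targets("MX", motifs, links, peaks, genes, det,
                                  "tumor")
        # brute force over explicit sets
        accessible = {p for p in det.index if det.loc[p, "tumor"] >= 0.05}
        hits = {"P0", "P1"}
        want = set()
        if "P0" in accessible & hits:
            want.add(("g1", "promoter_motif"))
        if "P1" in accessible & hits:
            want.add(("g2", "linked_ccre"))
        assert {(r.target, r.evidence) for r in out.itertuples()} == want

    def test_unknown_motif_fails(self):
        peaks, genes, motifs, links = self._setup()
        det = pd.DataFrame({"tumor": [1, 1, 1]}, index=["P0", "P1", "P2"])
        with pytest.raises(KeyError):
            identify_tf_targets("NOPE", motifs, links, peaks, genes, det,
                                "tumor")


class TestNetwork:
    def test_duplicate_edges_merge_evidence(self):
        pairs = pd.DataFrame({
            "tf": ["T1", "T1", "T1"], "target": ["g1", "g1", "g2"],
            "evidence": ["promoter_motif", "linked_ccre", "promoter_motif"],
            "peak": ["P0", "P5", "P1"]})
        G = build_network(pairs, deg_flags={"g2"})
        assert G.number_of_edges() == 2
        assert len(G["T1"]["g1"]["evidence"]) == 2
        assert G.nodes["g2"]["is_deg"] and not G.nodes["g1"]["is_deg"]

    def test_empty_input_gives_empty_graph(self):
        G = build_network(pd.DataFrame(columns=["tf", "target", "evidence",
                                                "peak"]))
        assert isinstance(G, nx.DiGraph) and G.number_of_nodes() == 0


class TestModuleScore:
    def test_random_sets_are_centered(self):
        rng = np.random.default_rng(0)
        X = np.log1p(rng.poisson(5, size=(80, 300)))
        gene_ids = [f"g{i}" for i in range(300)]
        means = []
        for draw in range(100):
            genes = list(rng.choice(gene_ids, 20, replace=False))
            means.append(score_gene_module(X, gene_ids, genes,
                                           seed=draw).mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(1)
        X = np.log1p(rng.poisson(5, size=(30, 100)))
        gene_ids = [f"g{i}" for i in range(100)]
        genes = gene_ids[10:30]
        a = score_gene_module(X, gene_ids, genes, seed=0)
        b = score_gene_module(X + 2.5, gene_ids, genes, seed=0)
        assert np.allclose(a, b)

    def test_empty_set_fails(self):
        with pytest.raises(ValueError):
            score_gene_module(np.ones((5, 5)), list("abcde"), [])


def test_type_mean_matrix_shape(default_multiome):
    rna, *_ = default_multiome
    means = type_mean_matrix(rna.X, rna.obs.cell_type, rna.var_names)
    assert means.shape == (rna.n_vars, 4)
    assert (means.to_numpy() >= 0).all()
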