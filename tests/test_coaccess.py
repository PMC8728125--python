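import numpy as np
import pytest
import scipy.optimize

from conftest import make_bam, make_peaks
from enhancon.coaccess import (
    AggregatedMatrix,
    aggregate_cells,
    coaccessibility_scores,
    connection_mask_and_interactions,
    embed_2d,
    lsi_embed,
    penalized_graphical_lasso,
    promoter_peak_mask,
    tfidf_transform,
)
from enhancon.intervals import GeneAnnotation, GenomicInterval, PeakSet


def tfidf_oracle(M):
    """Elementwise evaluation of the three TF-IDF equations."""
    M = np.asarray(M, dtype=float)
    n_peaks, n_cells = M.shape
    colsums = M.sum(axis=0)
    rowsums = M.sum(axis=1)
    tf = np.zeros_like(M)
    for i in range(n_peaks):
        for j in range(n_cells):
            tf[i, j] = M[i, j] / colsums[j]
    idf = np.array([np.log(1 + n_cells / rowsums[i]) for i in range(n_peaks)])
    out = np.zeros_like(M)
    for i in range(n_peaks):
        for j in range(n_cells):
            out[i, j] = idf[i] * tf[i, j]
    return out, idf


class TestTfIdf:
    def test_identity_matrix_hand_evaluation(self):
        # 2x2 identity: colSums (1,1), M_TF = I, IDF = log(3) -> diag(log 3)
        bam = make_bam(np.eye(2, dtype=int))
        res = tfidf_transform(bam)
        assert np.allclose(res.values.toarray(), np.log(3) * np.eye(2))
        assert np.allclose(res.idf, np.log(3))

    def test_matches_elementwise_oracle(self, rng):
        M = (rng.random((10, 8)) < 0.5).astype(int)
        M[0] = 1
        M[:, M.sum(axis=0) == 0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        res = tfidf_transform(make_bam(M))
        expected, idf = tfidf_oracle(M)
        assert np.allclose(res.values.toarray(), expected, atol=1e-10)
        assert np.allclose(res.idf, idf, atol=1e-10)

    def test_tf_column_sums_are_one(self, rng):
        M = (rng.random((12, 6)) < 0.4).astype(int)
        M[0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        res = tfidf_transform(make_bam(M))
        tf = res.values.toarray() / res.idf[:, None]
        assert np.allclose(tf.sum(axis=0), 1.0)

    def test_zero_row_rejected(self):
        M = np.array([[1, 1], [0, 0]])
        with pytest.raises(ValueError, match="row 1"):
            tfidf_transform(make_bam(M))

    def test_duplicating_column_leaves_others_unchanged(self, rng):
        M = (rng.random((10, 5)) < 0.5).astype(int)
        M[0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        base, _ = tfidf_oracle(M)
        M2 = np.hstack([M, M[:, [0]]])
        dup, _ = tfidf_oracle(M2)
        # TF of untouched columns is unchanged; only IDF shifts (row sums grow)
        tf_base = base / np.array([np.log(1 + 5 / M.sum(1))]).T
        tf_dup = dup[:, :5] / np.array([np.log(1 + 6 / M2.sum(1))]).T
        assert np.allclose(tf_base, tf_dup, atol=1e-10)


class TestLsiEmbed:
    def test_rank_one_matrix_collapses(self):
        M = np.outer(np.ones(6), [1, 1, 1, 1]).astype(int)
        emb = lsi_embed(tfidf_transform(make_bam(M)), n_components=3)
        # all variation is depth; components 2+ are numerically null
        assert np.allclose(emb.singular_values, 0.0, atol=1e-10)
        assert np.allclose(emb.coordinates, 0.0, atol=1e-10)

    def test_full_svd_reconstructs(self, rng):
        M = (rng.random((9, 5)) < 0.5).astype(int)
        M[0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        tfidf = tfidf_transform(make_bam(M))
        emb = lsi_embed(tfidf, n_components=5, drop_first=False)
        recon = emb.loadings @ emb.coordinates.T
        assert np.allclose(recon, tfidf.values.toarray(), atol=1e-8)

    def test_drop_first_arithmetic(self, rng):
        M = (rng.random((8, 6)) < 0.5).astype(int)
        M[0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        emb = lsi_embed(tfidf_transform(make_bam(M)), n_components=2)
        assert emb.coordinates.shape == (6, 1)

    def test_clip_warns(self, rng):
        M = np.eye(4, dtype=int)
        with pytest.warns(RuntimeWarning, match="clipped"):
            lsi_embed(tfidf_transform(make_bam(M)), n_components=50)

    def test_deterministic(self, rng):
        M = (rng.random((20, 10)) < 0.4).astype(int)
        M[0] = 1
        M[M.sum(axis=1) == 0, 0] = 1
        t = tfidf_transform(make_bam(M))
        a = lsi_embed(t, n_components=5)
        b = lsi_embed(t, n_components=5)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestEmbed2d:
    def test_deterministic_and_separates_clusters(self, rng):
        from sklearn.metrics import silhouette_score
        from enhancon.coaccess import ReducedEmbedding

        # two well-separated planted clusters in a 10-d latent space
        labels = np.repeat([0, 1], 50)
        coords = rng.normal(size=(100, 10)) + labels[:, None] * 8.0
        emb = ReducedEmbedding(
            coordinates=coords,
            singular_values=np.ones(10),
            loadings=np.zeros((5, 10)),
            cell_ids=[f"c{i}" for i in range(100)],
        )
        xy1 = embed_2d(emb, seed=3)
        xy2 = embed_2d(emb, seed=3)
        assert np.allclose(xy1, xy2)
        assert silhouette_score(xy1, labels) > 0.5

    def test_single_cell_rejected(self):
        from enhancon.coaccess import ReducedEmbedding

        emb = ReducedEmbedding(
            coordinates=np.zeros((1, 3)),
            singular_values=np.ones(3),
            loadings=np.zeros((2, 3)),
            cell_ids=["c0"],
        )
        with pytest.raises(ValueError):
            embed_2d(emb, seed=0)


class TestAggregateCells:
    def _setup(self, vals):
        bam = make_bam(vals)
        emb = lsi_embed(tfidf_transform(bam), n_components=min(vals.shape), drop_first=False)
        return bam, emb

    def test_k_equals_n_single_metacell(self, rng):
        vals = (rng.random((10, 6)) < 0.5).astype(int)
        vals[0] = 1
        vals[vals.sum(axis=1) == 0, 0] = 1
        bam, emb = self._setup(vals)
        agg = aggregate_cells(bam, emb, k=6, seed=0)
        assert agg.values.shape == (10, 1)
        assert np.array_equal(agg.values[:, 0], vals.sum(axis=1))

    def test_k_one_metacells_are_cells(self, rng):
        vals = (rng.random((10, 5)) < 0.5).astype(int)
        vals[0] = 1
        vals[vals.sum(axis=1) == 0, 0] = 1
        bam, emb = self._setup(vals)
        agg = aggregate_cells(bam, emb, k=1, seed=0)
        assert agg.values.shape == (10, 5)
        cols = {tuple(agg.values[:, m]) for m in range(5)}
        assert cols == {tuple(vals[:, j]) for j in range(5)}

    def test_identical_cells_give_k_times_common_vector(self):
        from enhancon.coaccess import ReducedEmbedding

        vals = np.tile([[1], [0], [1]], (1, 8))
        bam = make_bam(vals)
        # identical cells: all at the same point in embedding space
        emb = ReducedEmbedding(
            coordinates=np.zeros((8, 2)),
            singular_values=np.ones(2),
            loadings=np.zeros((3, 2)),
            cell_ids=bam.cell_ids,
        )
        agg = aggregate_cells(bam, emb, k=4, seed=0)
        for m in range(agg.values.shape[1]):
            assert np.array_equal(agg.values[:, m], 4 * vals[:, 0])

    def test_k_exceeding_cells_rejected(self, rng):
        vals = np.ones((4, 3), dtype=int)
        bam, emb = self._setup(vals)
        with pytest.raises(ValueError):
            aggregate_cells(bam, emb, k=4, seed=0)

    def test_every_cell_covered(self, rng):
        vals = (rng.random((30, 40)) < 0.4).astype(int)
        vals[0] = 1
        vals[vals.sum(axis=1) == 0, 0] = 1
        bam, emb = self._setup(vals)
        agg = aggregate_cells(bam, emb, k=5, seed=1)
        covered = set()
        for m in agg.membership:
            covered.update(m.tolist())
        assert covered == set(range(40))


def glasso_objective_oracle(S, rho, theta_flat):
    """Penalized negative log-likelihood on the 6 free entries of a 3x3."""
    T = np.zeros((3, 3))
    T[np.triu_indices(3)] = theta_flat
    T = T + np.triu(T, 1).T
    sign, logdet = np.linalg.slogdet(T)
    if sign <= 0:
        return 1e10
    return -logdet + np.trace(S @ T) + np.sum(rho * np.abs(T))


class TestPenalizedGraphicalLasso:
    def test_matches_direct_objective_minimization(self, rng):
        # random well-conditioned 3x3 covariance, random penalties
        A = rng.normal(size=(3, 3))
        S = A @ A.T + 3 * np.eye(3)
        rho = rng.uniform(0.05, 0.3, size=(3, 3))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 0.0)
        _, Theta, converged = penalized_graphical_lasso(S, rho, tol=1e-8)
        assert converged
        x0 = Theta[np.triu_indices(3)]
        res = scipy.optimize.minimize(
            lambda x: glasso_objective_oracle(S, rho, x),
            x0=np.linalg.inv(S)[np.triu_indices(3)],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        ours = glasso_objective_oracle(S, rho, x0)
        # our solution attains the independently-minimized objective
        assert ours <= res.fun + 1e-6
        T_oracle = np.zeros((3, 3))
        T_oracle[np.triu_indices(3)] = res.x
        T_oracle = T_oracle + np.triu(T_oracle, 1).T
        assert np.allclose(Theta, T_oracle, atol=1e-3)

    def test_zero_penalty_inverts_covariance(self, rng):
        A = rng.normal(size=(4, 4))
        S = A @ A.T + 2 * np.eye(4)
        _, Theta, _ = penalized_graphical_lasso(S, np.zeros((4, 4)), tol=1e-10)
        assert np.allclose(Theta, np.linalg.inv(S), atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            penalized_graphical_lasso(np.eye(3), np.zeros((2, 2)))


def _agg(values, peak_set, k=10):
    values = np.asarray(values)
    return AggregatedMatrix(
        values=values,
        membership=[np.arange(1)] * values.shape[1],
        peak_ids=list(peak_set.ids),
        k=k,
    )


class TestCoaccessibilityScores:
    def test_correlated_pair_scores_high_independent_low(self, rng):
        # peaks A and B share identical counts; C is independent noise
        ps = PeakSet(
            [
                GenomicInterval("chr1", 1000, 1400),
                GenomicInterval("chr1", 20_000, 20_400),
                GenomicInterval("chr1", 90_000, 90_400),
            ]
        )
        common = rng.integers(0, 10, size=40)
        other = rng.integers(0, 10, size=40)
        vals = np.vstack([common, common, other])
        pairs = {(p.peak_i, p.peak_j): p.score
                 for p in coaccessibility_scores(_agg(vals, ps), ps, min_open_frac=0.0,
                                                 penalty_base=0.1)}
        a, b, c = ps.ids
        assert pairs[(a, b)] > 0.5
        assert abs(pairs[(a, c)]) < 0.1
        assert abs(pairs[(b, c)]) < 0.1

    def test_pairs_beyond_window_not_emitted(self, rng):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 0, 400),
                GenomicInterval("chr1", 700_000, 700_400),
            ]
        )
        vals = rng.integers(0, 10, size=(2, 30))
        pairs = coaccessibility_scores(
            _agg(vals, ps), ps, window_bp=500_000, min_open_frac=0.0
        )
        assert pairs == []

    def test_zero_variance_peak_produces_no_pairs(self, rng):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 0, 400),
                GenomicInterval("chr1", 10_000, 10_400),
                GenomicInterval("chr1", 20_000, 20_400),
            ]
        )
        vals = np.vstack(
            [rng.integers(0, 10, 30), np.full(30, 5), rng.integers(0, 10, 30)]
        )
        pairs = coaccessibility_scores(_agg(vals, ps), ps, min_open_frac=0.0)
        flat = {ps.ids[1]} & {x for p in pairs for x in (p.peak_i, p.peak_j)}
        assert flat == set()

    def test_symmetry_and_distance_invariants(self, rng):
        ps = make_peaks(12, spacing=40_000)
        vals = rng.integers(0, 8, size=(12, 25))
        pairs = coaccessibility_scores(
            _agg(vals, ps), ps, window_bp=300_000, min_open_frac=0.0
        )
        seen = set()
        for p in pairs:
            assert p.peak_i != p.peak_j
            assert p.distance <= 300_000
            key = frozenset((p.peak_i, p.peak_j))
            assert key not in seen  # each unordered pair scored once
            seen.add(key)
        assert len(pairs) > 0

    def test_duplicating_metacells_leaves_scores_unchanged(self, rng):
        ps = make_peaks(6, spacing=30_000)
        vals = rng.integers(0, 8, size=(6, 20))
        base = coaccessibility_scores(_agg(vals, ps), ps, min_open_frac=0.0)
        doubled = coaccessibility_scores(
            _agg(np.hstack([vals, vals]), ps), ps, min_open_frac=0.0
        )
        b = {(p.peak_i, p.peak_j): p.score for p in base}
        d = {(p.peak_i, p.peak_j): p.score for p in doubled}
        assert b.keys() == d.keys()
        for k in b:
            assert b[k] == pytest.approx(d[k], abs=1e-8)

    def test_requires_two_metacells(self):
        ps = make_peaks(3)
        with pytest.raises(ValueError, match="metacell"):
            coaccessibility_scores(_agg(np.ones((3, 1)), ps), ps)


class TestPromoterPeakMask:
    def _genes(self):
        return [
            GeneAnnotation("g1", "chr1", "+", tss=10_000),
            GeneAnnotation("g2", "chr1", "+", tss=10_500),
        ]

    def test_promoter_overlap_detected(self):
        # + strand window [tss-1000, tss+100)
        ps = PeakSet([GenomicInterval("chr1", 9_400, 9_600)])
        mask, genes = promoter_peak_mask(ps, [self._genes()[0]])
        assert mask[0]
        assert genes[0] == {"g1"}

    def test_intergenic_peak_false(self):
        ps = PeakSet([GenomicInterval("chr1", 500_000, 500_400)])
        mask, genes = promoter_peak_mask(ps, self._genes())
        assert not mask[0]
        assert genes == {}

    def test_multi_gene_overlap_maps_to_all(self):
        ps = PeakSet([GenomicInterval("chr1", 9_900, 10_100)])
        mask, genes = promoter_peak_mask(ps, self._genes())
        assert genes[0] == {"g1", "g2"}


class TestConnectionMask:
    def _fixture(self):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 0, 400),        # distal
                GenomicInterval("chr1", 9_500, 9_900),  # promoter of g1
                GenomicInterval("chr1", 50_000, 50_400),  # promoter of g2
            ]
        )
        prom = np.array([False, True, True])
        pg = {1: {"g1"}, 2: {"g2"}}
        return ps, prom, pg

    def test_strong_connection_passes(self):
        from enhancon.coaccess import CoaccessibilityPair

        ps, prom, pg = self._fixture()
        pairs = [CoaccessibilityPair(ps.ids[0], ps.ids[1], 0.3, 9500)]
        mask, inter, best = connection_mask_and_interactions(pairs, prom, pg, ps)
        assert mask.tolist() == [True, False, False]
        assert len(inter) == 1
        assert (inter[0].gene_id, inter[0].score) == ("g1", 0.3)
        assert best[0] == 0.3

    def test_weak_connection_fails(self):
        from enhancon.coaccess import CoaccessibilityPair

        ps, prom, pg = self._fixture()
        pairs = [CoaccessibilityPair(ps.ids[0], ps.ids[1], 0.05, 9500)]
        mask, inter, _ = connection_mask_and_interactions(pairs, prom, pg, ps)
        assert not mask.any()
        assert inter == []

    def test_two_genes_two_records(self):
        from enhancon.coaccess import CoaccessibilityPair

        ps, prom, pg = self._fixture()
        pairs = [
            CoaccessibilityPair(ps.ids[0], ps.ids[1], 0.2, 9500),
            CoaccessibilityPair(ps.ids[0], ps.ids[2], 0.4, 50000),
        ]
        mask, inter, best = connection_mask_and_interactions(pairs, prom, pg, ps)
        assert len(inter) == 2
        assert {(r.gene_id, r.score) for r in inter} == {("g1", 0.2), ("g2", 0.4)}
        assert best[0] == 0.4
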