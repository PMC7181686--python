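import numpy as np
import pandas as pd
import pytest
import scipy.stats

import celldecon as cd
from celldecon.expr_io import CountsMatrix, MarkerSet
from celldecon.marker_wpca import (
    MarkerConfig,
    correct_global_pc,
    marker_decompose,
    select_marker_count,
    weighted_pc1,
)

from .oracles import svd_pc1_scores


def _mat(vals, unit="arbitrary"):
    vals = np.asarray(vals, float)
    return CountsMatrix(
        vals,
        [f"g{i}" for i in range(vals.shape[0])],
        [f"s{i}" for i in range(vals.shape[1])],
        unit,
    )


class TestCorrectGlobalPc:
    def test_rank_one_matrix_residuals_vanish(self, rng):
        factor = rng.uniform(1, 3, 8)
        load = rng.uniform(0.5, 2, 20)
        X = _mat(np.outer(load, factor))
        out = correct_global_pc(X)
        assert np.abs(out.values).max() < 1e-8

    def test_residuals_orthogonal_to_pc1(self, rng):
        X = _mat(rng.uniform(0, 10, (30, 10)))
        S = (X.values.T - X.values.T.mean(axis=0)) / X.values.T.std(axis=0, ddof=1)
        pc1 = svd_pc1_scores(S)
        out = correct_global_pc(X)
        corr = out.values @ (pc1 - pc1.mean())
        np.testing.assert_allclose(corr, 0.0, atol=1e-8)

    def test_matches_explicit_svd_projection(self, rng):
        M = rng.uniform(0, 10, (50, 10))
        X = _mat(M)
        out = correct_global_pc(X)
        # independent construction: standardize genes, PC1 scores by SVD,
        # per-gene OLS residual of the original values on those scores
        Mt = M.T
        S = (Mt - Mt.mean(axis=0)) / Mt.std(axis=0, ddof=1)
        pc1 = svd_pc1_scores(S)
        cen = Mt - Mt.mean(axis=0)
        beta = (pc1 @ cen) / (pc1 @ pc1)
        expected = (cen - np.outer(pc1, beta)).T
        np.testing.assert_allclose(out.values, expected, atol=1e-8)

    def test_requires_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correct_global_pc(_mat(np.ones((4, 2))))


class TestWeightedPc1:
    def test_rank_one_markers_recover_common_factor(self, rng):
        v = rng.uniform(0, 5, 12)
        noiseless = np.tile(v, (6, 1))
        # add per-gene scaling so columns differ but share the factor
        scale = rng.uniform(0.5, 2, 6)
        X = _mat(noiseless * scale[:, None])
        score = weighted_pc1(X, X.gene_ids, np.ones(6))
        r = np.corrcoef(score, v)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_fixed_under_factor_flip(self, rng):
        v = rng.normal(0, 1, 15)
        load = rng.uniform(0.5, 2, 8)
        X1 = _mat(np.outer(load, v) + rng.normal(0, 0.01, (8, 15)))
        X2 = _mat(np.outer(load, -v) + rng.normal(0, 0.01, (8, 15)))
        s1 = weighted_pc1(X1, X1.gene_ids, np.ones(8))
        s2 = weighted_pc1(X2, X2.gene_ids, np.ones(8))
        # markers load positively on the score in both cases
        assert np.corrcoef(s1, X1.values.mean(axis=0))[0, 1] > 0
        assert np.corrcoef(s2, X2.values.mean(axis=0))[0, 1] > 0

    def test_matches_independent_svd(self, rng):
        X = _mat(rng.normal(0, 1, (30, 20)))
        w = rng.uniform(0.5, 2, 30)
        score = weighted_pc1(X, X.gene_ids, w)
        M = X.values.T
        S = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
        ref = svd_pc1_scores(S * w)
        ref = (ref - ref.mean()) / ref.std(ddof=1)
        agree = min(np.abs(score - ref).max(), np.abs(score + ref).max())
        assert agree < 1e-8

    def test_scores_invariant_to_weight_rescaling_and_sample_order(self, rng):
        X = _mat(rng.normal(0, 1, (10, 12)))
        w = rng.uniform(0.5, 2, 10)
        s1 = weighted_pc1(X, X.gene_ids, w)
        s2 = weighted_pc1(X, X.gene_ids, 7.3 * w)
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        perm = rng.permutation(12)
        Xp = CountsMatrix(X.values[:, perm], X.gene_ids,
                          [X.sample_ids[i] for i in perm], "arbitrary")
        sp = weighted_pc1(Xp, X.gene_ids, w)
        np.testing.assert_allclose(sp, s1[perm], atol=1e-10)

    def test_zero_variance_markers_dropped(self, rng):
        vals = rng.normal(0, 1, (4, 10))
        vals[2] = 3.0
        X = _mat(vals)
        score = weighted_pc1(X, X.gene_ids, np.ones(4))
        assert score.shape == (10,)
        with pytest.raises(ValueError, match="zero variance"):
            weighted_pc1(_mat(np.ones((3, 5))), ["g0", "g1", "g2"], np.ones(3))


class TestSelectMarkerCount:
    def _ranked(self, genes, lfc=None):
        n = len(genes)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "cell_type": ["A"] * n,
                "log_fold_change": lfc if lfc is not None else np.ones(n),
                "p_value": np.linspace(1e-8, 1e-4, n),
                "fdr": np.linspace(1e-8, 1e-4, n),
            }
        )

    def test_planted_factor_width_detected(self, rng):
        n_samples, n_shared = 40, 50
        factor = rng.normal(0, 1, n_samples)
        shared = np.outer(rng.uniform(0.8, 1.2, n_shared), factor)
        noise = rng.normal(0, 1, (150, n_samples))
        X = _mat(np.vstack([shared + rng.normal(0, 0.2, shared.shape), noise]))
        ranked = self._ranked(X.gene_ids)
        n = select_marker_count(X, ranked, count_range=(25, 200), step=25)
        # the ratio at the planted width must beat the full-range candidate
        assert n <= 75

    def test_clipping_to_available_markers(self, rng):
        X = _mat(rng.normal(0, 1, (30, 10)))
        ranked = self._ranked(X.gene_ids)
        n = select_marker_count(X, ranked, count_range=(25, 200), step=5)
        assert n in (25, 30)

    def test_fewer_than_minimum_uses_all(self, rng):
        X = _mat(rng.normal(0, 1, (10, 8)))
        ranked = self._ranked(X.gene_ids)
        assert select_marker_count(X, ranked, count_range=(25, 200), step=5) == 10


@pytest.fixture(scope="module")
def mixtures():
    cfg = cd.ScSimConfig(n_individuals=40, cells_per_individual=200, seed=21)
    sc, ann, truth, markers = cd.simulate_sc(cfg)
    bulk = cd.base_bulk(sc, ann)
    return bulk, truth, markers


class TestMarkerDecompose:
    def test_scores_track_true_proportions(self, mixtures):
        bulk, truth, markers = mixtures
        scores = marker_decompose(bulk, markers, MarkerConfig(global_correction=False))
        sp = []
        for i, ct in enumerate(scores.cell_types):
            j = truth.cell_types.index(ct)
            sp.append(
                abs(scipy.stats.spearmanr(scores.values[i], truth.values[j]).statistic)
            )
        assert np.mean(sp) >= 0.8

    def test_direction_agreement_high_on_separated_data(self, mixtures):
        bulk, truth, markers = mixtures
        scores = marker_decompose(bulk, markers, MarkerConfig(global_correction=False))
        assert all(a > 0.9 for a in scores.direction_agreement.values())

    def test_disjoint_marker_scores_nearly_independent(self, rng):
        # two marker blocks driven by independent factors
        n = 50
        f1, f2 = rng.normal(0, 1, n), rng.normal(0, 1, n)
        block1 = np.outer(rng.uniform(0.8, 1.2, 30), f1)
        block2 = np.outer(rng.uniform(0.8, 1.2, 30), f2)
        noise = rng.normal(0, 0.3, (60, n))
        X = _mat(np.vstack([block1, block2]) + noise)
        rows = []
        for i in range(30):
            rows.append((f"g{i}", "A", 1.0, 1e-6, 1e-6))
        for i in range(30, 60):
            rows.append((f"g{i}", "B", 1.0, 1e-6, 1e-6))
        markers = MarkerSet(
            pd.DataFrame(rows, columns=["gene_id", "cell_type", "log_fold_change",
                                        "p_value", "fdr"])
        )
        scores = marker_decompose(
            X, markers, MarkerConfig(global_correction=False, log_transform=False)
        )
        r = np.corrcoef(scores.values[0], scores.values[1])[0, 1]
        assert abs(r) < 0.3

    def test_insignificant_cell_type_omitted(self, rng):
        X = _mat(rng.normal(0, 1, (10, 8)))
        rows = [(f"g{i}", "A", 1.0, 1e-6, 1e-6) for i in range(5)]
        rows += [(f"g{i}", "B", 1.0, 0.5, 0.9) for i in range(5, 10)]
        markers = MarkerSet(
            pd.DataFrame(rows, columns=["gene_id", "cell_type", "log_fold_change",
                                        "p_value", "fdr"])
        )
        scores = marker_decompose(
            X, markers, MarkerConfig(global_correction=False, log_transform=False)
        )
        assert scores.cell_types == ["A"]

    def test_scores_standardized(self, mixtures):
        bulk, _, markers = mixtures
        scores = marker_decompose(bulk, markers, MarkerConfig(global_correction=False))
        np.testing.assert_allclose(scores.values.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(scores.values.std(axis=1, ddof=1), 1.0, atol=1e-10)
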