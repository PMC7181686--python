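import numpy as np
import pytest
import scipy.stats

import celldecon as cd
from celldecon.expr_io import CountsMatrix
from celldecon.simulate import (
    BiasModel,
    ScSimConfig,
    apply_bias,
    base_bulk,
    mix_unknown,
    perturb_reference_proportions,
    sample_bias,
    simulate_sc,
)


class TestSimulateSc:
    def test_fixed_seed_reproducible(self):
        cfg = ScSimConfig(n_individuals=2, n_cell_types=2, cells_per_individual=30,
                          n_genes=50, n_markers_per_type=5, seed=3)
        a = simulate_sc(cfg)
        b = simulate_sc(cfg)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[1].table.equals(b[1].table)
        np.testing.assert_array_equal(a[2].values, b[2].values)
        assert a[3].table.equals(b[3].table)

    def test_truth_matches_realized_label_fractions(self, tiny_sim):
        cfg, sc, ann, truth, markers = tiny_sim
        for j, ind in enumerate(truth.individual_ids):
            sub = ann.table[ann.table["individual_id"] == ind]
            for i, ct in enumerate(truth.cell_types):
                frac = (sub["cell_type"] == ct).mean()
                assert truth.values[i, j] == pytest.approx(frac, abs=1e-15)

    def test_unit_fold_makes_markers_exchangeable(self):
        # with marker_fold=1 marker and background genes share the same
        # marginal distribution: compare group means over repeated draws
        diffs = []
        for seed in range(20):
            cfg = ScSimConfig(n_individuals=2, n_cell_types=2, cells_per_individual=50,
                              n_genes=60, n_markers_per_type=10, marker_fold=1.0, seed=seed)
            sc, ann, truth, markers = simulate_sc(cfg)
            is_marker = np.isin(sc.gene_ids, markers.gene_ids)
            diffs.append(sc.values[is_marker].mean() - sc.values[~is_marker].mean())
        t, p = scipy.stats.ttest_1samp(diffs, 0.0)
        assert p > 0.01

    def test_infeasible_marker_count_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            ScSimConfig(n_genes=10, n_cell_types=3, n_markers_per_type=5)

    def test_marker_pvalues_rank_consistent_with_fold(self, tiny_sim):
        _, _, _, _, markers = tiny_sim
        for ct in markers.cell_types:
            sub = markers.for_cell_type(ct)
            order = np.argsort(-sub["log_fold_change"].to_numpy())
            p_sorted = sub["p_value"].to_numpy()[order]
            assert np.all(np.diff(p_sorted) >= 0)


class TestBaseBulk:
    def test_sums_cells_per_individual(self, tiny_sim):
        cfg, sc, ann, truth, markers = tiny_sim
        bulk = base_bulk(sc, ann)
        ind = ann.individuals[0]
        ids = ann.table.loc[ann.table["individual_id"] == ind, "cell_id"]
        cols = [sc.sample_ids.index(c) for c in ids]
        np.testing.assert_array_equal(bulk.values[:, 0], sc.values[:, cols].sum(axis=1))

    def test_two_cell_example(self):
        sc = CountsMatrix(np.array([[1.0, 3.0], [2.0, 4.0]]), ["g1", "g2"], ["c1", "c2"])
        import pandas as pd

        from celldecon.expr_io import CellAnnotation
        ann = CellAnnotation(pd.DataFrame(
            {"cell_id": ["c1", "c2"], "individual_id": ["i1", "i1"], "cell_type": ["A", "B"]}
        ))
        np.testing.assert_array_equal(base_bulk(sc, ann).values[:, 0], [4.0, 6.0])


class TestSampleBias:
    def test_sigma_zero_identity(self):
        bias = sample_bias(0.0, 100, seed=4)
        assert np.all(bias.beta == 1.0) and np.all(bias.alpha == 0.0)

    def test_half_normal_mean_closed_form(self):
        sigma, n = 5.0, 100_000
        bias = sample_bias(sigma, n, seed=4)
        expected = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(bias.alpha.mean() - expected) < 3 * se
        assert abs((bias.beta - 1).mean() - expected) < 3 * se

    def test_support_constraints(self):
        for sigma in (0.0, 1.0, 20.0):
            bias = sample_bias(sigma, 1000, seed=1)
            assert bias.beta.min() >= 1.0 and bias.alpha.min() >= 0.0

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            sample_bias(-1.0, 10, seed=0)

    def test_sigma_zero_model_invariant_enforced(self):
        with pytest.raises(ValueError):
            BiasModel(0.0, np.array([2.0]), np.array([0.0]), seed=0)


class TestApplyBias:
    def test_identity_and_arithmetic(self):
        bulk = CountsMatrix(np.array([[10.0]]), ["g"], ["s"])
        ident = BiasModel(0.0, np.ones(1), np.zeros(1), 0)
        np.testing.assert_array_equal(apply_bias(bulk, ident).values, [[10.0]])
        bias = BiasModel(1.0, np.array([2.0]), np.array([1.0]), 0)
        assert apply_bias(bulk, bias).values[0, 0] == 21.0

    def test_invertible(self, rng):
        bulk = CountsMatrix(rng.uniform(0, 100, (20, 3)),
                            [f"g{i}" for i in range(20)], list("abc"))
        bias = sample_bias(5.0, 20, seed=2)
        out = apply_bias(bulk, bias)
        rec = (out.values - bias.alpha[:, None]) / bias.beta[:, None]
        np.testing.assert_allclose(rec, bulk.values, atol=1e-12)


class TestPerturbProportions:
    def test_factor_one_is_identity_on_counts(self, tiny_sim):
        cfg, sc, ann, truth, markers = tiny_sim
        _, ann2 = perturb_reference_proportions(sc, ann, "type1", 1.0, seed=0)
        before = ann.table.groupby(["individual_id", "cell_type"]).size()
        after = ann2.table.groupby(["individual_id", "cell_type"]).size()
        assert before.sort_index().equals(after.sort_index())

    def test_downsampling_halves_counts(self, tiny_sim):
        cfg, sc, ann, truth, markers = tiny_sim
        _, ann2 = perturb_reference_proportions(sc, ann, "type1", 0.5, seed=0)
        for ind in ann.individuals:
            n0 = ((ann.table["individual_id"] == ind) & (ann.table["cell_type"] == "type1")).sum()
            n1 = ((ann2.table["individual_id"] == ind) & (ann2.table["cell_type"] == "type1")).sum()
            assert n1 == int(np.rint(0.5 * n0))

    def test_upsampling_creates_unique_ids_and_matching_columns(self, tiny_sim):
        cfg, sc, ann, truth, markers = tiny_sim
        sc2, ann2 = perturb_reference_proportions(sc, ann, "type2", 2.0, seed=0)
        assert ann2.table["cell_id"].is_unique
        assert sc2.sample_ids == ann2.cell_ids
        # duplicated cells carry copies of a source column
        dup = [c for c in ann2.cell_ids if "_dup" in c][0]
        src = dup.split("_dup")[0]
        np.testing.assert_array_equal(
            sc2.values[:, sc2.sample_ids.index(dup)],
            sc.values[:, sc.sample_ids.index(src)],
        )


class TestMixUnknown:
    def test_zero_fraction_is_cpm_identity(self, rng):
        bulk = CountsMatrix(rng.uniform(1, 10, (6, 3)),
                            [f"g{i}" for i in range(6)], list("abc"))
        cont = CountsMatrix(rng.uniform(1, 10, (6, 2)), bulk.gene_ids, ["u", "v"])
        out = mix_unknown(bulk, cont, np.zeros(3))
        np.testing.assert_allclose(out.values, cd.cpm_normalize(bulk).values, rtol=1e-12)

    def test_self_mixing_identity(self, rng):
        bulk = CountsMatrix(rng.uniform(1, 10, (6, 3)),
                            [f"g{i}" for i in range(6)], list("abc"))
        out = mix_unknown(bulk, bulk, np.full(3, 0.5))
        np.testing.assert_allclose(out.values, cd.cpm_normalize(bulk).values, rtol=1e-12)

    def test_mixed_columns_stay_on_cpm_scale(self, rng):
        bulk = CountsMatrix(rng.uniform(1, 10, (6, 4)),
                            [f"g{i}" for i in range(6)], list("abcd"))
        cont = CountsMatrix(rng.uniform(1, 10, (6, 2)), bulk.gene_ids, ["u", "v"])
        out = mix_unknown(bulk, cont, rng.uniform(0, 0.9, 4))
        np.testing.assert_allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_fraction_one_rejected(self, rng):
        bulk = CountsMatrix(rng.uniform(1, 10, (3, 1)), list("abc"), ["s"])
        with pytest.raises(ValueError):
            mix_unknown(bulk, bulk, np.array([1.0]))


class TestRunBiasSweep:
    def test_table_layout_and_determinism(self):
        cfg = ScSimConfig(n_individuals=4, n_cell_types=3, cells_per_individual=60,
                          n_genes=150, n_markers_per_type=10, seed=5)
        tab1, summ1 = cd.run_bias_sweep(cfg, sigmas=(0.0, 5.0), replicates=2, seed=9)
        tab2, _ = cd.run_bias_sweep(cfg, sigmas=(0.0, 5.0), replicates=2, seed=9)
        assert tab1.equals(tab2)
        assert set(tab1["method_mode"]) == {"transformed", "untransformed"}
        assert len(tab1) == 2 * 2 * 2
        assert {"mean", "ci_low", "ci_high"} <= set(summ1.columns)
        assert (summ1["ci_low"] <= summ1["ci_high"]).all()
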