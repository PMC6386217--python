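import numpy as np
import pytest

from hpfactor.core import HyperParams, SparseCountMatrix
from hpfactor.evaluation import (
    cv_vector,
    gaussian_baseline,
    inverse_transform,
    ks_statistic,
    normalize_counts,
    normalize_values,
    posterior_predictive_sample,
    ppc_cv_ks,
    prediction_error,
    predict_heldout,
    select_k_benchmark,
    split_nonzeros,
)
from hpfactor.inference import FitConfig, fit
from hpfactor.synthetic import default_sim_hyper, sample_generative

from _reference import brute_force_ks
from conftest import random_count_matrix, random_state
from test_core import make_model


class TestSplitNonzeros:
    def test_default_fractions_give_printed_sizes(self):
        # T = 10,000 -> 400 test, 200 validation, 9,400 train
        rng = np.random.default_rng(0)
        N = 100
        dense = rng.integers(1, 5, size=(N, 100))
        X = SparseCountMatrix.from_dense(dense)
        assert X.nnz == 10_000
        split = split_nonzeros(X, seed=1)
        assert len(split.test[2]) == 400
        assert len(split.validation[2]) == 200
        assert split.train.nnz == 9_400

    def test_zero_fractions_keep_everything(self, rng):
        X = random_count_matrix(rng, 10, 10)
        split = split_nonzeros(X, test_frac=0.0, val_frac=0.0, seed=0)
        assert split.train.nnz == X.nnz
        assert len(split.test[2]) == 0

    def test_deterministic_given_seed(self, rng):
        X = random_count_matrix(rng, 20, 20)
        s1 = split_nonzeros(X, seed=7)
        s2 = split_nonzeros(X, seed=7)
        assert np.array_equal(s1.test[0], s2.test[0])
        assert np.array_equal(s1.train.counts, s2.train.counts)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_disjoint_and_complete(self, seed):
        rng = np.random.default_rng(seed)
        X = random_count_matrix(rng, 15, 15, density=0.5)
        split = split_nonzeros(X, seed=seed)
        parts = [
            set(zip(split.train.rows, split.train.cols)),
            set(zip(*split.validation[:2])),
            set(zip(*split.test[:2])),
        ]
        assert sum(len(p) for p in parts) == X.nnz
        assert parts[0] | parts[1] | parts[2] == set(zip(X.rows, X.cols))

    def test_invalid_fractions_rejected(self, rng):
        X = random_count_matrix(rng, 5, 5)
        with pytest.raises(ValueError):
            split_nonzeros(X, test_frac=0.6, val_frac=0.5)
        with pytest.raises(ValueError):
            split_nonzeros(X, test_frac=-0.1)


class TestNormalization:
    def test_log_of_three_is_two(self):
        X = SparseCountMatrix(2, 2, rows=[0], cols=[0], counts=[3])
        Y, _ = normalize_counts(X, "log")
        assert Y[0, 0] == pytest.approx(2.0)
        assert Y[1, 1] == 0.0

    def test_rate_is_counts_per_median(self):
        # cell totals (4, 8, 8, 12): median 8; cell 0 counts (1,1,2) -> (2,2,4)
        dense = np.array(
            [[1, 1, 2], [4, 2, 2], [2, 2, 4], [4, 4, 4]], dtype=np.int64
        )
        X = SparseCountMatrix.from_dense(dense)
        Y, meta = normalize_counts(X, "rate")
        assert meta.median_total == 8.0
        np.testing.assert_allclose(Y[0], [2.0, 2.0, 4.0])

    @pytest.mark.parametrize("method", ["log", "rate", "log_rate"])
    def test_round_trip_exact_on_integer_counts(self, rng, method):
        X = random_count_matrix(rng, 8, 9, density=0.7)
        Y, meta = normalize_counts(X, method)
        back = inverse_transform(Y, method, meta)
        np.testing.assert_allclose(back, X.to_dense(), atol=1e-9)

    def test_negative_log_values_pass_through(self):
        X = SparseCountMatrix(2, 2, rows=[0, 1], cols=[0, 1], counts=[1, 1])
        _, meta = normalize_counts(X, "log")
        out = inverse_transform(np.full((2, 2), -0.5), "log", meta)
        assert np.all((out > -1) & (out < 0))

    def test_entrywise_matches_dense_normalization(self, rng):
        X = random_count_matrix(rng, 6, 7, density=0.6)
        for method in ("log", "rate", "log_rate"):
            dense, meta = normalize_counts(X, method)
            got = normalize_values(X.counts.astype(float), X.rows, method, meta)
            np.testing.assert_allclose(got, dense[X.rows, X.cols], rtol=1e-12)

    def test_rate_requires_positive_totals(self):
        X = SparseCountMatrix(2, 2, rows=[0], cols=[0], counts=[1])
        with pytest.raises(ValueError):
            normalize_counts(X, "rate")

    def test_unknown_method_rejected(self, rng):
        X = random_count_matrix(rng, 3, 3)
        with pytest.raises(ValueError):
            normalize_counts(X, "sqrt")


class TestPredictionError:
    def test_identical_vectors_zero(self):
        assert prediction_error([1, 2], [1, 2], "mse") == 0
        assert prediction_error([1, 2], [1, 2], "mae") == 0

    def test_printed_values(self):
        assert prediction_error([0, 0], [3, 4], "mse") == pytest.approx(12.5)
        assert prediction_error([0, 0], [3, 4], "mae") == pytest.approx(3.5)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random(50), rng.random(50)
        mse = sum((x - y) ** 2 for x, y in zip(a, b)) / 50
        mae = sum(abs(x - y) for x, y in zip(a, b)) / 50
        assert prediction_error(a, b, "mse") == pytest.approx(mse, rel=1e-12)
        assert prediction_error(a, b, "mae") == pytest.approx(mae, rel=1e-12)

    def test_nonnegative_with_equality_iff_identical(self, rng):
        a = rng.random(20)
        b = a.copy()
        b[3] += 1e-6
        assert prediction_error(a, a) == 0
        assert prediction_error(a, b) > 0
        with pytest.raises(ValueError):
            prediction_error([], [])


class TestPosteriorPredictive:
    def test_huge_rates_give_all_zero_replicate(self, rng, small_hyper):
        st = random_state(rng, 5, 6, 3)
        st.gamma_rate[:] = 1e12
        st.lambda_rate[:] = 1e12
        rep = posterior_predictive_sample(make_model(st, small_hyper), seed=0)
        assert rep.shape == (5, 6)
        assert rep.sum() == 0

    def test_same_seed_identical(self, rng, small_hyper):
        model = make_model(random_state(rng, 4, 4, 2), small_hyper)
        assert np.array_equal(
            posterior_predictive_sample(model, seed=3),
            posterior_predictive_sample(model, seed=3),
        )

    def test_replicate_mean_matches_expected_rate(self, rng, small_hyper):
        # Monte-Carlo oracle: E[x] = E[theta] . E[beta] by iterated expectation
        st = random_state(rng, 1, 1, 2)
        model = make_model(st, small_hyper)
        gen = np.random.default_rng(0)
        draws = np.array(
            [posterior_predictive_sample(model, gen)[0, 0] for _ in range(20_000)]
        )
        expect = float(st.e_theta()[0] @ st.e_beta()[0])
        # Var(x) = E[rate] + Var(rate); bound the standard error generously
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - expect) < 4 * se + 1e-9


class TestCV:
    def test_constant_row_zero(self):
        assert cv_vector(np.full((1, 4), 3.0), "per_cell")[0] == 0.0

    def test_printed_arithmetic(self):
        cv = cv_vector(np.array([[2.0, 4.0, 6.0, 8.0]]), "per_cell")[0]
        assert cv == pytest.approx(np.sqrt(5) / 5)

    def test_zero_mean_marked_nan(self):
        out = cv_vector(np.zeros((2, 3)), "per_gene")
        assert np.all(np.isnan(out))


class TestKS:
    def test_identical_zero(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0

    def test_disjoint_supports_one(self):
        assert ks_statistic([0, 0, 0], [1, 1, 1]) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_ecdf_scan(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=40)
        b = rng.normal(0.3, 1.2, size=25)
        assert ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_symmetric_and_permutation_invariant(self, rng):
        a, b = rng.random(30), rng.random(20)
        assert ks_statistic(a, b) == pytest.approx(ks_statistic(b, a))
        assert ks_statistic(rng.permutation(a), b) == pytest.approx(ks_statistic(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


class TestPPC:
    def test_observed_sampler_gives_zero_ks(self, rng, small_hyper):
        X = random_count_matrix(rng, 10, 12, density=0.6)
        model = make_model(random_state(rng, 10, 12, 3), small_hyper)
        ks_cell, ks_gene, _ = ppc_cv_ks(
            model, X, n_reps=3, seed=0, sampler=lambda r: X.to_dense()
        )
        assert ks_cell == 0
        assert ks_gene == 0

    def test_shifted_sampler_gives_ks_one(self, rng, small_hyper):
        X = random_count_matrix(rng, 8, 10, density=0.6)
        model = make_model(random_state(rng, 8, 10, 3), small_hyper)
        # simulated CVs strictly above all observed CVs -> disjoint supports
        big = X.to_dense().astype(float)
        spiky = np.zeros_like(big)
        spiky[:, 0] = 1000.0
        spiky[0, :] = np.maximum(spiky[0, :], 1.0)
        ks_cell, _, _ = ppc_cv_ks(model, X, n_reps=2, seed=0, sampler=lambda r: spiky)
        assert ks_cell == 1.0

    def test_rejects_bad_reps(self, rng, small_hyper):
        X = random_count_matrix(rng, 4, 4)
        model = make_model(random_state(rng, 4, 4, 3), small_hyper)
        with pytest.raises(ValueError):
            ppc_cv_ks(model, X, n_reps=0)


class TestGaussianBaseline:
    def test_full_rank_exact_reconstruction(self, rng):
        Xn = rng.random((6, 5))
        base = gaussian_baseline(Xn, K=5)
        np.testing.assert_allclose(base.reconstruction, Xn, atol=1e-10)
        np.testing.assert_allclose(base.residual_sd, 0, atol=1e-10)

    def test_error_nonincreasing_in_k(self, rng):
        Xn = rng.random((10, 8))
        errs = [
            np.mean((gaussian_baseline(Xn, K=k).reconstruction - Xn) ** 2)
            for k in range(1, 8)
        ]
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            gaussian_baseline(rng.random((4, 4)), K=5)


class TestPredictHeldout:
    def test_rates_and_normalized_error_paths_agree(self):
        truth = sample_generative(40, 50, default_sim_hyper(2), seed=11)
        X = truth.counts
        split = split_nonzeros(X, seed=11)
        model = fit(
            split.train, HyperParams(K=2), FitConfig(n_trials=1, seed=11, max_iter=60)
        )
        trows, tcols, tcounts = split.test
        pred = predict_heldout(model, trows, tcols)
        assert np.all(pred > 0)
        dense_norm, meta = normalize_counts(split.train, "log")
        # two-path equality: entrywise normalization vs dense machinery on a
        # matrix holding the predictions at the test coordinates
        pred_mat = np.zeros((X.n_cells, X.n_genes))
        pred_mat[trows, tcols] = pred
        dense_pred = np.log2(pred_mat + 1.0)
        entrywise = normalize_values(pred, trows, "log", meta)
        np.testing.assert_allclose(entrywise, dense_pred[trows, tcols], rtol=1e-12)


class TestSelectK:
    @pytest.mark.parametrize("n_clusters,expected", [(7, 10), (10, 15), (1, 5), (5, 10), (14, 15)])
    def test_smallest_multiple_of_five_strictly_greater(self, n_clusters, expected):
        assert select_k_benchmark(n_clusters) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            select_k_benchmark(0)
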