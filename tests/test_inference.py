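"""Covariance estimation, Lyapunov solves, ensembles and differential comparison."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from metajac.experiments import kron_lyapunov_solve, random_stable_sparse_jacobian
from metajac.inference import (
    CovarianceMatrix,
    FluctuationMatrix,
    InferenceError,
    JacobianEnsemble,
    MetaboliteDataset,
    NormalizedJacobian,
    SolverError,
    covariance_from_replicates,
    differential_jacobian,
    entry_significance,
    forward_lyapunov,
    inverse_jacobian,
    normalize_ensemble,
    run_ensemble,
    sample_fluctuation_matrix,
    structure_mask_from_interactions,
)


def _dataset(values, pools=None):
    values = np.asarray(values, dtype=float)
    pools = pools or [f"p{i}" for i in range(values.shape[1])]
    return MetaboliteDataset(pool_ids=pools, values=values)


class TestCovariance:
    def test_identical_replicates_give_zero_matrix(self):
        with pytest.warns(UserWarning, match="constant"):
            cov = covariance_from_replicates(_dataset(np.ones((5, 3))))
        assert np.array_equal(cov.values, np.zeros((3, 3)))

    def test_perfect_correlation_hand_computed(self):
        cov = covariance_from_replicates(_dataset([[1, 2], [2, 4], [3, 6]]))
        assert np.allclose(cov.values, [[1, 2], [2, 4]], atol=1e-14)
        assert np.linalg.matrix_rank(cov.values) == 1

    def test_matches_double_loop_bruteforce(self, rng):
        x = rng.random((5, 4))
        cov = covariance_from_replicates(_dataset(x)).values
        n = x.shape[0]
        xb = x.mean(axis=0)
        brute = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                brute[i, j] = sum(
                    (x[r, i] - xb[i]) * (x[r, j] - xb[j]) for r in range(n)
                ) / (n - 1)
        assert np.abs(cov - brute).max() < 1e-12

    def test_single_replicate_rejected(self):
        with pytest.raises(InferenceError, match="2 replicates"):
            covariance_from_replicates(_dataset([[1.0, 2.0]]))

    def test_missing_rows_dropped_on_ingestion(self):
        import pandas as pd

        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="dropped 1"):
            ds = MetaboliteDataset.from_dataframe(df)
        assert ds.n_replicates == 2
        assert ds.n_dropped == 1


class TestFluctuationSampling:
    def test_diagonal_positive_structure(self):
        D = sample_fluctuation_matrix(3, rng=0)
        assert D.diagonal.shape == (3,)
        assert np.all(D.diagonal > 0)
        full = D.values
        assert np.count_nonzero(full - np.diag(np.diag(full))) == 0

    def test_deterministic_under_seed(self):
        a = sample_fluctuation_matrix(4, rng=123)
        b = sample_fluctuation_matrix(4, rng=123)
        assert np.array_equal(a.diagonal, b.diagonal)

    def test_halfnormal_distribution(self):
        draws = np.concatenate(
            [sample_fluctuation_matrix(100, rng=np.random.default_rng(s)).diagonal
             for s in range(100)]
        )
        assert abs(draws.mean() - np.sqrt(2 / np.pi)) < 0.02  # ~3 standard errors
        _, p = scipy.stats.kstest(draws, scipy.stats.halfnorm.cdf)
        assert p > 0.01

    def test_signed_draws_keep_negative_values(self):
        D = sample_fluctuation_matrix(100, rng=np.random.default_rng(5), signed=True)
        assert (D.diagonal < 0).any()

    def test_dimension_below_one_rejected(self):
        with pytest.raises(InferenceError):
            sample_fluctuation_matrix(0, rng=0)


class TestForwardLyapunov:
    def test_negative_identity_closed_form(self):
        C = forward_lyapunov(-np.eye(2), np.eye(2))
        assert np.abs(C - np.eye(2)).max() < 1e-12

    def test_diagonal_closed_form(self):
        C = forward_lyapunov(np.diag([-1.0, -2.0]), np.eye(2))
        assert np.abs(C - np.diag([1.0, 0.5])).max() < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_kronecker_vectorization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J, _ = random_stable_sparse_jacobian(rng, 4)
        D = np.diag(rng.uniform(0.2, 1.5, size=4))
        assert np.abs(forward_lyapunov(J, D) - kron_lyapunov_solve(J, D)).max() < 1e-9

    def test_unstable_jacobian_names_eigenvalue(self):
        with pytest.raises(SolverError, match="eigenvalue"):
            forward_lyapunov(np.diag([1.0, -1.0]), np.eye(2))


class TestInverseJacobian:
    def test_identity_inputs_minimum_norm_symmetric_representative(self):
        sol = inverse_jacobian(np.eye(2), np.eye(2), np.ones((2, 2), bool))
        assert np.abs(sol.jacobian.values + np.eye(2)).max() < 1e-10
        assert sol.method == "ols_fallback"  # the operator is rank deficient
        assert sol.nullspace_dim == 1

    def test_forward_inverse_round_trip_sparse(self, rng):
        J, mask = random_stable_sparse_jacobian(rng, 5)
        D = np.diag(rng.uniform(0.3, 1.5, size=5))
        C = forward_lyapunov(J, D)
        sol = inverse_jacobian(C, D, mask)
        assert sol.nullspace_dim == 0
        assert np.abs(sol.jacobian.values - J).max() < 1e-6
        assert sol.lyapunov_residual <= 1e-8 * np.linalg.norm(2 * D, "fro")

    def test_single_entry_mask_preserves_structural_zeros(self):
        C = np.array([[1.0, 0.2], [0.2, 1.5]])
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        D = np.diag([1.0, 2.0])  # not reachable with one free entry
        sol = inverse_jacobian(C, D, mask)
        off = sol.jacobian.values.copy()
        off[0, 0] = 0.0
        assert np.all(off == 0.0)
        assert sol.lyapunov_residual > 1.0

    def test_zero_covariance_rejected(self):
        with pytest.raises(SolverError, match="fluctuation information"):
            inverse_jacobian(np.zeros((2, 2)), np.eye(2), np.ones((2, 2), bool))

    def test_empty_mask_rejected(self):
        with pytest.raises(InferenceError, match="mask"):
            inverse_jacobian(np.eye(2), np.eye(2), np.zeros((2, 2), bool))


@pytest.fixture(scope="module")
def small_cov():
    rng = np.random.default_rng(42)
    J, mask = random_stable_sparse_jacobian(rng, 4)
    D = np.diag(rng.uniform(0.5, 1.2, size=4))
    C = forward_lyapunov(J, D)
    return CovarianceMatrix(pool_ids=list("abcd"), values=C), mask


class TestEnsemble:
    def test_single_iteration_equals_direct_solve(self, small_cov):
        cov, mask = small_cov
        ens = run_ensemble(cov, mask, n_iterations=1, seed=99)
        rng = np.random.default_rng(np.random.SeedSequence(99).spawn(1)[0])
        D = sample_fluctuation_matrix(4, rng)
        sol = inverse_jacobian(cov, D, mask)
        assert np.array_equal(ens.samples[0], sol.jacobian.values)

    def test_bit_identical_under_same_seed(self, small_cov):
        cov, mask = small_cov
        a = run_ensemble(cov, mask, 64, seed=7)
        b = run_ensemble(cov, mask, 64, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_no_entry_written_outside_mask(self, small_cov):
        cov, mask = small_cov
        ens = run_ensemble(cov, mask, 32, seed=3)
        assert np.all(ens.samples[:, ~mask] == 0.0)

    def test_median_stable_under_ensemble_growth(self, small_cov):
        cov, mask = small_cov
        small = normalize_ensemble(run_ensemble(cov, mask, 300, seed=11))
        large = normalize_ensemble(run_ensemble(cov, mask, 3000, seed=12))
        pooled = (small.iqr_matrix + large.iqr_matrix) / 2
        ok = pooled > 0
        shift = np.abs(small.median_matrix - large.median_matrix)[ok]
        assert np.all(shift <= 2 * pooled[ok])

    def test_iteration_count_below_one_rejected(self, small_cov):
        cov, mask = small_cov
        with pytest.raises(InferenceError):
            run_ensemble(cov, mask, 0, seed=1)


def _ensemble_from_samples(samples, mask=None):
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[1]
    mask = np.ones((n, n), bool) if mask is None else mask
    return JacobianEnsemble(
        pool_ids=[f"p{i}" for i in range(n)],
        structure_mask=mask,
        samples=samples,
        n_iterations=samples.shape[0],
        seed=0,
    )


class TestNormalize:
    def test_degenerate_ensemble_flagged_undefined_not_infinite(self):
        ens = _ensemble_from_samples([np.eye(2)] * 5)
        norm = normalize_ensemble(ens)
        assert np.isnan(norm.normalized_matrix).all()
        assert not np.isinf(norm.normalized_matrix).any()

    def test_hand_quantile_computation(self):
        # one entry taking values 1..5: median 3, IQR 2, normalized 0.75
        samples = np.zeros((5, 2, 2))
        samples[:, 0, 0] = [1, 2, 3, 4, 5]
        norm = normalize_ensemble(_ensemble_from_samples(samples))
        assert norm.median_matrix[0, 0] == 3.0
        assert norm.iqr_matrix[0, 0] == 2.0
        assert norm.normalized_matrix[0, 0] == pytest.approx(0.75)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scaling_homogeneity(self, k, rng):
        samples = rng.standard_normal((50, 3, 3))
        a = normalize_ensemble(_ensemble_from_samples(samples))
        b = normalize_ensemble(_ensemble_from_samples(k * samples))
        ok = a.defined_mask & b.defined_mask
        assert np.allclose(
            b.normalized_matrix[ok], a.normalized_matrix[ok] / k, rtol=1e-10
        )

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(InferenceError, match="3 samples"):
            normalize_ensemble(_ensemble_from_samples(np.zeros((2, 2, 2))))


def _normalized(values, pools=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return NormalizedJacobian(
        pool_ids=pools or [f"p{i}" for i in range(n)],
        structure_mask=np.ones((n, n), bool),
        median_matrix=values,
        iqr_matrix=np.ones_like(values),
        normalized_matrix=values,
    )


class TestDifferentialJacobian:
    def test_self_comparison_is_zero(self, rng):
        a = _normalized(rng.standard_normal((3, 3)))
        dj = differential_jacobian(a, a)
        assert np.all(dj.entries[dj.defined_mask] == 0.0)

    def test_worked_log_ratios(self):
        a = _normalized([[2.0, -4.0], [1.0, 1.0]])
        b = _normalized([[1.0, 1.0], [1.0, 1.0]])
        dj = differential_jacobian(a, b)
        assert dj.entries[0, 0] == pytest.approx(1.0)  # ratio 2 -> 1
        assert dj.entries[0, 1] == pytest.approx(2.0)  # ratio -4 -> inner abs -> 2

    def test_zero_and_undefined_entries_excluded(self):
        a = _normalized([[1.0, np.nan], [0.0, 1.0]])
        b = _normalized([[0.0, 1.0], [1.0, 1.0]])
        dj = differential_jacobian(a, b)
        assert np.isnan(dj.entries[0, 0])  # b zero
        assert np.isnan(dj.entries[0, 1])  # a undefined
        assert np.isnan(dj.entries[1, 0])  # a zero
        assert dj.entries[1, 1] == 0.0

    @given(
        st.lists(
            st.floats(
                min_value=1e-6, max_value=1e6, allow_nan=False, allow_infinity=False
            ),
            min_size=8,
            max_size=8,
        ),
        st.lists(st.booleans(), min_size=8, max_size=8),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_condition_swap_symmetry(self, magnitudes, signs):
        vals = np.array(
            [(-1 if s else 1) * m for m, s in zip(magnitudes, signs)]
        ).reshape(2, 4)[:, :2]
        a, b = _normalized(vals), _normalized(vals[::-1].copy())
        ab = differential_jacobian(a, b).entries
        ba = differential_jacobian(b, a).entries
        assert np.array_equal(ab, ba)

    def test_pool_order_mismatch_rejected(self):
        a = _normalized(np.ones((2, 2)), pools=["x", "y"])
        b = _normalized(np.ones((2, 2)), pools=["y", "x"])
        with pytest.raises(InferenceError, match="ordering"):
            differential_jacobian(a, b)

    def test_ranked_entries_sorted_descending(self):
        a = _normalized([[2.0, 8.0], [1.0, 0.5]])
        b = _normalized(np.ones((2, 2)))
        ranked = differential_jacobian(a, b).ranked_entries()
        vals = [v for _, _, v in ranked]
        assert vals == sorted(vals, reverse=True)
        assert ranked[0][:2] == (0, 1)


class TestEntrySignificance:
    def test_identical_ensembles_nothing_significant(self, small_cov):
        cov, mask = small_cov
        ens = run_ensemble(cov, mask, 200, seed=4)
        sig = entry_significance(ens, ens, alpha=0.05)
        assert not sig.significant.any()

    def test_gross_separation_tiny_pvalue(self, rng):
        base = rng.standard_normal((400, 2, 2)) * 0.1
        shifted = base + 10.0
        sig = entry_significance(
            _ensemble_from_samples(base), _ensemble_from_samples(shifted)
        )
        assert np.all(sig.pvalues[np.isfinite(sig.pvalues)] < 1e-6)

    def test_welch_statistic_matches_hand_formula(self, rng):
        x = rng.standard_normal(40) + 0.3
        y = 1.5 * rng.standard_normal(35)
        from metajac.inference import welch_t

        t, p = welch_t(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        se2 = vx / nx + vy / ny
        t_hand = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), df)
        assert abs(t - t_hand) < 1e-10
        assert abs(p - p_hand) < 1e-10

    def test_batch_median_reduces_effective_n(self, small_cov):
        cov, mask = small_cov
        a = run_ensemble(cov, mask, 400, seed=1)
        b = run_ensemble(cov, mask, 400, seed=2)
        batched = entry_significance(a, b, procedure="batch_median")
        full = entry_significance(a, b, procedure="full")
        assert batched.effective_n == 100
        assert full.effective_n == 400

    def test_bh_correction_is_monotone_and_conservative(self, small_cov):
        cov, mask = small_cov
        a = run_ensemble(cov, mask, 300, seed=5)
        b = run_ensemble(cov, mask, 300, seed=6)
        raw = entry_significance(a, b, fdr="none")
        adj = entry_significance(a, b, fdr="bh")
        ok = np.isfinite(raw.pvalues) & np.isfinite(adj.pvalues)
        assert np.all(adj.pvalues[ok] >= raw.pvalues[ok] - 1e-15)

    def test_mask_mismatch_rejected(self, small_cov):
        cov, mask = small_cov
        a = run_ensemble(cov, mask, 16, seed=1)
        other = mask.copy()
        other[np.argwhere(mask)[0][0], np.argwhere(mask)[0][1]] = False
        b = run_ensemble(cov, other, 16, seed=1)
        with pytest.raises(InferenceError, match="mask"):
            entry_significance(a, b)


def test_structure_mask_from_interactions():
    # two reactions: a->b, c->(nothing shared) ; a,b share, c only with itself
    values = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, -1.0]])
    mask = structure_mask_from_interactions(values)
    assert mask[0, 1] and mask[1, 0] and mask[0, 0]
    assert mask[2, 2]
    assert not mask[0, 2] and not mask[2, 1]


def test_covariance_matrix_validation_rejects_asymmetry():
    with pytest.raises(InferenceError, match="symmetric"):
        CovarianceMatrix(pool_ids=["a", "b"], values=np.array([[1.0, 0.5], [0.2, 1.0]]))


def test_fluctuation_matrix_requires_diagonal_vector():
    with pytest.raises(InferenceError):
        FluctuationMatrix(diagonal=np.eye(2))
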