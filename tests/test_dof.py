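"""Cross-validated rank selection: SVD, CV error, golden section, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcsy
from tcsy.dof import (
    cv_error,
    estimate_dof,
    extrapolate_linear_increments,
    extrapolate_quadric,
    golden_section_min,
    svd_decompose,
)
from tcsy.qc import center_and_impute

from conftest import make_matrix


# ---------------------------------------------------------------- oracles
def cv_error_loop_oracle(T, P):
    """Explicit-loop evaluation of sum_i ||row_i (I - PP' + diag(PP'))||^2."""
    n = T.shape[1]
    PPt = [[sum(P[a][c] * P[b][c] for c in range(P.shape[1])) for b in range(n)]
           for a in range(n)]
    M = [[(1.0 if a == b else 0.0) - PPt[a][b] + (PPt[a][b] if a == b else 0.0)
          for b in range(n)] for a in range(n)]
    total = 0.0
    for row in T:
        transformed = [sum(row[a] * M[a][b] for a in range(n)) for b in range(n)]
        total += sum(v * v for v in transformed)
    return total


def gaussian_elimination_solve(A, b):
    """Hand-rolled Gaussian elimination with partial pivoting."""
    n = len(b)
    M = [list(map(float, A[i])) + [float(b[i])] for i in range(n)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(M[r][col]))
        M[col], M[piv] = M[piv], M[col]
        for r in range(col + 1, n):
            factor = M[r][col] / M[col][col]
            for c in range(col, n + 1):
                M[r][c] -= factor * M[col][c]
    x = [0.0] * n
    for r in range(n - 1, -1, -1):
        x[r] = (M[r][n] - sum(M[r][c] * x[c] for c in range(r + 1, n))) / M[r][r]
    return np.array(x)


# ---------------------------------------------------------------- SVD
class TestSvdDecompose:
    def test_diagonal_singular_values(self):
        m = make_matrix(np.diag([3.0, 2.0, 1.0]), centered=True)
        basis = svd_decompose(m)
        np.testing.assert_allclose(basis.sigma, [3.0, 2.0, 1.0], atol=1e-12)

    def test_rank2_noiseless(self):
        rng = np.random.default_rng(0)
        values = np.outer(rng.standard_normal(20), rng.standard_normal(8))
        values += np.outer(rng.standard_normal(20), rng.standard_normal(8))
        basis = svd_decompose(make_matrix(values, centered=True))
        assert np.sum(basis.sigma > 1e-10 * basis.sigma[0]) == 2

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((20, 10))
        basis = svd_decompose(make_matrix(values, centered=True))
        np.testing.assert_allclose(basis.U.T @ basis.U, np.eye(10), atol=1e-8)
        np.testing.assert_allclose(basis.V.T @ basis.V, np.eye(10), atol=1e-8)
        err = np.linalg.norm(basis.reconstruct() - values) / np.linalg.norm(values)
        assert err < 1e-10

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((15, 6))
        b1 = svd_decompose(make_matrix(values, centered=True))
        b2 = svd_decompose(make_matrix(values.copy(), centered=True))
        assert np.array_equal(b1.U, b2.U)
        idx = np.argmax(np.abs(b1.U), axis=0)
        assert np.all(b1.U[idx, np.arange(6)] > 0)

    def test_requires_centered_input(self):
        with pytest.raises(ValueError):
            svd_decompose(make_matrix(np.ones((3, 3)), centered=False))


# ---------------------------------------------------------------- CV error
class TestCvError:
    def test_k0_equals_frobenius(self):
        rng = np.random.default_rng(3)
        T = rng.standard_normal((4, 5))
        P = np.empty((5, 0))
        assert cv_error(T, P) == pytest.approx(np.sum(T * T), rel=1e-12)

    def test_full_rank_projector_equals_frobenius(self):
        rng = np.random.default_rng(4)
        T = rng.standard_normal((4, 5))
        P, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        assert cv_error(T, P) == pytest.approx(np.sum(T * T), rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_explicit_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_exp = int(rng.integers(2, 6))
        n_genes = int(rng.integers(1, 6))
        k = int(rng.integers(1, n_exp + 1))
        P, _ = np.linalg.qr(rng.standard_normal((n_exp, k)))
        P = P[:, :k]
        T = rng.standard_normal((n_genes, n_exp))
        assert cv_error(T, P) == pytest.approx(cv_error_loop_oracle(T, P), rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_endpoint_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_exp = int(rng.integers(3, 10))
        T = rng.standard_normal((int(rng.integers(2, 8)), n_exp))
        frob2 = np.sum(T * T)
        P_full, _ = np.linalg.qr(rng.standard_normal((n_exp, n_exp)))
        assert cv_error(T, np.empty((n_exp, 0))) == pytest.approx(frob2, rel=1e-10)
        assert cv_error(T, P_full) == pytest.approx(frob2, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cv_error(np.ones((2, 3)), np.ones((4, 1)))


# ---------------------------------------------------------------- search
class TestGoldenSection:
    def test_integer_quadratic(self):
        assert golden_section_min(lambda k: (k - 7) ** 2, 1, 100) == 7

    def test_boundary_minimum(self):
        assert golden_section_min(lambda k: float(k), 1, 50) == 1
        assert golden_section_min(lambda k: float(-k), 1, 50) == 50

    def test_tie_breaks_toward_smaller(self):
        # f(3) == f(4): plateau between two integers
        f = lambda k: abs(k - 3.5)
        assert golden_section_min(f, 1, 20) == 3

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        vertex=st.integers(min_value=1, max_value=200),
        scale=st.floats(min_value=0.01, max_value=50),
        hi=st.integers(min_value=10, max_value=200),
    )
    def test_matches_exhaustive_scan_on_convex_quadratics(self, vertex, scale, hi):
        f = lambda k: scale * (k - vertex) ** 2
        result = golden_section_min(f, 1, hi)
        exhaustive = min(range(1, hi + 1), key=f)
        assert f(result) == pytest.approx(f(exhaustive))

    def test_cv_curve_matches_exhaustive(self):
        truth = tcsy.SyntheticTruth.linear_profile(
            rank=4, top=20, bottom=8, noise_sd=0.1, seed=6
        )
        delta, _ = tcsy.simulate_low_rank_delta(120, 30, truth)
        rng = np.random.default_rng(0)
        perm = rng.permutation(120)
        train, test = perm[:90], perm[90:]
        means = delta.values[train].mean(axis=0)
        Tr = delta.values[train] - means
        Te = delta.values[test] - means
        V = np.linalg.svd(Tr, full_matrices=False)[2].T
        f = lambda k: cv_error(Te, V[:, :k])
        found = golden_section_min(f, 1, 29)
        exhaustive = min(range(1, 30), key=f)
        assert f(found) == pytest.approx(f(exhaustive))

    def test_invalid_bracket(self):
        with pytest.raises(ValueError):
            golden_section_min(lambda k: k, 5, 5)


# ---------------------------------------------------------------- estimation
class TestEstimateDof:
    def test_recovers_planted_rank(self):
        truth = tcsy.SyntheticTruth.linear_profile(
            rank=5, top=30.0, bottom=12.0, noise_sd=0.1, seed=21
        )
        delta, _ = tcsy.simulate_low_rank_delta(300, 80, truth)
        est = estimate_dof(delta, n_train=240, n_repeats=5, seed=0, bracket=(1, 40))
        assert abs(est.mean - 5) <= 2

    def test_pure_noise_selects_minimal_rank(self):
        rng = np.random.default_rng(11)
        delta = make_matrix(rng.standard_normal((400, 300)))
        # bracket kept well below the rank bound, as with 800 vs a full corpus
        est = estimate_dof(delta, n_train=320, n_repeats=15, seed=0, bracket=(1, 100))
        assert np.sum(np.asarray(est.runs) <= 5) >= 13

    def test_gene_order_invariance_given_same_split(self):
        truth = tcsy.SyntheticTruth.linear_profile(
            rank=3, top=15, bottom=6, noise_sd=0.05, seed=5
        )
        delta, _ = tcsy.simulate_low_rank_delta(60, 25, truth)
        rng = np.random.default_rng(9)
        perm = rng.permutation(60)
        train, test = perm[:45], perm[45:]
        est1 = estimate_dof(delta, n_train=45, n_repeats=1, splits=[(train, test)])
        shuffle = rng.permutation(60)
        inverse = np.argsort(shuffle)
        permuted = delta.subset(gene_index=shuffle)
        est2 = estimate_dof(
            permuted,
            n_train=45,
            n_repeats=1,
            splits=[(inverse[train], inverse[test])],
        )
        assert est1.runs == est2.runs

    def test_summary_statistics_consistent(self):
        est = tcsy.DofEstimate(runs=[4, 5, 6], n_repeats=3)
        assert est.mean == pytest.approx(5.0)
        assert est.min == 4 and est.max == 6
        assert est.sd == pytest.approx(1.0)

    def test_preconditions(self):
        delta = make_matrix(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            estimate_dof(delta, n_train=10)
        with pytest.raises(ValueError):
            estimate_dof(make_matrix(np.zeros((10, 1))), n_train=5)


@pytest.fixture(scope="module")
def structured_world():
    truth = tcsy.SyntheticTruth.linear_profile(
        rank=30, top=40.0, bottom=15.0, noise_sd=0.1, seed=17
    )
    delta, _ = tcsy.simulate_low_rank_delta(400, 240, truth)
    return delta


class TestDataSizeSweep:

    def test_mean_dof_nondecreasing_in_experiments(self, structured_world):
        # at small experiment counts the resolvable rank is data-limited
        table, summary, increments = tcsy.dof_vs_datasize(
            structured_world,
            "experiments",
            sizes=[40, 120, 240],
            n_repeats=4,
            seed=0,
            bracket=(1, 35),
        )
        means = summary["mean_dof"].to_numpy()
        assert np.all(np.diff(means) >= -1.0)
        assert len(increments) == 2

    def test_gene_sweep_flat_for_fixed_rank(self, structured_world):
        truth = tcsy.SyntheticTruth.linear_profile(
            rank=5, top=30.0, bottom=12.0, noise_sd=0.1, seed=19
        )
        delta, _ = tcsy.simulate_low_rank_delta(500, 100, truth)
        _, summary, _ = tcsy.dof_vs_datasize(
            delta, "genes", sizes=[250, 350, 500], n_repeats=4, seed=0, bracket=(1, 40)
        )
        means = summary["mean_dof"].to_numpy()
        assert np.max(np.abs(means - 5)) <= 2

    def test_oversized_request_rejected(self, structured_world):
        with pytest.raises(ValueError):
            tcsy.dof_vs_datasize(structured_world, "experiments", sizes=[10_000])


class TestExtrapolation:
    def test_exact_parabola_vertex(self):
        x = np.array([1.0, 5.0, 9.0, 13.0])
        y = -((x - 11.0) ** 2) + 443.0
        vx, vy = extrapolate_quadric(x, y)
        assert vx == pytest.approx(11.0)
        assert vy == pytest.approx(443.0)

    def test_exact_line_zero_crossing(self):
        x = np.array([1.5, 2.5, 3.5, 4.5])
        y = 72.0 - 8.0 * (x - 1.5)  # root at x = 10.5
        assert extrapolate_linear_increments(x, y) == pytest.approx(10.5)

    def test_upward_parabola_flagged(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            extrapolate_quadric(x, (x - 2.0) ** 2)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_quadric([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            extrapolate_linear_increments([2.0, 2.0], [1.0, 2.0])
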