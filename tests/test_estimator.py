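import numpy as np
import pytest

from gpgee import (
    EstimationError,
    GroupStructure,
    ScadPenalty,
    Table1Design,
    WorkingCorrelation,
    bic_path,
    build_ar1,
    fit_gpgee,
    gee_hessian,
    gee_score,
    generate_arrays,
    lambda_grid,
    newton_mm_step,
    scad_derivative,
)


def _random_problem(rng, n=8, m=4, p=3, beta=None):
    X = rng.standard_normal((n, m, p))
    if beta is None:
        beta = rng.standard_normal(p)
    y = X.reshape(n * m, p).dot(beta).reshape(n, m) + rng.standard_normal((n, m))
    return X, y


class TestScore:
    def test_zero_at_least_squares_solution_under_independence(self, rng):
        X, y = _random_problem(rng)
        b_ls, *_ = np.linalg.lstsq(X.reshape(-1, 3), y.ravel(), rcond=None)
        S = gee_score(b_ls, X, y, np.eye(4))
        np.testing.assert_allclose(S, 0, atol=1e-10)

    def test_plug_in_value_at_beta_zero(self, rng):
        X = rng.standard_normal((5, 3, 2))
        Xf = X.reshape(-1, 2)
        y = Xf.dot(np.ones(2)).reshape(5, 3)
        S = gee_score(np.zeros(2), X, y, np.eye(3))
        np.testing.assert_allclose(S, Xf.T @ Xf @ np.ones(2), rtol=1e-12)

    def test_two_subject_toy_against_explicit_inverse(self):
        # n=2 clusters of size 2, single covariate of ones, R = AR1(0.5);
        # oracle uses the hand-inverted 2x2 correlation matrix
        X = np.ones((2, 2, 1))
        y = np.array([[1.0, 2.0], [0.0, 1.0]])
        R = build_ar1(2, 0.5)
        Rinv = np.array([[1, -0.5], [-0.5, 1]]) / 0.75
        oracle = sum(X[i].T @ Rinv @ y[i] for i in range(2))
        S = gee_score(np.zeros(1), X, y, R)
        np.testing.assert_allclose(S, oracle, atol=1e-12)


class TestHessian:
    def test_identity_R_gives_gram_matrix(self, rng):
        X, y = _random_problem(rng)
        H = gee_hessian(np.zeros(3), X, y, np.eye(4))
        Xf = X.reshape(-1, 3)
        np.testing.assert_allclose(H, Xf.T @ Xf, rtol=1e-12)

    def test_symmetric_positive_semidefinite(self, rng):
        X, y = _random_problem(rng)
        H = gee_hessian(np.zeros(3), X, y, build_ar1(4, 0.7))
        np.testing.assert_allclose(H, H.T)
        assert np.linalg.eigvalsh(H)[0] > -1e-10

    def test_against_naive_triple_product_loop(self, rng):
        X, y = _random_problem(rng, n=4, m=3, p=2)
        R = build_cs_like = build_ar1(3, 0.4)
        Rinv = np.linalg.inv(R)
        oracle = np.zeros((2, 2))
        for i in range(4):
            oracle += X[i].T @ Rinv @ X[i]
        H = gee_hessian(np.zeros(2), X, y, R)
        np.testing.assert_allclose(H, oracle, rtol=1e-10)


class TestNewtonStep:
    def test_unpenalized_step_reaches_least_squares_fixed_point(self, rng):
        X, y = _random_problem(rng)
        Xf = X.reshape(-1, 3)
        H = Xf.T @ Xf
        S0 = Xf.T @ y.ravel()
        beta1 = newton_mm_step(np.zeros(3), H, np.zeros(3), S0, n_subjects=8)
        b_ls, *_ = np.linalg.lstsq(Xf, y.ravel(), rcond=None)
        np.testing.assert_allclose(beta1, b_ls, atol=1e-7)

    def test_stationarity_preserved(self):
        out = newton_mm_step(
            np.zeros(2), np.eye(2), np.ones(2), np.zeros(2), n_subjects=5
        )
        np.testing.assert_allclose(out, 0)

    def test_scalar_instance_hand_computed(self):
        # beta + (H + nE)^{-1} (S - nE beta) = 1 + (2+2*0.5)^{-1} (4 - 1) = 2
        out = newton_mm_step(
            np.array([1.0]), np.array([[2.0]]), np.array([0.5]),
            np.array([4.0]), n_subjects=2,
        )
        assert out[0] == pytest.approx(2.0, abs=1e-7)  # up to the 1e-8 ridge

    def test_non_finite_update_raises(self):
        with pytest.raises(EstimationError):
            newton_mm_step(
                np.array([np.inf]), np.array([[1.0]]), np.zeros(1),
                np.array([1.0]), 1,
            )


class TestFitGpgee:
    def test_unpenalized_independence_fit_is_least_squares(self, rng):
        for _ in range(5):
            X, y = _random_problem(rng, n=10, m=4, p=4)
            fit = fit_gpgee(
                X, y, GroupStructure.singletons(4), correlation="independence",
                dims=(2, 2), lam=0.0,
            )
            b_ls, *_ = np.linalg.lstsq(X.reshape(-1, 4), y.ravel(), rcond=None)
            np.testing.assert_allclose(fit.beta, b_ls, atol=1e-8)
            assert fit.converged

    def test_full_shrinkage_leaves_only_unpenalized_terms(self, rng):
        # pure-noise covariates plus an unpenalized intercept
        n, m, p = 40, 4, 4
        X = rng.standard_normal((n, m, p))
        X[:, :, 0] = 1.0
        y = 3.0 + rng.standard_normal((n, m))
        groups = GroupStructure.singletons(p, unpenalized=[0])
        lam_big = 5 * np.max(np.abs(X.reshape(-1, p).T @ y.ravel())) / n
        fit = fit_gpgee(
            X, y, groups, correlation="independence", dims=(2, 2), lam=lam_big
        )
        assert fit.selected_groups == ()
        np.testing.assert_array_equal(fit.beta[1:], 0)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_monotone_support_shrinkage_along_ascending_grid(self):
        design = Table1Design(n_subjects=50)
        X, y = generate_arrays(design, seed=100)
        groups = design.group_structure("grouped")
        lams = np.sort(lambda_grid(X, y, groups))
        prev = None
        beta_prev = None
        for lam in lams:
            fit = fit_gpgee(
                X, y, groups, correlation="kron:unstructured,ar1", dims=(2, 10),
                lam=float(lam), beta0=beta_prev,
            )
            beta_prev = fit.beta
            support = set(fit.selected_groups)
            if prev is not None:
                assert support.issubset(prev)
            prev = support

    def test_max_iter_reached_returns_unconverged_fit(self, rng):
        X, y = _random_problem(rng, n=10, m=4, p=4)
        fit = fit_gpgee(
            X, y, GroupStructure.singletons(4), correlation="ar1", dims=(2, 2),
            lam=0.5, max_iter=2,
        )
        assert not fit.converged and fit.n_iter == 2

    def test_string_spec_requires_dims(self, rng):
        X, y = _random_problem(rng)
        with pytest.raises(Exception):
            fit_gpgee(X, y, GroupStructure.singletons(3), correlation="ar1")

    def test_fast_and_reference_routes_agree(self):
        design = Table1Design(n_subjects=30)
        X, y = generate_arrays(design, seed=11)
        groups = design.group_structure("grouped")
        for corr in ("kron:unstructured,ar1", "ar1", "cs"):
            fast = fit_gpgee(
                X, y, groups, correlation=corr, dims=(2, 10), lam=3.0
            )
            ref = fit_gpgee(
                X, y, groups, correlation=corr, dims=(2, 10), lam=3.0,
                keep_trace=True,  # trace keeping uses the reference loop
            )
            np.testing.assert_allclose(fast.beta, ref.beta, atol=1e-10)
            assert fast.selected_groups == ref.selected_groups
            assert fast.n_iter == ref.n_iter


def _pgee_oracle_iterates(X, y, lam, a=3.7, eps=1e-6, tol=1e-5, max_iter=100):
    """Direct per-coefficient SCAD MM under working independence.

    Independent re-implementation of individual-SCAD penalized GEE used as
    the oracle for the singleton-group reduction.
    """
    n, m, p = X.shape
    Xf = X.reshape(n * m, p)
    H = Xf.T @ Xf
    beta, *_ = np.linalg.lstsq(Xf, y.ravel(), rcond=None)
    iterates = [beta.copy()]
    for _ in range(max_iter):
        S = Xf.T @ (y.ravel() - Xf @ beta)
        q = np.array(
            [scad_derivative(abs(b), ScadPenalty(lam=lam, a=a)) for b in beta]
        )
        E = q / (eps + np.abs(beta))
        M = H + n * np.diag(E)
        M[np.diag_indices_from(M)] += 1e-8
        beta = beta + np.linalg.solve(M, S - n * E * beta)
        iterates.append(beta.copy())
        if np.abs(iterates[-1] - iterates[-2]).sum() < tol:
            break
    return iterates


def test_singleton_groups_reproduce_individual_scad_iterates():
    """All-singleton GPGEE equals a direct per-coefficient SCAD solver."""
    design = Table1Design(n_subjects=25)
    X, y = generate_arrays(design, seed=21)
    lam = 5.0
    fit = fit_gpgee(
        X, y, GroupStructure.singletons(40), correlation="independence",
        dims=(2, 10), lam=lam, keep_trace=True,
    )
    oracle = _pgee_oracle_iterates(X, y, lam)
    assert len(fit.trace) == len(oracle)
    for ours, theirs in zip(fit.trace, oracle):
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestBicPath:
    def test_single_value_grid_returns_that_fit(self, rng):
        X, y = _random_problem(rng, n=10, m=4, p=4)
        fit = bic_path(
            X, y, GroupStructure.singletons(4), correlation="independence",
            dims=(2, 2), lambdas=np.array([0.3]),
        )
        assert fit.lam == pytest.approx(0.3)
        assert len(fit.bic_path) == 1

    def test_ties_resolve_to_larger_lambda(self, rng):
        n, m, p = 30, 4, 3
        X = rng.standard_normal((n, m, p))
        y = rng.standard_normal((n, m))
        lam_big = 5 * np.max(np.abs(X.reshape(-1, p).T @ y.ravel())) / n
        fit = bic_path(
            X, y, GroupStructure.singletons(p), correlation="independence",
            dims=(2, 2), lambdas=np.array([lam_big, 2 * lam_big]),
        )
        assert fit.lam == pytest.approx(2 * lam_big)
        assert fit.selected_groups == ()

    def test_pure_noise_design_retains_no_penalized_group(self):
        # benchmark layout with beta = 0: BIC should keep the empty model
        design = Table1Design(n_subjects=100, beta=np.zeros(40))
        groups = design.group_structure("grouped")
        hits = 0
        reps = 10
        for r in range(reps):
            X, y = generate_arrays(design, 600 + r)
            fit = bic_path(
                X, y, groups, correlation="kron:unstructured,ar1", dims=(2, 10)
            )
            hits += fit.selected_groups == ()
        assert hits >= 0.9 * reps

    def test_bic_minimum_is_interior_on_benchmark_replicate(self):
        design = Table1Design(n_subjects=50)
        X, y = generate_arrays(design, seed=100)
        fit = bic_path(
            X, y, design.group_structure("grouped"),
            correlation="kron:unstructured,ar1", dims=(2, 10),
        )
        lams = [l for (l, b, d) in fit.bic_path]
        assert min(lams) < fit.lam < max(lams)
        assert fit.selected_groups == (0, 1, 2, 3)
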