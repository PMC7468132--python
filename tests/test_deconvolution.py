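import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecn.deconvolution import (
    DeconvolutionParams,
    Solution,
    objective,
    solve_cacf_cd,
    solve_cacf_ilp,
    update_copy_numbers,
    update_proportions,
)
from conftest import tree_truth


def matches_up_to_permutation(sol, A, B, U, atol=1e-6):
    """Check equality of (A, B, U) up to tumor-clone permutation and
    per-cluster allele mirroring of the truth."""
    if sol.n != A.shape[1]:
        return False
    n = A.shape[1]
    for perm in itertools.permutations(range(1, n)):
        p = (0,) + perm
        ok = np.allclose(sol.U, U[list(p)], atol=atol)
        if not ok:
            continue
        Ap, Bp = A[:, list(p)], B[:, list(p)]
        state_ok = True
        for s in range(A.shape[0]):
            same = (sol.A[s] == Ap[s]).all() and (sol.B[s] == Bp[s]).all()
            mirrored = (sol.A[s] == Bp[s]).all() and (sol.B[s] == Ap[s]).all()
            if not (same or mirrored):
                state_ok = False
                break
        if state_ok:
            return True
    return False


class TestObjective:
    def test_exact_factorization_zero(self):
        rng = np.random.default_rng(0)
        A, B, U = tree_truth(10, 3, 2, rng)
        assert objective(A @ U, B @ U, A, B, U, np.full(10, 1.0)) == 0.0

    def test_weighted_arithmetic(self):
        # one cluster, one sample, length 10, residuals 0.2 and 0.1 -> 3.0
        A = np.array([[1, 2]])
        B = np.array([[1, 1]])
        U = np.array([[0.5], [0.5]])
        FA = A @ U + 0.2
        FB = B @ U - 0.1
        assert objective(FA, FB, A, B, U, np.array([10.0])) == pytest.approx(3.0)

    def test_linearity_in_lengths(self):
        rng = np.random.default_rng(1)
        A, B, U = tree_truth(8, 3, 2, rng)
        FA = A @ U + rng.normal(0, 0.1, size=(8, 2))
        FB = B @ U
        w = rng.uniform(1, 5, size=8)
        assert objective(FA, FB, A, B, U, 2 * w) == pytest.approx(
            2 * objective(FA, FB, A, B, U, w)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 10.0))
    def test_scaling_lengths_scales_objective(self, seed, factor):
        rng = np.random.default_rng(seed)
        A, B, U = tree_truth(6, 3, 2, rng)
        FA = A @ U + rng.normal(0, 0.2, size=(6, 2))
        FB = np.minimum(B @ U, FA)
        w = rng.uniform(0.5, 2.0, size=6)
        base = objective(FA, FB, A, B, U, w)
        assert objective(FA, FB, A, B, U, factor * w) == pytest.approx(
            factor * base, rel=1e-9
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            objective(np.zeros((3, 2)), np.zeros((3, 2)), np.ones((3, 2), int),
                      np.ones((3, 2), int), np.ones((3, 2)), np.ones(3))


class TestUpdateCopyNumbers:
    def test_single_tumor_clone_closed_form(self):
        # n = 2: a = round((fA - u1) / u2) cluster-wise
        rng = np.random.default_rng(2)
        params = DeconvolutionParams()
        A, B, U = tree_truth(15, 2, 2, rng)
        FA, FB = A @ U, B @ U
        A2, B2 = update_copy_numbers(FA, FB, U, np.full(15, 1.0), params)
        np.testing.assert_array_equal(A2, A)
        np.testing.assert_array_equal(B2, B)

    def test_midway_tie_broken_toward_theta(self):
        # fA exactly midway between integer fits: state closer to theta wins
        params = DeconvolutionParams(theta=1)
        U = np.array([[0.5], [0.5]])
        FA = np.array([[0.5 + 0.5 * 2.5]])  # a = 2 or 3 fit equally
        FB = np.array([[0.5 + 0.5 * 1.0]])
        A2, B2 = update_copy_numbers(FA, FB, U, np.array([1.0]), params)
        assert A2[0, 1] == 2  # 2 is closer to theta = 1 than 3
        assert B2[0, 1] == 1

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_exact_minimizer_vs_enumeration(self, n):
        """The lattice/prefix-min update equals brute-force enumeration."""
        rng = np.random.default_rng(n)
        params = DeconvolutionParams(c_max=4, theta=1)
        m, k = 4, 2
        A, B, U = tree_truth(m, n, k, rng, c_max=4)
        FA = A @ U + rng.normal(0, 0.2, size=(m, k))
        FB = B @ U + rng.normal(0, 0.2, size=(m, k))
        FB = np.minimum(FA, FB)
        w = rng.uniform(1, 3, size=m)
        A2, B2 = update_copy_numbers(FA, FB, U, w, params)
        got = objective(FA, FB, A2, B2, U, w)
        # brute force over all theta-respecting state vectors per cluster
        d = n - 1
        side = [
            v for v in itertools.product(range(params.c_max + 1), repeat=d)
            if all(x <= params.theta for x in v) or all(x >= params.theta for x in v)
        ]
        best = 0.0
        for s in range(m):
            cbest = np.inf
            for av in side:
                for bv in side:
                    if any(a + b > params.c_max for a, b in zip(av, bv)):
                        continue
                    fa_fit = U[0] + np.array(av) @ U[1:]
                    fb_fit = U[0] + np.array(bv) @ U[1:]
                    c = w[s] * (np.abs(FA[s] - fa_fit).sum()
                                + np.abs(FB[s] - fb_fit).sum())
                    cbest = min(cbest, c)
            best += cbest
        assert got == pytest.approx(best, abs=1e-9)

    def test_descent_step_never_increases_objective(self):
        rng = np.random.default_rng(5)
        params = DeconvolutionParams()
        A, B, U = tree_truth(12, 3, 2, rng)
        FA = A @ U + rng.normal(0, 0.1, size=(12, 2))
        FB = np.minimum(B @ U + rng.normal(0, 0.1, size=(12, 2)), FA)
        w = np.full(12, 1.0)
        before = objective(FA, FB, A, B, U, w)
        A2, B2 = update_copy_numbers(FA, FB, U, w, params)
        after = objective(FA, FB, A2, B2, U, w)
        assert after <= before + 1e-12

    def test_constraints_respected(self):
        rng = np.random.default_rng(6)
        for theta in (1, 2):
            params = DeconvolutionParams(c_max=6, theta=theta)
            A, B, U = tree_truth(10, 4, 2, rng, theta=theta, c_max=6)
            FA = A @ U + rng.normal(0, 0.3, size=(10, 2))
            FB = np.minimum(B @ U + rng.normal(0, 0.3, size=(10, 2)), FA)
            A2, B2 = update_copy_numbers(FA, FB, U, np.full(10, 1.0), params)
            assert (A2[:, 0] == 1).all() and (B2[:, 0] == 1).all()
            assert (A2 + B2 <= params.c_max).all()
            for s in range(10):
                for M in (A2, B2):
                    v = M[s, 1:]
                    assert (v >= theta).all() or (v <= theta).all()


class TestUpdateProportions:
    def test_pure_normal_when_f_is_diploid(self):
        params = DeconvolutionParams()
        A = np.array([[1, 3], [1, 0]])
        B = np.array([[1, 2], [1, 0]])
        FA = np.array([[1.0], [1.0]])
        FB = np.array([[1.0], [1.0]])
        U = update_proportions(FA, FB, A, B, np.array([1.0, 1.0]), params)
        np.testing.assert_allclose(U[:, 0], [1.0, 0.0], atol=1e-9)

    def test_noiseless_two_clone_exact_recovery(self):
        rng = np.random.default_rng(7)
        params = DeconvolutionParams()
        A, B, U = tree_truth(12, 3, 2, rng)
        FA, FB = A @ U, B @ U
        U2 = update_proportions(FA, FB, A, B, np.full(12, 1.0), params)
        assert objective(FA, FB, A, B, U2, np.full(12, 1.0)) < 1e-8

    def test_semi_continuity_enforced(self):
        rng = np.random.default_rng(8)
        params = DeconvolutionParams(u_min=0.1)
        A, B, U = tree_truth(10, 4, 3, rng)
        FA = A @ U + rng.normal(0, 0.2, size=(10, 3))
        FB = np.minimum(B @ U + rng.normal(0, 0.2, size=(10, 3)), FA)
        U2 = update_proportions(FA, FB, A, B, np.full(10, 1.0), params)
        tum = U2[1:]
        assert ((tum < 1e-12) | (tum >= params.u_min - 1e-9)).all()
        np.testing.assert_allclose(U2.sum(axis=0), 1.0, atol=1e-9)


class TestCoordinateDescent:
    def test_noiseless_recovery_m20(self):
        rng = np.random.default_rng(9)
        params = DeconvolutionParams()
        A, B, U = tree_truth(20, 3, 3, rng)
        FA, FB = A @ U, B @ U
        w = np.full(20, 50_000.0)
        sol = solve_cacf_cd(FA, FB, 3, params, w, restarts=20, seed=0)
        assert sol.D < 1e-6
        assert matches_up_to_permutation(sol, A, B, U, atol=1e-5)

    def test_pure_normal_target(self):
        params = DeconvolutionParams()
        FA = np.ones((6, 2))
        FB = np.ones((6, 2))
        sol = solve_cacf_cd(FA, FB, 2, params, np.full(6, 1.0), restarts=5, seed=0)
        assert sol.D < 1e-9
        # the tumor clone either vanished or duplicated the normal states
        assert sol.n == 1 or (sol.U[1:] < 1e-9).all()

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(10)
        params = DeconvolutionParams()
        A, B, U = tree_truth(15, 4, 2, rng)
        FA, FB = A @ U, B @ U
        w = np.full(15, 1.0)
        d1 = solve_cacf_cd(FA, FB, 4, params, w, restarts=1, seed=3).D
        d20 = solve_cacf_cd(FA, FB, 4, params, w, restarts=20, seed=3).D
        assert d20 <= d1 + 1e-9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        params = DeconvolutionParams()
        A, B, U = tree_truth(10, 3, 2, rng)
        FA = A @ U + rng.normal(0, 0.05, size=(10, 2))
        FB = np.minimum(B @ U, FA)
        w = np.full(10, 1.0)
        s1 = solve_cacf_cd(FA, FB, 3, params, w, restarts=5, seed=4)
        s2 = solve_cacf_cd(FA, FB, 3, params, w, restarts=5, seed=4)
        assert s1.D == s2.D
        np.testing.assert_array_equal(s1.A, s2.A)
        np.testing.assert_allclose(s1.U, s2.U)

    def test_noise_stability_bound(self):
        """With iid noise of scale eps on F, the best D stays within the L1
        perturbation bound 2 sum(l) eps k (asserted empirically)."""
        rng = np.random.default_rng(12)
        params = DeconvolutionParams()
        m, k, eps = 20, 2, 0.02
        A, B, U = tree_truth(m, 3, k, rng)
        FA = A @ U + rng.uniform(-eps, eps, size=(m, k))
        FB = np.minimum(B @ U + rng.uniform(-eps, eps, size=(m, k)), FA)
        w = np.full(m, 1.0)
        sol = solve_cacf_cd(FA, FB, 3, params, w, restarts=10, seed=0)
        assert sol.D <= 2 * w.sum() * eps * k


class TestSolutionDerived:
    def test_ploidy_purity_identity(self):
        rng = np.random.default_rng(13)
        A, B, U = tree_truth(12, 3, 2, rng)
        w = np.full(12, 50_000.0)
        sol = Solution(A, B, U, 0.0, w, DeconvolutionParams())
        L = w.sum()
        Li = sol.clone_genome_lengths
        for p in range(2):
            mu = sol.purity[p]
            if mu > 0:
                lhs = sol.ploidy[p] * mu * L
                rhs = float(U[1:, p] @ Li[1:])
                assert lhs == pytest.approx(rhs)

    def test_dedup_merges_identical_clones(self):
        A = np.array([[1, 2, 2], [1, 0, 0]])
        B = np.array([[1, 1, 1], [1, 0, 0]])
        U = np.array([[0.4, 0.2], [0.3, 0.5], [0.3, 0.3]])
        sol = Solution(A, B, U, 0.0, np.full(2, 1.0), DeconvolutionParams())
        out = sol.dedup_clones()
        assert out.n == 2
        np.testing.assert_allclose(out.U[1], [0.6, 0.8])


class TestILPOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noiseless_instance_reaches_zero(self, seed):
        rng = np.random.default_rng(seed)
        params = DeconvolutionParams()
        m, n, k = 6, 2, 2
        A, B, U = tree_truth(m, n, k, rng)
        U = np.round(U * 100) / 100  # representable on the default grid
        U[0] = 1 - U[1:].sum(axis=0)
        FA, FB = A @ U, B @ U
        sol = solve_cacf_ilp(FA, FB, n, params, np.full(m, 1.0))
        assert sol.D < 1e-9

    def test_oracle_dominates_coordinate_descent(self):
        """On instances whose optimum lies on the proportion grid the ILP
        value is a true lower bound for coordinate descent; off-grid the
        bound relaxes by the grid resolution (c_max-Lipschitz in u)."""
        rng = np.random.default_rng(3)
        params = DeconvolutionParams()
        m, n, k = 6, 2, 2
        A, B, U = tree_truth(m, n, k, rng)
        U = np.round(U * 100) / 100
        U[0] = 1 - U[1:].sum(axis=0)
        w = np.full(m, 1.0)
        # noiseless, on-grid: both should reach (near) zero, ILP not above CD
        FA, FB = A @ U, B @ U
        d_ilp = solve_cacf_ilp(FA, FB, n, params, w).D
        d_cd = solve_cacf_cd(FA, FB, n, params, w, restarts=10, seed=0).D
        assert d_ilp <= d_cd + 1e-6
        # noisy: the grid optimum can exceed the continuous optimum by at
        # most 2 c_max (n-1) * grid/2 per cluster-sample entry
        grid = 0.01
        FA = FA + rng.normal(0, 0.05, size=(m, k))
        FB = np.minimum(FB + rng.normal(0, 0.05, size=(m, k)), FA)
        d_ilp = solve_cacf_ilp(FA, FB, n, params, w, grid=grid).D
        d_cd = solve_cacf_cd(FA, FB, n, params, w, restarts=10, seed=0).D
        slack = w.sum() * k * 2 * params.c_max * (n - 1) * grid / 2
        assert d_ilp <= d_cd + slack + 1e-6

    def test_single_cluster_brute_force_cross_check(self):
        """m = 1: exhaustive search over states and the proportion grid
        equals the ILP optimum."""
        rng = np.random.default_rng(4)
        params = DeconvolutionParams(c_max=4)
        FA = np.array([[1.37]])
        FB = np.array([[0.61]])
        w = np.array([1.0])
        d_ilp = solve_cacf_ilp(FA, FB, 2, params, w, grid=0.01).D
        best = np.inf
        for a in range(params.c_max + 1):
            for b in range(params.c_max + 1 - a):
                for g in range(101):
                    u = g / 100
                    if 0 < u < params.u_min:
                        continue
                    fa = (1 - u) + a * u
                    fb = (1 - u) + b * u
                    best = min(best, abs(FA[0, 0] - fa) + abs(FB[0, 0] - fb))
        assert d_ilp == pytest.approx(best, abs=1e-9)

    def test_guard_rejected_without_force(self):
        params = DeconvolutionParams()
        FA = np.ones((20, 2))
        FB = np.ones((20, 2))
        with pytest.raises(ValueError, match="guard"):
            solve_cacf_ilp(FA, FB, 2, params, np.full(20, 1.0))
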