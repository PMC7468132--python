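"""Distance-based constrained allele-specific copy-number factorization.

Given allele-specific fractional copy numbers F^A, F^B (clusters x samples)
the goal is to find integer copy-number matrices A, B (clusters x clones)
and clone proportions U (clones x samples) minimizing the length-weighted
L1 distance

    D = ||F^A - AU|| + ||F^B - BU||,
    ||X - Y|| = sum_s sum_p l_s |x_{s,p} - y_{s,p}|,

subject to: clone 1 is the diploid normal (a = b = 1 everywhere); total
copy numbers a+b <= c_max; tumor proportions are 0 or >= u_min with simplex
columns; and per cluster and allele all tumor clones sit on one side of
theta (theta = 1 without WGD, 2 with WGD) — an allele cannot be amplified
in one clone and deleted in another.

The solver is coordinate descent alternating an exact integer update of
(A, B) with an exact per-sample proportion update, from multiple random
restarts. A mixed-integer program over a discretized proportion grid
provides a global oracle for small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

__all__ = [
    "DeconvolutionParams",
    "Solution",
    "objective",
    "update_copy_numbers",
    "update_proportions",
    "solve_cacf_cd",
    "solve_cacf_ilp",
]

C_MAX = 12
U_MIN = 0.03


@dataclass(frozen=True)
class DeconvolutionParams:
    c_max: int = C_MAX
    u_min: float = U_MIN
    theta: int = 1  # 1 without WGD, 2 with WGD

    def __post_init__(self) -> None:
        if self.c_max < 2:
            raise ValueError("c_max must be at least 2")
        if not 0 < self.u_min < 1:
            raise ValueError("u_min must be in (0, 1)")
        if self.theta not in (1, 2):
            raise ValueError("theta must be 1 or 2")


@dataclass
class Solution:
    """A factorization F^A ~ AU, F^B ~ BU with its objective value."""

    A: np.ndarray
    B: np.ndarray
    U: np.ndarray
    D: float
    lengths: np.ndarray
    params: DeconvolutionParams
    hypothesis: object = None
    cluster_ids: list = field(default_factory=list)
    samples: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.A.shape[1]

    @property
    def C(self) -> np.ndarray:
        return self.A + self.B

    @property
    def purity(self) -> np.ndarray:
        """Tumor purity mu_p = 1 - u_{1,p} per sample."""
        return 1.0 - self.U[0]

    @property
    def clone_genome_lengths(self) -> np.ndarray:
        """L_i = sum_s c_{s,i} l_s per clone."""
        return self.C.T @ self.lengths

    @property
    def ploidy(self) -> np.ndarray:
        """rho_p = (1/mu_p) sum_{i>=2} u_{i,p} L_i / L; NaN where mu_p = 0."""
        L = float(self.lengths.sum())
        Li = self.clone_genome_lengths
        mu = self.purity
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = (self.U[1:].T @ Li[1:]) / (mu * L)
        rho[mu <= 0] = np.nan
        return rho

    def dedup_clones(self) -> "Solution":
        """Merge tumor clones with identical state vectors (proportions sum).

        A tumor clone identical to the normal clone merges into it. Keeps D
        unchanged; prevents model selection from double-counting clones.
        """
        cols = {}
        order = []
        for i in range(self.A.shape[1]):
            key = (tuple(self.A[:, i]), tuple(self.B[:, i]))
            if i == 0:
                cols[key] = 0
                order.append(key)
            elif key in cols:
                pass
            else:
                cols[key] = len(order)
                order.append(key)
        if len(order) == self.A.shape[1]:
            return self
        n_new = len(order)
        A = np.zeros((self.A.shape[0], n_new), dtype=self.A.dtype)
        B = np.zeros_like(A)
        U = np.zeros((n_new, self.U.shape[1]))
        for i in range(self.A.shape[1]):
            key = (tuple(self.A[:, i]), tuple(self.B[:, i]))
            j = cols[key]
            A[:, j] = self.A[:, i]
            B[:, j] = self.B[:, i]
            U[j] += self.U[i]
        return Solution(A, B, U, self.D, self.lengths, self.params,
                        self.hypothesis, self.cluster_ids, self.samples)


def objective(FA: np.ndarray, FB: np.ndarray, A: np.ndarray, B: np.ndarray,
              U: np.ndarray, lengths: np.ndarray) -> float:
    """Length-weighted L1 distance D = ||F^A - AU|| + ||F^B - BU||."""
    FA, FB = np.asarray(FA, float), np.asarray(FB, float)
    if FA.shape != FB.shape or A.shape != B.shape:
        raise ValueError("F and copy-number matrices must be conformable")
    if A.shape[0] != FA.shape[0] or U.shape != (A.shape[1], FA.shape[1]):
        raise ValueError("shape mismatch between F, A and U")
    w = np.asarray(lengths, float)
    ra = np.abs(FA - A @ U).sum(axis=1)
    rb = np.abs(FB - B @ U).sum(axis=1)
    return float(w @ (ra + rb))


from functools import lru_cache


@lru_cache(maxsize=32)
def _side_candidates_cached(d: int, c_max: int, theta: int) -> np.ndarray:
    low = np.stack(
        np.meshgrid(*([np.arange(theta + 1)] * d), indexing="ij"), axis=-1
    ).reshape(-1, d)
    high = np.stack(
        np.meshgrid(*([np.arange(theta, c_max + 1)] * d), indexing="ij"), axis=-1
    ).reshape(-1, d)
    # the boxes intersect only at (theta, ..., theta); drop one copy
    keep = ~(low == theta).all(axis=1)
    cand = np.vstack([low[keep], high])
    dist = np.abs(cand - theta).sum(axis=1)
    order = np.lexsort(tuple(cand[:, j] for j in reversed(range(d))) + (dist,))
    out = cand[order]
    out.setflags(write=False)
    return out


def _side_candidates(d: int, c_max: int, theta: int) -> np.ndarray:
    """Integer vectors in [0, theta]^d union [theta, c_max]^d.

    Ordered by (L1 distance from (theta, ..., theta), lexicographic), so a
    first-minimum argmin implements the tie-breaking rule.
    """
    return _side_candidates_cached(d, c_max, theta)


@lru_cache(maxsize=32)
def _lattice_cached(d: int, c_max: int, theta: int):
    c1 = c_max + 1
    lattice = np.stack(
        np.meshgrid(*([np.arange(c1)] * d), indexing="ij"), axis=-1
    ).reshape(-1, d)
    valid = (lattice <= theta).all(axis=1) | (lattice >= theta).all(axis=1)
    lattice.setflags(write=False)
    valid.setflags(write=False)
    return lattice, valid


def _lattice_costs(G: np.ndarray, u_t: np.ndarray, points: np.ndarray) -> np.ndarray:
    """cost[s, j] = sum_p |G[s,p] - points[j] . u_t[:,p]| (unweighted by l)."""
    V = points @ u_t  # (N, k)
    m, k = G.shape
    cost = np.zeros((m, V.shape[0]))
    for p in range(k):
        cost += np.abs(G[:, p][:, None] - V[:, p][None, :])
    return cost


def _prefix_min(val: np.ndarray, shape: tuple) -> np.ndarray:
    """Lower-orthant running minimum over a d-dimensional lattice.

    val has shape (m, prod(shape)); returns M with M[s, flat(cap)] =
    min over lattice points b <= cap (coordinate-wise) of val[s, flat(b)].
    """
    m = val.shape[0]
    v = val.reshape((m,) + shape).copy()
    for ax in range(1, len(shape) + 1):
        np.minimum.accumulate(v, axis=ax, out=v)
    return v.reshape(m, -1)


def _exact_ab_update(GA: np.ndarray, GB: np.ndarray, u_t: np.ndarray,
                     params: DeconvolutionParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact per-cluster minimizer over tumor copy-state vectors.

    GA, GB are the residual targets after subtracting the normal clone's
    contribution; u_t the tumor-clone proportions (d x k). The coupling
    a_i + b_i <= c_max is handled by a prefix-min table over the b lattice.
    """
    d, k = u_t.shape
    c1 = params.c_max + 1
    shape = (c1,) * d
    cand = _side_candidates(d, params.c_max, params.theta)
    cost_a = _lattice_costs(GA, u_t, cand)  # (m, Na)

    lattice, valid = _lattice_cached(d, params.c_max, params.theta)
    cost_b = _lattice_costs(GB, u_t, lattice)
    cost_b[:, ~valid] = np.inf
    M = _prefix_min(cost_b, shape)

    strides = np.array([c1 ** (d - 1 - j) for j in range(d)], dtype=np.int64)
    cap_flat = (params.c_max - cand) @ strides  # (Na,)
    total = cost_a + M[:, cap_flat]  # (m, Na)
    j_star = np.argmin(total, axis=1)  # first minimum: tie rule via ordering
    m = GA.shape[0]
    A_t = cand[j_star]  # (m, d)
    # recover the minimizing b per cluster within its cap box
    B_t = np.empty((m, d), dtype=np.int64)
    for s in range(m):
        cap = params.c_max - A_t[s]
        box = valid & (lattice <= cap).all(axis=1)
        flat = np.flatnonzero(box)
        B_t[s] = lattice[flat[np.argmin(cost_b[s, flat])]]
    return A_t, B_t


def _blockwise_ab_update(GA, GB, u_t, params, A_t, B_t, sweeps: int = 8):
    """Per-clone enumeration fallback for many tumor clones (monotone, local)."""
    d, k = u_t.shape
    pairs = [
        (a, b)
        for a in range(params.c_max + 1)
        for b in range(params.c_max + 1 - a)
    ]
    pairs.sort(key=lambda ab: (abs(ab[0] - params.theta) + abs(ab[1] - params.theta), ab))
    pairs = np.array(pairs)
    for _ in range(sweeps):
        changed = False
        for i in range(d):
            others = [j for j in range(d) if j != i]
            RA = GA - A_t[:, others] @ u_t[others]
            RB = GB - B_t[:, others] @ u_t[others]
            # theta-side bounds imposed by the other clones
            lo_a = np.where((A_t[:, others] > params.theta).any(axis=1), params.theta, 0)
            hi_a = np.where((A_t[:, others] < params.theta).any(axis=1),
                            params.theta, params.c_max)
            lo_b = np.where((B_t[:, others] > params.theta).any(axis=1), params.theta, 0)
            hi_b = np.where((B_t[:, others] < params.theta).any(axis=1),
                            params.theta, params.c_max)
            cost = (
                np.abs(RA[:, None, :] - np.outer(pairs[:, 0], u_t[i])[None]).sum(-1)
                + np.abs(RB[:, None, :] - np.outer(pairs[:, 1], u_t[i])[None]).sum(-1)
            )  # (m, npairs)
            ok = (
                (pairs[None, :, 0] >= lo_a[:, None]) & (pairs[None, :, 0] <= hi_a[:, None])
                & (pairs[None, :, 1] >= lo_b[:, None]) & (pairs[None, :, 1] <= hi_b[:, None])
            )
            cost[~ok] = np.inf
            pick = np.argmin(cost, axis=1)
            new_a, new_b = pairs[pick, 0], pairs[pick, 1]
            if not (np.array_equal(new_a, A_t[:, i]) and np.array_equal(new_b, B_t[:, i])):
                changed = True
            A_t[:, i], B_t[:, i] = new_a, new_b
        if not changed:
            break
    return A_t, B_t


MAX_EXACT_TUMOR_CLONES = 4


def update_copy_numbers(FA: np.ndarray, FB: np.ndarray, U: np.ndarray,
                        lengths: np.ndarray,
                        params: DeconvolutionParams) -> tuple[np.ndarray, np.ndarray]:
    """Minimize D over integer A, B with U fixed.

    The objective separates by cluster; each cluster is solved exactly for
    up to MAX_EXACT_TUMOR_CLONES tumor clones (lattice enumeration with the
    a+b <= c_max coupling handled by a prefix-min table), with a monotone
    per-clone descent fallback beyond that. The normal clone's column is
    fixed at (1, 1).
    """
    FA, FB, U = np.asarray(FA, float), np.asarray(FB, float), np.asarray(U, float)
    m, k = FA.shape
    n = U.shape[0]
    d = n - 1
    u1 = U[0]
    u_t = U[1:]
    GA = FA - u1[None, :]
    GB = FB - u1[None, :]
    if d <= MAX_EXACT_TUMOR_CLONES:
        A_t, B_t = _exact_ab_update(GA, GB, u_t, params)
    else:
        A_t = np.full((m, d), params.theta, dtype=np.int64)
        B_t = np.full((m, d), params.theta, dtype=np.int64)
        exact_d = MAX_EXACT_TUMOR_CLONES
        subA, subB = _exact_ab_update(GA, GB, u_t[:exact_d], params)
        A_t[:, :exact_d] = subA
        B_t[:, :exact_d] = subB
        A_t, B_t = _blockwise_ab_update(GA, GB, u_t, params, A_t, B_t)
    A = np.hstack([np.ones((m, 1), dtype=np.int64), A_t.astype(np.int64)])
    B = np.hstack([np.ones((m, 1), dtype=np.int64), B_t.astype(np.int64)])
    return A, B


def _simplex_l1_lp(fa, fb, Asub, Bsub, lengths, lower):
    """min sum_s l_s(|fa - a.u| + |fb - b.u|) over the simplex with lower
    bounds per proportion; returns (u, value) or None when infeasible."""
    m = len(fa)
    nu = Asub.shape[1]
    I = np.eye(m)
    Z = np.zeros((m, m))
    A_ub = np.block([
        [Asub, -I, Z], [-Asub, -I, Z], [Bsub, Z, -I], [-Bsub, Z, -I],
    ])
    b_ub = np.concatenate([fa, -fa, fb, -fb])
    c = np.concatenate([np.zeros(nu), lengths, lengths])
    A_eq = np.concatenate([np.ones(nu), np.zeros(2 * m)])[None, :]
    bounds = [(lo, 1.0) for lo in lower] + [(0.0, None)] * (2 * m)
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                           bounds=bounds, method="highs")
    if not res.success:
        return None
    return res.x[:nu], float(res.fun)


def _support_lp(fa, fb, A, B, lengths, support, u_min):
    """LP for one sample and one tumor support set; returns (u, value)."""
    cols = [0] + list(support)
    out = _simplex_l1_lp(fa, fb, A[:, cols].astype(float), B[:, cols].astype(float),
                         lengths, [0.0] + [u_min] * (len(cols) - 1))
    if out is None:
        return None
    u = np.zeros(A.shape[1])
    u[cols] = out[0]
    return u, out[1]


def _fast_proportions(FA, FB, A, B, lengths, u_min):
    """Heuristic per-sample update: relaxed LP, then a refit on the support
    surviving the u_min threshold. Cheap but not guaranteed optimal for the
    semi-continuous problem; callers must guard against ascent."""
    m, k = FA.shape
    n = A.shape[1]
    Af, Bf = A.astype(float), B.astype(float)
    U = np.zeros((n, k))
    for p in range(k):
        out = _simplex_l1_lp(FA[:, p], FB[:, p], Af, Bf, lengths, [0.0] * n)
        u = out[0] if out is not None else np.eye(n)[0]
        tum = u[1:]
        if out is not None and ((tum <= 1e-12) | (tum >= u_min - 1e-12)).all():
            # relaxed optimum already satisfies the semi-continuity
            U[:, p] = np.where(np.abs(u) < 1e-12, 0.0, u)
            continue
        support = [i for i in range(1, n) if u[i] >= u_min / 2]
        refit = _support_lp(FA[:, p], FB[:, p], A, B, lengths, support, u_min)
        if refit is None:
            refit = _support_lp(FA[:, p], FB[:, p], A, B, lengths, [], u_min)
        U[:, p] = refit[0]
    return U


def update_proportions(FA: np.ndarray, FB: np.ndarray, A: np.ndarray,
                       B: np.ndarray, lengths: np.ndarray,
                       params: DeconvolutionParams) -> np.ndarray:
    """Minimize D over U with A, B fixed; exact per sample.

    Each sample's problem is a simplex LP with semi-continuous tumor
    proportions (0 or >= u_min); supports are enumerated over all tumor
    subsets and the best LP value wins. The all-normal support is always
    feasible.
    """
    FA, FB = np.asarray(FA, float), np.asarray(FB, float)
    m, k = FA.shape
    n = A.shape[1]
    w = np.asarray(lengths, float)
    U = np.zeros((n, k))
    tumor = list(range(1, n))
    for p in range(k):
        best_u = np.zeros(n)
        best_u[0] = 1.0
        best_val = float(
            w @ (np.abs(FA[:, p] - A[:, 0]) + np.abs(FB[:, p] - B[:, 0]))
        )
        for size in range(1, len(tumor) + 1):
            if size * params.u_min > 1 + 1e-12:
                break
            for support in itertools.combinations(tumor, size):
                out = _support_lp(FA[:, p], FB[:, p], A, B, w, support, params.u_min)
                if out is not None and out[1] < best_val - 1e-12:
                    best_u, best_val = out[0], out[1]
        U[:, p] = best_u
    return U


def _random_u(n: int, k: int, u_min: float, rng: np.random.Generator) -> np.ndarray:
    """Dirichlet(1) columns with tumor entries below u_min zeroed."""
    U = rng.dirichlet(np.ones(n), size=k).T
    U[1:][U[1:] < u_min] = 0.0
    # the normal entry is almost surely positive, so columns renormalize;
    # surviving tumor entries only grow and stay >= u_min
    U /= U.sum(axis=0)[None, :]
    return U


def _random_u_purity(n: int, k: int, u_min: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniform normal proportion, Dirichlet tumor split of the remainder.

    Complements the symmetric Dirichlet draw: purities near 0 or 1 are
    reached far more often, which matters because the normal clone plays a
    special role in the factorization.
    """
    U = np.zeros((n, k))
    for p in range(k):
        u_norm = rng.uniform(0.02, 0.9)
        t = rng.dirichlet(np.ones(n - 1)) * (1 - u_norm)
        t[t < u_min] = 0.0
        col = np.concatenate([[u_norm], t])
        U[:, p] = col / col.sum()
    return U


def _split_seeds(U: np.ndarray, n: int, rng: np.random.Generator) -> list:
    """Seed n-clone inits by splitting each tumor clone of a smaller U."""
    seeds = []
    k = U.shape[1]
    for i in range(1, U.shape[0]):
        for alpha in (0.5, 0.25):
            Unew = np.zeros((n, k))
            Unew[: U.shape[0]] = U
            Unew[U.shape[0]] = alpha * U[i]
            Unew[i] -= Unew[U.shape[0]]
            tot = Unew.sum(axis=0)
            if (tot <= 0).any():
                continue
            seeds.append(Unew / tot[None, :])
    return seeds


def _cd_run(FA, FB, U, w, params, max_iter, tol):
    """One guarded descent: exact A/B update + fast proportion heuristic.

    The fast proportion step is not guaranteed optimal, so any ascent stops
    the run; D is therefore non-increasing along the trajectory.
    """
    prev = np.inf
    A, B = update_copy_numbers(FA, FB, U, w, params)
    best = (A, B, U, objective(FA, FB, A, B, U, w))
    for _ in range(max_iter):
        U2 = _fast_proportions(FA, FB, A, B, w, params.u_min)
        D2 = objective(FA, FB, A, B, U2, w)
        if D2 > best[3]:
            break
        U = U2
        A, B = update_copy_numbers(FA, FB, U, w, params)
        D = objective(FA, FB, A, B, U, w)
        best = (A, B, U, D)
        if prev - D < tol:
            break
        prev = D
    return best


def _polish_exact(FA, FB, A, B, U, w, params, max_iter, tol):
    """Alternate the two exact updates to convergence from a good start."""
    D = objective(FA, FB, A, B, U, w)
    for _ in range(max_iter):
        U2 = update_proportions(FA, FB, A, B, w, params)
        A2, B2 = update_copy_numbers(FA, FB, U2, w, params)
        D2 = objective(FA, FB, A2, B2, U2, w)
        if D2 > D - tol:
            if D2 < D:
                A, B, U, D = A2, B2, U2, D2
            break
        A, B, U, D = A2, B2, U2, D2
    return A, B, U, D


def solve_cacf_cd(FA: np.ndarray, FB: np.ndarray, n: int,
                  params: DeconvolutionParams, lengths: np.ndarray,
                  restarts: int = 20, seed: int = 0, max_iter: int = 50,
                  tol: float = 1e-6, warm_starts: list | None = None,
                  hypothesis=None, cluster_ids=None, samples=None) -> Solution:
    """Coordinate descent over (A, B) and U from multiple restarts.

    Each restart alternates the exact integer copy-number update with a
    proportion update until the objective stops decreasing; the best
    trajectory is then polished with the exact semi-continuous proportion
    update. For n > 2 half of the restart budget is seeded by splitting
    tumor clones of a quickly-fit smaller-n solution (mirroring how
    subclones arise from existing clones); ``warm_starts`` are extra
    initial U matrices tried first. Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least the normal clone plus one tumor clone")
    FA, FB = np.asarray(FA, float), np.asarray(FB, float)
    m, k = FA.shape
    w = np.asarray(lengths, float)
    rng = np.random.default_rng(seed)

    inits = [np.asarray(W, float) for W in (warm_starts or [])]
    n_random = restarts
    if n > 2 and not inits:
        # bootstrap a smaller-n solution and split its clones
        boot = solve_cacf_cd(FA, FB, n - 1, params, w,
                             restarts=max(4, restarts // 4), seed=seed + 1,
                             max_iter=max_iter, tol=tol)
        inits.extend(_split_seeds(boot.U, n, rng)[: restarts // 2])
        n_random = restarts - len(inits)
    for r in range(max(n_random, 1)):
        draw = _random_u_purity if r % 2 else _random_u
        inits.append(draw(n, k, params.u_min, rng))

    best = None
    for U0 in inits:
        if U0.shape != (n, k):
            W = np.zeros((n, k))
            W[: min(U0.shape[0], n)] = U0[:n]
            U0 = W / np.maximum(W.sum(axis=0), 1e-12)[None, :]
        run = _cd_run(FA, FB, U0, w, params, max_iter, tol)
        if run[3] >= tol:
            # escape move: the commonest trap is a tumor clone impersonating
            # the normal; try swapping their proportions and re-descending
            for i in range(1, n):
                Uk = run[2].copy()
                Uk[[0, i]] = Uk[[i, 0]]
                kick = _cd_run(FA, FB, Uk, w, params, max_iter, tol)
                if kick[3] < run[3] - 1e-12:
                    run = kick
                if run[3] < tol:
                    break
        if best is None or run[3] < best[3] - 1e-12:
            best = run
        if best[3] < tol:
            break
    A, B, U, D = _polish_exact(FA, FB, best[0], best[1], best[2], w, params,
                               max_iter, tol)
    sol = Solution(A, B, U, D, w, params, hypothesis,
                   list(cluster_ids or []), list(samples or []))
    return sol.dedup_clones()


# ---------------------------------------------------------------------------
# Exact MILP oracle (small instances)

ILP_GUARD = dict(m=12, n=3, k=3)


def solve_cacf_ilp(FA: np.ndarray, FB: np.ndarray, n: int,
                   params: DeconvolutionParams, lengths: np.ndarray,
                   grid: float = 0.01, force: bool = False,
                   hypothesis=None) -> Solution:
    """Global optimum of D with proportions discretized on a grid.

    Proportions are integer multiples of ``grid``; copy numbers enter the
    bilinear products through a binary (bit) expansion linearized with
    big-M constraints. Intended as a test oracle on small instances; the
    default guard (m <= 12, n <= 3, k <= 3) can be overridden with
    ``force``.
    """
    FA, FB = np.asarray(FA, float), np.asarray(FB, float)
    m, k = FA.shape
    d = n - 1
    if not force and (m > ILP_GUARD["m"] or n > ILP_GUARD["n"] or k > ILP_GUARD["k"]):
        raise ValueError("instance exceeds the ILP oracle guard; pass force=True")
    G = int(round(1.0 / grid))
    gmin = int(np.ceil(params.u_min * G))
    nbits = int(np.ceil(np.log2(params.c_max + 1)))
    w = np.asarray(lengths, float)

    # variable layout
    idx = {}
    nv = 0

    def var(name, count, kind, lb, ub):
        nonlocal nv
        idx[name] = (nv, nv + count, kind, lb, ub)
        nv += count

    var("g", d * k, "int", 0, G)            # tumor proportion numerators
    var("z", d * k, "bin", 0, 1)            # presence indicators
    var("bitA", m * d * nbits, "bin", 0, 1)  # bits of a_{s,i}
    var("bitB", m * d * nbits, "bin", 0, 1)
    var("yA", m * d * k * nbits, "cont", 0, G)  # bit * g products
    var("yB", m * d * k * nbits, "cont", 0, G)
    var("sideA", m, "bin", 0, 1)            # theta-side selectors
    var("sideB", m, "bin", 0, 1)
    var("eA", m * k, "cont", 0, None)       # L1 residuals
    var("eB", m * k, "cont", 0, None)

    def g_i(i, p):
        return idx["g"][0] + i * k + p

    def z_i(i, p):
        return idx["z"][0] + i * k + p

    def bit(name, s, i, t):
        return idx[name][0] + (s * d + i) * nbits + t

    def y_i(name, s, i, p, t):
        return idx[name][0] + ((s * d + i) * k + p) * nbits + t

    def side(name, s):
        return idx[name][0] + s

    def e_i(name, s, p):
        return idx[name][0] + s * k + p

    rows, cols, data, lo, hi = [], [], [], [], []
    nrow = 0

    def add(coeffs, lb, ub):
        nonlocal nrow
        for c_, v_ in coeffs:
            rows.append(nrow); cols.append(c_); data.append(v_)
        lo.append(lb); hi.append(ub)
        nrow += 1

    INF = np.inf
    for p in range(k):
        # proportions sum to at most 1 (normal takes the remainder)
        add([(g_i(i, p), 1.0) for i in range(d)], -INF, G)
        for i in range(d):
            add([(g_i(i, p), 1.0), (z_i(i, p), -gmin)], 0, INF)   # g >= gmin*z
            add([(g_i(i, p), 1.0), (z_i(i, p), -G)], -INF, 0)     # g <= G*z

    for s in range(m):
        for i in range(d):
            for name in ("bitA", "bitB"):
                # value of x_{s,i} from bits is bounded by c_max
                add([(bit(name, s, i, t), float(2 ** t)) for t in range(nbits)],
                    -INF, params.c_max)
            # total copy number a + b <= c_max
            add(
                [(bit("bitA", s, i, t), float(2 ** t)) for t in range(nbits)]
                + [(bit("bitB", s, i, t), float(2 ** t)) for t in range(nbits)],
                -INF, params.c_max,
            )
            # theta-side constraints: side=1 -> x >= theta; side=0 -> x <= theta
            for name, sname in (("bitA", "sideA"), ("bitB", "sideB")):
                add(
                    [(bit(name, s, i, t), float(2 ** t)) for t in range(nbits)]
                    + [(side(sname, s), -float(params.theta))],
                    0, INF,
                )
                add(
                    [(bit(name, s, i, t), float(2 ** t)) for t in range(nbits)]
                    + [(side(sname, s), -float(params.c_max - params.theta))],
                    -INF, float(params.theta),
                )
            for p in range(k):
                for name in ("yA", "yB"):
                    bname = "bitA" if name == "yA" else "bitB"
                    for t in range(nbits):
                        y = y_i(name, s, i, p, t)
                        add([(y, 1.0), (bit(bname, s, i, t), -float(G))], -INF, 0)
                        add([(y, 1.0), (g_i(i, p), -1.0)], -INF, 0)
                        add([(y, 1.0), (g_i(i, p), -1.0),
                             (bit(bname, s, i, t), -float(G))], -float(G), INF)

    # residual constraints: e >= +-(f - predicted); predicted in units of 1/G
    for s in range(m):
        for p in range(k):
            for name, ename, F in (("yA", "eA", FA), ("yB", "eB", FB)):
                pred = [(g_i(i, p), -1.0 / G) for i in range(d)]  # normal: (G - sum g)/G
                for i in range(d):
                    for t in range(nbits):
                        pred.append((y_i(name, s, i, p, t), (2 ** t) / G))
                target = F[s, p] - 1.0
                # e >= target - pred  and  e >= pred - target
                add([(e_i(ename, s, p), 1.0)] + pred, target, INF)
                add([(e_i(ename, s, p), 1.0)] + [(c_, -v_) for c_, v_ in pred],
                    -target, INF)

    c_obj = np.zeros(nv)
    for s in range(m):
        for p in range(k):
            c_obj[e_i("eA", s, p)] = w[s]
            c_obj[e_i("eB", s, p)] = w[s]

    integrality = np.zeros(nv)
    lbv = np.zeros(nv)
    ubv = np.full(nv, np.inf)
    for name, (a0, a1, kind, lb_, ub_) in idx.items():
        if kind in ("int", "bin"):
            integrality[a0:a1] = 1
        lbv[a0:a1] = lb_
        ubv[a0:a1] = np.inf if ub_ is None else ub_

    A_con = sparse.csc_matrix((data, (rows, cols)), shape=(nrow, nv))
    res = optimize.milp(
        c=c_obj,
        constraints=optimize.LinearConstraint(A_con, np.asarray(lo), np.asarray(hi)),
        integrality=integrality,
        bounds=optimize.Bounds(lbv, ubv),
    )
    if res.status != 0:
        raise RuntimeError(f"ILP oracle failed: {res.message}")
    x = res.x
    A = np.ones((m, n), dtype=np.int64)
    B = np.ones((m, n), dtype=np.int64)
    for s in range(m):
        for i in range(d):
            A[s, i + 1] = int(round(sum(2 ** t * x[bit("bitA", s, i, t)]
                                        for t in range(nbits))))
            B[s, i + 1] = int(round(sum(2 ** t * x[bit("bitB", s, i, t)]
                                        for t in range(nbits))))
    U = np.zeros((n, k))
    for p in range(k):
        gs = [x[g_i(i, p)] / G for i in range(d)]
        U[0, p] = 1.0 - sum(gs)
        U[1:, p] = gs
    D = objective(FA, FB, A, B, U, w)
    return Solution(A, B, U, D, w, params, hypothesis)
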