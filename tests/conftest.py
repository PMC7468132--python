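import numpy as np
import pytest

from clonecn.bulk_sim import SimConfig, simulate_patient


@pytest.fixture(scope="session")
def small_patient():
    """A small 3-clone, 2-sample patient used across modules (20 Mb, 30x)."""
    config = SimConfig(n_clones=3, n_samples=2, wgd=False, coverage=30.0,
                       genome_length=20_000_000, seed=42)
    return simulate_patient(config)


@pytest.fixture(scope="session")
def wgd_patient():
    config = SimConfig(n_clones=3, n_samples=2, wgd=True, coverage=30.0,
                       genome_length=20_000_000, seed=43)
    return simulate_patient(config)


def tree_truth(m, n, k, rng, theta=1, c_max=12, u_min=0.03,
               frac_truncal=0.6, frac_branch=0.3):
    """Random valid (A, B, U): clones related by a tree, truncal events
    plus per-branch modifications, with the theta-separation and c_max
    constraints enforced."""
    A = np.ones((m, n), dtype=int)
    B = np.ones((m, n), dtype=int)
    parents = [-1, 0] + [int(rng.integers(1, i)) for i in range(2, n)]
    for i in range(1, n):
        par = parents[i]
        A[:, i], B[:, i] = A[:, par].copy(), B[:, par].copy()
        n_ev = max(1, int((frac_truncal if par == 0 else frac_branch) * m))
        for s in rng.choice(m, size=n_ev, replace=False):
            M = A if rng.random() < 0.5 else B
            delta = 1 if rng.random() < 0.5 else -1
            new = M[s, i] + delta
            if 0 <= new and A[s, i] + B[s, i] + delta <= c_max:
                M[s, i] = new
    for s in range(m):
        for M in (A, B):
            vals = M[s, 1:]
            if (vals > theta).any() and (vals < theta).any():
                vals[vals < theta] = theta
            M[s, 1:] = vals
    U = rng.dirichlet(np.ones(n) * 2, size=k).T
    U[1:][U[1:] < u_min] = 0.0
    U /= U.sum(axis=0)
    return A, B, U
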