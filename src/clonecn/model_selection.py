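"""Joint selection of the number of clones and the WGD hypothesis.

The WGD question is decided first, from the scaled fractional matrices
(see :func:`choose_hypothesis`): the scaling ambiguity lets a diploid
tumor be re-explained as genome-doubled with every state doubled, so fit
quality cannot discriminate — but the doubled re-interpretation uses
only even allele copy numbers, whereas a real WGD genome carries odd
copies from single-copy events around the doubling. The number of clones
is then chosen within the selected hypothesis: increasing n always fits
at least as well, so n stops when the objective reaches the measurement-
noise floor, or at the elbow of the D(n) curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconvolution import DeconvolutionParams, Solution, solve_cacf_cd
from .fractional_scaling import FractionalMatrixPair

__all__ = [
    "ModelGrid",
    "ClusterClassification",
    "choose_hypothesis",
    "build_model_grid",
    "select_solution",
    "classify_clusters",
    "summarize",
]

TAU_ELBOW = 0.05
N_MAX = 6
EPS = 1e-9
#: a fit counts as explaining the data once D is within this factor of the
#: measurement-noise floor estimated by split-half resampling
ADEQUATE_FIT = 1.5
#: minimum subclonal-genome-fraction reduction for the WGD explanation to
#: win outright (and, mirrored, for the no-WGD explanation)
DELTA_S_MARGIN = 0.01
#: minimum genome fraction carrying odd allele copy numbers for a WGD
#: solution to be credible when parsimony ties (a re-interpreted diploid
#: has every state doubled, hence even)
ODD_FRACTION_MIN = 0.15
#: a cluster counts as clonally explained when its summed per-sample L1
#: residual to the best integer state is below this fraction of the
#: clonal lattice spacing per sample
CLONAL_FIT_TOL = 0.25


@dataclass
class ModelGrid:
    """Solutions indexed by (hypothesis name, n) with objective values.

    Within a hypothesis D is non-increasing in n; this is enforced by
    warm-starting the fit at n+1 from the solution at n (new clone cloned
    from the normal with zero proportion). ``floors`` holds the per-
    hypothesis measurement-noise floor of D when available.
    """

    solutions: dict = field(default_factory=dict)  # (name, n) -> Solution
    floors: dict = field(default_factory=dict)     # name -> noise floor

    def hypotheses(self) -> list:
        return sorted({name for name, _ in self.solutions})

    def objectives(self, name: str) -> dict:
        return {n: sol.D for (h, n), sol in self.solutions.items() if h == name}


@dataclass
class ClusterClassification:
    """Sample-level and tumor-level clonality classification per cluster.

    ``sample_clonal`` is a (cluster x sample) boolean frame: True when all
    clones present in the sample share one copy-number state at the
    cluster. ``tumor_clonal`` is per cluster: True when all tumor clones
    share one state regardless of presence.
    """

    sample_clonal: pd.DataFrame
    tumor_clonal: pd.Series


def _clonal_states(c_max: int = 12) -> np.ndarray:
    return np.array([(a, b) for a in range(c_max + 1)
                     for b in range(a + 1) if a + b <= c_max])


def _best_clonal_profile(FA, FB, u1, states):
    """Best single tumor-clonal state per cluster given per-sample normal
    proportions; returns (per-cluster residual summed over samples,
    chosen state per cluster)."""
    tot = states.sum(axis=1)[:, None]
    minor = states[:, 1][:, None]
    mu = (1 - u1)[None, :]
    pf = 2 * u1[None, :] + tot * mu
    pb = u1[None, :] + minor * mu
    pb = np.minimum(pb, pf - pb)
    resid = (
        np.abs(FA[:, None, :] + FB[:, None, :] - pf[None])
        + np.abs(FB[:, None, :] - pb[None])
    ).sum(axis=2)
    j = resid.argmin(axis=1)
    return resid[np.arange(len(FA)), j], states[j]


def _fit_normal_proportion(FA, FB, lengths, states) -> np.ndarray:
    """Per-sample normal proportion by grid search on the clonal misfit,
    normalized by the lattice spacing (the u1 -> 1 limit otherwise wins
    trivially)."""
    m, k = FA.shape
    tot = states.sum(axis=1)
    minor = states[:, 1]
    u_grid = np.arange(0.0, 0.96, 0.01)
    u1 = np.zeros(k)
    for p in range(k):
        best_val = np.inf
        for u in u_grid:
            mu = 1 - u
            pf = 2 * u + tot * mu
            pb = u + minor * mu
            pb = np.minimum(pb, pf - pb)
            r = (
                np.abs(FA[:, p, None] + FB[:, p, None] - pf[None, :])
                + np.abs(FB[:, p, None] - pb[None, :])
            ).min(axis=1)
            val = float((lengths * r).sum()) / max(mu, 0.05)
            if val < best_val:
                best_val, u1[p] = val, u
    return u1


def clonal_explanation(pair: FractionalMatrixPair, lengths: np.ndarray,
                       tol: float = CLONAL_FIT_TOL, c_max: int = 12):
    """Fraction of the genome clonally explained under one hypothesis.

    Each cluster is matched to its best single tumor-clonal state given
    per-sample normal proportions (implied by the anchors for the WGD
    hypothesis, grid-fit for the diploid one); a cluster is "explained"
    when its residual is below ``tol`` lattice spacings per sample.
    Returns (explained fraction, fraction explained by a state with an
    odd allele copy number, normal proportions used).
    """
    states = _clonal_states(c_max)
    k = pair.FA.shape[1]
    if pair.hypothesis.wgd and pair.hypothesis.u_normal is not None:
        u1 = np.asarray(pair.hypothesis.u_normal, float)
    else:
        u1 = _fit_normal_proportion(pair.FA, pair.FB, lengths, states)
    resid, st = _best_clonal_profile(pair.FA, pair.FB, u1, states)
    spacing = float(np.maximum(1 - u1, 0.05).mean())
    ok = resid <= tol * spacing * k
    total = float(lengths.sum())
    explained = float(lengths[ok].sum() / total)
    odd = ok & (((st[:, 0] % 2) == 1) | ((st[:, 1] % 2) == 1))
    odd_frac = float(lengths[odd].sum() / total)
    return explained, odd_frac, u1


def choose_hypothesis(pairs: list, lengths: np.ndarray,
                      odd_min: float = ODD_FRACTION_MIN,
                      tol: float = CLONAL_FIT_TOL) -> FractionalMatrixPair:
    """Decide WGD vs no WGD from the scaled matrices, before factorization.

    A tumor re-interpreted under the wrong hypothesis still explains much
    of its genome clonally (the scaling ambiguity maps diploid solutions
    to doubled ones), so fit quality alone does not discriminate. What
    cannot be faked is parity: the doubled re-interpretation of a diploid
    tumor uses only even allele copy numbers, whereas a genuinely doubled
    genome carries odd copies from single-copy gains/losses around the
    doubling. The WGD hypothesis is accepted only when at least
    ``odd_min`` of the genome is clonally explained by odd-copy states
    under its anchor-implied scaling (threshold calibrated on a simulated
    cohort disjoint from any evaluation seeds).
    """
    by_name = {("WGD" if p.hypothesis.wgd else "noWGD"): p for p in pairs}
    if "WGD" not in by_name:
        return by_name["noWGD"]
    if "noWGD" not in by_name:
        return by_name["WGD"]
    _, odd_frac, _ = clonal_explanation(by_name["WGD"], lengths, tol=tol)
    if odd_frac >= odd_min:
        return by_name["WGD"]
    return by_name["noWGD"]


def _expand_warm_start(sol: Solution, n: int) -> np.ndarray:
    """Pad a solution's U to n clones (new clones absent everywhere)."""
    U = np.zeros((n, sol.U.shape[1]))
    U[: sol.U.shape[0]] = sol.U
    return U


def build_model_grid(
    candidates: list[FractionalMatrixPair],
    lengths: np.ndarray,
    c_max: int = 12,
    u_min: float = 0.03,
    n_max: int = N_MAX,
    tau: float = TAU_ELBOW,
    restarts: int = 8,
    seed: int = 0,
) -> ModelGrid:
    """Fit the factorization for each hypothesis over increasing n.

    n grows from 2 until the elbow criterion is met (one extra n is always
    fit to evaluate it), capped at n_max; the solution at n seeds one warm
    start at n+1, which makes D non-increasing in n.
    """
    grid = ModelGrid()
    for pair in candidates:
        hyp = pair.hypothesis
        name = "WGD" if hyp.wgd else "noWGD"
        theta = 2 if hyp.wgd else 1
        params = DeconvolutionParams(c_max=c_max, u_min=u_min, theta=theta)
        if pair.noise_floor is not None:
            grid.floors[name] = float(pair.noise_floor)
        prev: Solution | None = None
        for n in range(2, n_max + 1):
            warm = [] if prev is None else [_expand_warm_start(prev, n)]
            sol = solve_cacf_cd(
                pair.FA, pair.FB, n, params, lengths,
                restarts=restarts, seed=seed + 97 * n + (1 if hyp.wgd else 0),
                warm_starts=warm, hypothesis=hyp,
                cluster_ids=pair.cluster_ids, samples=pair.samples,
            )
            if prev is not None and sol.D > prev.D:
                # warm start guarantees D(n+1) <= D(n) up to solver jitter
                sol = prev
            grid.solutions[(name, n)] = sol
            floor = grid.floors.get(name)
            if floor is not None and sol.D <= ADEQUATE_FIT * floor:
                break  # fits to within measurement noise; stop adding clones
            if prev is not None:
                rel = (prev.D - sol.D) / max(prev.D, EPS)
                if rel < tau:
                    break
            prev = sol
    return grid


def _hypothesis_n_star(grid: ModelGrid, name: str, tau: float, eps: float,
                       adequate_fit: float = ADEQUATE_FIT) -> int:
    """Smallest n explaining the data to within noise; elbow fallback."""
    objs = grid.objectives(name)
    ns = sorted(objs)
    floor = grid.floors.get(name)
    if floor is not None:
        for n in ns:
            if objs[n] <= adequate_fit * floor:
                return n
    n_star = ns[-1]
    for n in ns[:-1]:
        if n + 1 in objs:
            rel = (objs[n] - objs[n + 1]) / max(objs[n], eps)
            if rel < tau:
                n_star = n
                break
    return n_star


#: clones below this proportion everywhere are ignored by the selection
#: metrics: low-proportion clones frequently absorb residual noise and
#: would otherwise mark the whole genome subclonal
CLONE_METRIC_FLOOR = 0.10


def _subclonal_fraction(solution: Solution,
                        clone_floor: float = CLONE_METRIC_FLOOR) -> float:
    """Genome length share where the major tumor clones disagree."""
    keep = [i for i in range(1, solution.n)
            if solution.U[i].max() >= clone_floor]
    sub = np.zeros(solution.A.shape[0], dtype=bool)
    for s in range(solution.A.shape[0]):
        states = {(solution.A[s, i], solution.B[s, i]) for i in keep}
        sub[s] = len(states) > 1
    return float(solution.lengths[sub].sum() / solution.lengths.sum())


def _odd_state_fraction(solution: Solution,
                        clone_floor: float = CLONE_METRIC_FLOOR) -> float:
    """Genome length share where a major tumor clone has an odd allele
    copy number."""
    odd = np.zeros(solution.A.shape[0], dtype=bool)
    for i in range(1, solution.n):
        if solution.U[i].max() >= clone_floor:
            odd |= (solution.A[:, i] % 2 == 1) | (solution.B[:, i] % 2 == 1)
    return float(solution.lengths[odd].sum() / solution.lengths.sum())


def select_solution(grid: ModelGrid, tau: float = TAU_ELBOW,
                    eps: float = EPS) -> Solution:
    """Pick the simplest adequate solution across hypotheses.

    Per hypothesis, n* is the smallest n whose objective reaches the
    measurement-noise floor, falling back to the elbow rule (smallest n
    whose relative improvement drops below ``tau``). Between the two
    hypotheses the deciding trade-off is subclonal CNAs versus WGD:

    * if the WGD explanation turns a larger genome fraction clonal than
      the diploid one (the subclonal fraction drops by more than
      ``DELTA_S_MARGIN``), the WGD is real — under the wrong diploid
      scaling, segments at odd total copy number can only be explained
      as subclonal mixtures;
    * symmetrically, a WGD explanation that is *more* subclonal than the
      diploid one is rejected;
    * when both explain the genome equally clonally, the parity of the
      WGD solution's states decides: a genuinely doubled genome carries
      the scars of single-copy events before/after the doubling (odd
      allele copy numbers on a fraction >= ``ODD_FRACTION_MIN`` of the
      genome), whereas a re-interpreted diploid tumor has every state
      doubled and therefore even.

    The margins were calibrated once on a simulated cohort separate from
    the evaluation seeds.
    """
    if not grid.solutions:
        raise ValueError("empty model grid")
    per_hyp = {}
    for name in grid.hypotheses():
        n_star = _hypothesis_n_star(grid, name, tau, eps)
        per_hyp[name] = grid.solutions[(name, n_star)]
    if "WGD" not in per_hyp:
        return per_hyp["noWGD"]
    if "noWGD" not in per_hyp:
        return per_hyp["WGD"]
    no_sol, w_sol = per_hyp["noWGD"], per_hyp["WGD"]
    delta_s = _subclonal_fraction(no_sol) - _subclonal_fraction(w_sol)
    if delta_s > DELTA_S_MARGIN:
        return w_sol
    if delta_s < -DELTA_S_MARGIN:
        return no_sol
    if _odd_state_fraction(w_sol) >= ODD_FRACTION_MIN:
        return w_sol
    return no_sol


def classify_clusters(solution: Solution) -> ClusterClassification:
    """Classify clusters by state uniqueness per sample and across clones.

    A cluster is sample-clonal in p iff every tumor clone present in p
    (u_{i,p} > 0) carries the same (a, b) there — the diploid normal is
    background, not a CNA state; it is tumor-clonal iff all tumor clones
    carry one state. Sample-subclonal anywhere implies tumor-subclonal.
    """
    m, n = solution.A.shape
    k = solution.U.shape[1]
    ids = solution.cluster_ids or list(range(m))
    samples = solution.samples or list(range(k))
    sample_clonal = np.ones((m, k), dtype=bool)
    for p in range(k):
        present = np.flatnonzero(solution.U[:, p] > 0)
        present = present[present >= 1]
        for s in range(m):
            states = {(solution.A[s, i], solution.B[s, i]) for i in present}
            sample_clonal[s, p] = len(states) <= 1
    tumor_clonal = np.array([
        len({(solution.A[s, i], solution.B[s, i]) for i in range(1, n)}) <= 1
        for s in range(m)
    ])
    return ClusterClassification(
        pd.DataFrame(sample_clonal, index=ids, columns=samples),
        pd.Series(tumor_clonal, index=ids),
    )


def summarize(solution: Solution) -> pd.DataFrame:
    """Per-sample report: purity, ploidy, WGD flag, subclonal fraction.

    The subclonal fraction is the genomic length share of clusters that
    are sample-subclonal in the sample; clone presence lists the clones
    with positive proportion.
    """
    cls = classify_clusters(solution)
    k = solution.U.shape[1]
    samples = solution.samples or list(range(k))
    lengths = solution.lengths
    total = float(lengths.sum())
    purity = solution.purity
    ploidy = solution.ploidy
    wgd = bool(solution.hypothesis.wgd) if solution.hypothesis is not None else False
    rows = []
    for p, name in enumerate(samples):
        subclonal = float(lengths[~cls.sample_clonal.iloc[:, p].to_numpy()].sum()) / total
        presence = ";".join(
            str(i + 1) for i in range(solution.n) if solution.U[i, p] > 0
        )
        rows.append((name, purity[p], ploidy[p], wgd, solution.n, subclonal, presence))
    return pd.DataFrame(
        rows,
        columns=["SAMPLE", "PURITY", "PLOIDY", "WGD", "N_CLONES",
                 "SUBCLONAL_FRACTION", "CLONES_PRESENT"],
    )
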