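"""Mutation-consistency checks and cancer cell fractions.

A solution (copy-number states plus clone proportions) predicts which
variant-allele frequencies (VAFs) a somatic mutation at a locus can have:
assuming no homoplasy, a mutation occupies 0..x copies of one allele in
each tumor clone, giving the attainable predicted VAFs

    VAF_pred = sum_i ctilde_i u_{i,p} / sum_i c_{s,i} u_{i,p}.

A mutation is "explained" when one of these values falls inside the 95%
equal-tailed credible interval of its observed VAF under a binomial model
with a uniform Beta prior. The cancer cell fraction (CCF) converts a VAF
into the fraction of tumor cells carrying the mutation given a mutation
multiplicity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import Solution
from .genome_model import Bins, MutationTable

__all__ = [
    "MutationAssessment",
    "credible_interval",
    "predicted_vafs",
    "classify_explained",
    "compute_ccf",
]

MIN_VAF_FILTER = 0.2
MAX_ENUMERATION = 10_000
CCF_TOL = 0.2


@dataclass
class MutationAssessment:
    chrom: str
    pos: int
    sample: str
    vaf: float
    ci: tuple
    candidates: np.ndarray
    explained: bool
    ccf: float
    multiplicity: int
    in_summary: bool


def credible_interval(v: int, T: int, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval of Beta(v+1, T-v+1).

    Boundary counts pin the corresponding end of the interval (v = 0 gives
    lo = 0; v = T gives hi = 1).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not 0 <= v <= T:
        raise ValueError("v must be between 0 and T")
    alpha = (1.0 - level) / 2.0
    dist = stats.beta(v + 1, T - v + 1)
    lo = 0.0 if v == 0 else float(dist.ppf(alpha))
    hi = 1.0 if v == T else float(dist.ppf(1.0 - alpha))
    return lo, hi


def predicted_vafs(states: list, u: np.ndarray,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """All attainable predicted VAFs at a locus for one sample.

    ``states`` holds the (a, b) state of the locus in each clone (clone 0
    normal, never mutated); for each allele side and each assignment of
    mutated copies 0..x_i per tumor clone the predicted VAF is computed,
    the all-zero assignment excluded and duplicates collapsed. Assignment
    sets larger than MAX_ENUMERATION per allele are randomly subsampled.
    """
    u = np.asarray(u, float)
    denom = float(sum((a + b) * ui for (a, b), ui in zip(states, u)))
    if denom <= 0:
        raise ValueError("locus totally deleted in this mixture")
    tumor = list(range(1, len(states)))
    out = set()
    for side in (0, 1):
        copies = [states[i][side] for i in tumor]
        sizes = [c + 1 for c in copies]
        n_comb = int(np.prod(sizes))
        if n_comb > MAX_ENUMERATION:
            gen = rng or np.random.default_rng(0)
            assignments = (
                tuple(int(gen.integers(0, c + 1)) for c in copies)
                for _ in range(MAX_ENUMERATION)
            )
        else:
            assignments = itertools.product(*(range(s) for s in sizes))
        for assign in assignments:
            num = float(sum(ct * u[i] for ct, i in zip(assign, tumor)))
            if num > 0:
                out.add(round(num / denom, 12))
    return np.array(sorted(out))


def _locus_states(solution: Solution, cluster_row: int) -> list:
    return [(int(solution.A[cluster_row, i]), int(solution.B[cluster_row, i]))
            for i in range(solution.n)]


def compute_ccf(vaf: float, states: list, u: np.ndarray,
                tol: float = CCF_TOL) -> tuple[float, int]:
    """Cancer cell fraction and the multiplicity used to compute it.

    CCF = VAF (mu c_T + 2(1 - mu)) / (m mu), with c_T the average tumor
    copy number at the locus and m a positive integer multiplicity up to
    the maximum allele copy number in any tumor clone. m is chosen to
    bring the CCF closest to 1 subject to CCF <= 1 + tol; when no m
    satisfies the cap, the m with the smallest CCF is used. The result is
    clipped to [0, 1.5].
    """
    u = np.asarray(u, float)
    mu = float(u[1:].sum())
    if mu <= 0:
        raise ValueError("CCF undefined at zero tumor purity")
    c_tumor = float(sum((a + b) * ui for (a, b), ui in zip(states[1:], u[1:]))) / mu
    m_max = max(max(a, b) for a, b in states[1:])
    m_max = max(m_max, 1)
    factor = vaf * (mu * c_tumor + 2 * (1 - mu)) / mu
    best = None
    for m in range(1, m_max + 1):
        ccf = factor / m
        if ccf <= 1 + tol:
            if best is None or abs(ccf - 1) < abs(best[0] - 1):
                best = (ccf, m)
    if best is None:
        best = (factor / m_max, m_max)
    return float(np.clip(best[0], 0.0, 1.5)), best[1]


def classify_explained(mutations: MutationTable, solution: Solution,
                       bins: Bins, labels: dict,
                       min_vaf: float = MIN_VAF_FILTER,
                       level: float = 0.95) -> pd.DataFrame:
    """Assess every mutation against the solution's predicted VAFs.

    ``labels`` maps bin INDEX -> cluster row of the solution matrices. A
    mutation is explained when some predicted VAF lies inside the credible
    interval of its observed VAF; mutations with observed VAF below
    ``min_vaf`` are kept in the table but flagged out of the summary
    counts. Mutations outside the covered genome are skipped.
    """
    sample_pos = {s: p for p, s in enumerate(solution.samples)} if solution.samples else {}
    rows = []
    for rec in mutations.df.itertuples(index=False):
        bin_id = bins.locate(rec.CHROM, int(rec.POS) - 1)
        if bin_id < 0 or bin_id not in labels:
            continue
        cluster_row = labels[bin_id]
        p = sample_pos.get(rec.SAMPLE, None)
        if p is None:
            continue
        u = solution.U[:, p]
        states = _locus_states(solution, cluster_row)
        T, v = int(rec.TOTAL_READS), int(rec.VAR_READS)
        if T == 0:
            continue
        vaf = v / T
        lo, hi = credible_interval(v, T, level=level)
        try:
            cands = predicted_vafs(states, u)
        except ValueError:
            continue
        explained = bool(((cands >= lo) & (cands <= hi)).any())
        mu = float(u[1:].sum())
        if mu > 0:
            ccf, mult = compute_ccf(vaf, states, u)
        else:
            ccf, mult = np.nan, 0
        rows.append((rec.CHROM, rec.POS, rec.SAMPLE, vaf, lo, hi, explained,
                     ccf, mult, vaf >= min_vaf))
    return pd.DataFrame(
        rows,
        columns=["CHROM", "POS", "SAMPLE", "VAF", "CI_LO", "CI_HI",
                 "EXPLAINED", "CCF", "MULTIPLICITY", "IN_SUMMARY"],
    )


def explained_summary(assessment: pd.DataFrame) -> dict:
    """Counts of explained/unexplained mutations above the VAF filter."""
    kept = assessment[assessment["IN_SUMMARY"]]
    return {
        "n_assessed": int(len(kept)),
        "n_explained": int(kept["EXPLAINED"].sum()),
        "fraction_explained": float(kept["EXPLAINED"].mean()) if len(kept) else np.nan,
    }
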