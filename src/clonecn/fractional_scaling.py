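"""Scaling cluster RDR/BAF into allele-specific fractional copy numbers.

The fractional copy number of a cluster in a sample, f_{s,p} = sum_i
c_{s,i} u_{i,p}, is proportional to its RDR with an unknown per-sample
constant. The constant is identified from anchor clusters whose total copy
number is the same in every tumor clone:

* no WGD — a cluster with state (1,1) in all clones (balanced BAF, largest
  such cluster), giving gamma_p = 2 / r_{anchor,p};
* WGD — the balanced cluster is reinterpreted as (2,2) and a second clonal
  cluster with a distinct known total omega is found; the per-sample pair
  (gamma_p, u_{1,p}) then solves a 2x2 linear system, which is non-singular
  exactly when r_{s',p} (omega_z - 2) != r_{z',p} (omega_s' - 2).

Both hypotheses are produced and carried forward; choosing between them is
deferred to model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .global_cluster import ClusterAssignment, TOL_BAF

__all__ = [
    "ScalingHypothesis",
    "FractionalMatrixPair",
    "InfeasibleHypothesis",
    "find_diploid_anchor",
    "find_second_anchor",
    "scale_to_fractional",
    "candidate_hypotheses",
]

#: clonal states reachable by one single-copy gain/loss before or after a WGD
WGD_CANDIDATE_STATES = [(2, 0), (2, 1), (3, 2), (4, 2), (3, 1), (4, 3)]

#: minimum genomic fraction for a cluster considered as a WGD second anchor
MIN_ANCHOR_FRACTION = 0.02


class InfeasibleHypothesis(RuntimeError):
    """Raised when no valid anchor set exists for a scaling hypothesis."""


@dataclass(frozen=True)
class ScalingHypothesis:
    """Anchor clusters and per-sample scale factors for one WGD hypothesis."""

    wgd: bool
    anchor1: int
    omega1: int
    gamma: np.ndarray  # per-sample RDR -> fractional-copy-number factor
    anchor2: int | None = None
    omega2: int | None = None
    u_normal: np.ndarray | None = None  # implied normal proportion (WGD only)

    def __post_init__(self) -> None:
        if not self.wgd and (self.omega1 != 2 or self.anchor2 is not None):
            raise ValueError("no-WGD hypothesis must anchor a diploid cluster only")
        if (np.asarray(self.gamma) <= 0).any():
            raise ValueError("gamma must be positive")


@dataclass
class FractionalMatrixPair:
    """Allele-specific fractional copy numbers F^A, F^B under one hypothesis.

    ``sigma_FA``/``sigma_FB`` are per-entry standard-error estimates of the
    scaled values, propagated from the read counts behind each cluster
    centroid; ``noise_floor`` is the expected length-weighted L1 distance
    between the estimated F and its noise-free value — the D level at which
    a factorization fits the data to within measurement error.
    """

    FA: np.ndarray
    FB: np.ndarray
    hypothesis: ScalingHypothesis
    cluster_ids: list = field(default_factory=list)
    samples: list = field(default_factory=list)
    sigma_FA: np.ndarray | None = None
    sigma_FB: np.ndarray | None = None
    noise_floor: float | None = None

    def __post_init__(self) -> None:
        if self.FA.shape != self.FB.shape:
            raise ValueError("FA and FB must be conformable")
        if (self.FA < -1e-9).any() or (self.FB < -1e-9).any():
            raise ValueError("fractional copy numbers must be non-negative")
        if (self.FB > self.FA + 1e-9).any():
            raise ValueError("F^B must not exceed F^A (minor-allele convention)")

    @property
    def F(self) -> np.ndarray:
        return self.FA + self.FB


def find_diploid_anchor(clusters: ClusterAssignment, tol_baf: float = TOL_BAF) -> int:
    """Largest cluster with balanced BAF (within tol of 0.5) in all samples."""
    _, Beta, lengths, ids, _ = clusters.matrices()
    balanced = (np.abs(Beta - 0.5) <= tol_baf).all(axis=1)
    if not balanced.any():
        raise InfeasibleHypothesis("no balanced clonal cluster")
    j = int(np.flatnonzero(balanced)[np.argmax(lengths[balanced])])
    return ids[j]


def _wgd_fit(r_anchor: np.ndarray, r_z: np.ndarray, omega_z: int):
    """Solve gamma_p r_anchor = 2u + 4(1-u), gamma_p r_z = 2u + omega_z(1-u).

    Returns (gamma, u_normal) arrays or None when the system is singular or
    the solution is out of range in any sample.
    """
    # gamma * r1 + 2 u = 4 ; gamma * r2 + (omega_z - 2) u = omega_z
    det = r_anchor * (omega_z - 2) - r_z * 2
    if np.any(np.isclose(det, 0.0, atol=1e-12)):
        return None
    gamma = (4 * (omega_z - 2) - 2 * omega_z) / det
    u = (4 * r_z - omega_z * r_anchor) / -det
    if np.any(gamma <= 0) or np.any(u < -1e-9) or np.any(u > 1 + 1e-9):
        return None
    return gamma, np.clip(u, 0.0, 1.0)


def _ordering_preserved(R: np.ndarray, Beta: np.ndarray, z: int,
                        large: np.ndarray, tol: float = 0.02) -> bool:
    """Check that cluster z keeps its RDR/BAF ordering vs other large clusters.

    A clonal cluster's position relative to other clusters cannot flip
    between samples; a flip indicates a sample-dependent (subclonal) state.
    """
    for t in np.flatnonzero(large):
        if t == z:
            continue
        dr = R[z] - R[t]
        if not ((dr > -tol).all() or (dr < tol).all()):
            return False
        db = Beta[z] - Beta[t]
        if not ((db > -2 * tol).all() or (db < 2 * tol).all()):
            return False
    return True


def _clonal_fit_score(R, Beta, lengths, gamma, u1, c_max: int = 12) -> float:
    """Length-weighted misfit of all clusters to the nearest clonal state.

    Under a candidate scaling (gamma_p, u_{1,p}) a clonal cluster with
    state (a, b) in every tumor clone predicts f = 2 u1 + (a+b)(1 - u1)
    and minor f^B = u1 + b (1 - u1) per sample. The score sums, over
    clusters and samples, the smallest L1 residual over integer states,
    normalized by the lattice spacing (1 - u1) of the sample — without
    the normalization a candidate implying purity near zero makes its
    lattice arbitrarily fine and trivially "fits" everything.
    """
    states = np.array([(a, b) for a in range(c_max + 1)
                       for b in range(a + 1) if a + b <= c_max])
    tot = states.sum(axis=1)[:, None]  # (S, 1)
    minor = states[:, 1][:, None]
    F = gamma[None, :] * R  # (m, k)
    FBm = Beta * F
    mu = (1 - u1)[None, :]
    pred_f = 2 * u1[None, :] + tot[:, :] * mu      # (S, k)
    pred_b = u1[None, :] + minor * mu
    spacing = np.maximum(1 - u1, 0.05)[None, None, :]
    resid = ((
        np.abs(F[:, None, :] - pred_f[None, :, :])
        + np.abs(FBm[:, None, :] - np.minimum(pred_b, pred_f - pred_b)[None, :, :])
    ) / spacing).sum(axis=2)  # (m, S)
    return float((lengths * resid.min(axis=1)).sum())


def find_second_anchor(clusters: ClusterAssignment, diploid_anchor: int,
                       tol_baf: float = TOL_BAF,
                       min_fraction: float = MIN_ANCHOR_FRACTION):
    """Find the WGD second anchor and its total copy number omega.

    The balanced anchor is reinterpreted as (2,2) (omega=4). For every
    large cluster whose RDR/BAF ordering against the anchor is preserved
    across samples, each candidate clonal state from
    ``WGD_CANDIDATE_STATES`` defines, via the 2x2 scaling system, a
    per-sample (gamma, normal proportion); candidates are ranked by how
    well that scaling places the whole genome on the clonal integer
    lattice (see :func:`_clonal_fit_score`), after a per-cluster BAF
    consistency pre-filter. A subclonal impostor cluster solves its own
    system but scatters the rest of the genome off the lattice, which
    this genome-wide score penalizes.

    Returns (cluster id, 4, omega). Raises InfeasibleHypothesis when no
    candidate satisfies the Theorem-1 non-singularity condition with an
    acceptable fit.
    """
    R, Beta, lengths, ids, _ = clusters.matrices()
    a_pos = ids.index(diploid_anchor)
    r_anchor = R[a_pos]
    large = lengths >= min_fraction * lengths.sum()
    best = None  # (score, |omega-4|, -length), cluster, omega
    anchor_only = np.zeros(len(ids), dtype=bool)
    anchor_only[a_pos] = True
    for z_pos, cid in enumerate(ids):
        if cid == diploid_anchor or not large[z_pos]:
            continue
        # a clonal candidate cannot flip its position vs the clonal anchor
        if not _ordering_preserved(R, Beta, z_pos, anchor_only):
            continue
        for (xa, xb) in WGD_CANDIDATE_STATES:
            omega = xa + xb
            fit = _wgd_fit(r_anchor, R[z_pos], omega)
            if fit is None:
                continue
            gamma, u = fit
            f_total = 2 * u + omega * (1 - u)
            f_minor = u + xb * (1 - u)
            beta_pred = np.minimum(f_minor, f_total - f_minor) / f_total
            rms = float(np.sqrt(np.mean((beta_pred - Beta[z_pos]) ** 2)))
            if rms > tol_baf:
                continue
            score = _clonal_fit_score(R, Beta, lengths, gamma, u)
            key = (score, abs(omega - 4), -lengths[z_pos])
            if best is None or key < best[0]:
                best = (key, cid, omega)
    if best is None:
        raise InfeasibleHypothesis("no WGD second anchor candidate")
    return best[1], 4, best[2]


def scale_to_fractional(clusters: ClusterAssignment,
                        hypothesis: ScalingHypothesis) -> FractionalMatrixPair:
    """Apply the per-sample scale factors: f = gamma_p * r, split by BAF.

    Count-noise standard errors of the centroids are propagated through
    the scaling so downstream model selection can judge fits against the
    measurement-noise floor on the same scale as D.
    """
    R, Beta, lengths, ids, samples = clusters.matrices()
    gamma = np.asarray(hypothesis.gamma, dtype=float)
    if gamma.shape != (R.shape[1],):
        raise ValueError("gamma must have one entry per sample")
    F = gamma[None, :] * R
    FB = Beta * F
    FA = F - FB
    if (F < -1e-9).any():
        raise InfeasibleHypothesis("negative fractional copy numbers")

    cent = clusters.centroids
    piv = lambda col: (
        cent.pivot(index="CLUSTER", columns="SAMPLE", values=col)
        .loc[ids, samples].to_numpy(dtype=float)
    )
    tum = np.maximum(piv("BIN_READS"), 1.0)
    norm = piv("NORM_READS") if "NORM_READS" in cent.columns else tum
    norm = np.maximum(norm, 1.0)
    snp = np.maximum(piv("SNP_READS"), 1.0)
    sigma_r = R * np.sqrt(1.0 / tum + 1.0 / norm)
    # the folded-moment BAF estimator runs ~1.5x above the binomial error
    sigma_b = 1.5 * 0.5 / np.sqrt(snp)
    sigma_fa = np.sqrt(((1 - Beta) * gamma * sigma_r) ** 2 + (F * sigma_b) ** 2)
    sigma_fb = np.sqrt((Beta * gamma * sigma_r) ** 2 + (F * sigma_b) ** 2)
    # E|N(0, sigma)| = sqrt(2/pi) sigma summed with the length weights
    floor = float(np.sqrt(2 / np.pi) * (lengths[:, None] * (sigma_fa + sigma_fb)).sum())
    return FractionalMatrixPair(FA, np.minimum(FB, FA), hypothesis,
                                cluster_ids=list(ids), samples=list(samples),
                                sigma_FA=sigma_fa, sigma_FB=sigma_fb,
                                noise_floor=floor)


def hypothesis_no_wgd(clusters: ClusterAssignment,
                      tol_baf: float = TOL_BAF) -> ScalingHypothesis:
    """No-WGD hypothesis: diploid anchor gives gamma_p = 2 / r_{anchor,p}."""
    anchor = find_diploid_anchor(clusters, tol_baf=tol_baf)
    R, _, _, ids, _ = clusters.matrices()
    r_anchor = R[ids.index(anchor)]
    if np.any(r_anchor <= 0):
        raise InfeasibleHypothesis("diploid anchor has zero RDR in a sample")
    return ScalingHypothesis(wgd=False, anchor1=anchor, omega1=2,
                             gamma=2.0 / r_anchor)


def hypothesis_wgd(clusters: ClusterAssignment,
                   tol_baf: float = TOL_BAF) -> ScalingHypothesis:
    """WGD hypothesis: balanced anchor as (2,2) plus a second clonal anchor."""
    anchor = find_diploid_anchor(clusters, tol_baf=tol_baf)
    z, omega1, omega2 = find_second_anchor(clusters, anchor, tol_baf=tol_baf)
    R, _, _, ids, _ = clusters.matrices()
    fit = _wgd_fit(R[ids.index(anchor)], R[ids.index(z)], omega2)
    if fit is None:
        raise InfeasibleHypothesis("WGD scaling system infeasible")
    gamma, u = fit
    return ScalingHypothesis(wgd=True, anchor1=anchor, omega1=omega1,
                             gamma=gamma, anchor2=z, omega2=omega2, u_normal=u)


def candidate_hypotheses(clusters: ClusterAssignment,
                         tol_baf: float = TOL_BAF) -> list[FractionalMatrixPair]:
    """Both scaled fractional matrices; an infeasible WGD case is dropped."""
    out = [scale_to_fractional(clusters, hypothesis_no_wgd(clusters, tol_baf))]
    try:
        out.append(scale_to_fractional(clusters, hypothesis_wgd(clusters, tol_baf)))
    except InfeasibleHypothesis:
        pass
    return out
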