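"""Global clustering of bins by (RDR, BAF) jointly across samples.

Bins with the same copy-number state in every tumor clone have the same
expected RDR and BAF in every sample, wherever they sit on the genome.
Clustering therefore acts on the 2k-dimensional feature vector of each bin
(RDR and BAF in each of the k samples) with a Dirichlet-process Gaussian
mixture, rather than on local segmentation along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import BayesianGaussianMixture

from .genome_model import Bins
from .rdr_baf import SignalTable, pool_signals

__all__ = ["ClusterAssignment", "cluster_bins", "merge_clusters"]

MAX_COMPONENTS = 50
CONCENTRATION_PRIOR = 0.01
N_RESTARTS = 10
TOL_R = 0.08
TOL_BAF = 0.04
MIN_CLUSTER_FRACTION = 0.001


@dataclass
class ClusterAssignment:
    """Bin labels plus per-(cluster, sample) centroids and genomic lengths.

    ``labels`` maps bin INDEX -> cluster id for every clustered bin;
    ``centroids`` has columns CLUSTER/SAMPLE/RDR/BAF/SNP_READS/BIN_READS/
    LENGTH (one row per cluster per sample); ``lengths`` maps cluster id ->
    summed member-bin length.
    """

    labels: dict
    centroids: pd.DataFrame
    lengths: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = (
            self.centroids.drop_duplicates("CLUSTER").set_index("CLUSTER")["LENGTH"]
        )
        if (self.lengths <= 0).any():
            raise ValueError("cluster with non-positive genomic length")

    @property
    def cluster_ids(self) -> list:
        return sorted(self.lengths.index)

    @property
    def samples(self) -> list:
        return sorted(self.centroids["SAMPLE"].unique())

    def matrices(self):
        """Return (R, Beta, lengths, cluster_ids, samples) as dense arrays."""
        ids = self.cluster_ids
        samples = self.samples
        R = (
            self.centroids.pivot(index="CLUSTER", columns="SAMPLE", values="RDR")
            .loc[ids, samples]
            .to_numpy()
        )
        Beta = (
            self.centroids.pivot(index="CLUSTER", columns="SAMPLE", values="BAF")
            .loc[ids, samples]
            .to_numpy()
        )
        lengths = self.lengths.loc[ids].to_numpy(dtype=float)
        return R, Beta, lengths, ids, samples


def _features(signals: SignalTable) -> tuple[np.ndarray, np.ndarray]:
    """Wide (n_bins, 2k) feature matrix of z-scored RDR/BAF per sample."""
    df = signals.unmasked()
    wide_r = df.pivot(index="BIN", columns="SAMPLE", values="RDR")
    wide_b = df.pivot(index="BIN", columns="SAMPLE", values="BAF")
    # a bin must be unmasked in every sample to be clustered
    keep = wide_r.notna().all(axis=1) & wide_b.notna().all(axis=1)
    wide_r, wide_b = wide_r[keep], wide_b[keep]
    X = np.hstack([wide_r.to_numpy(), wide_b.to_numpy()])
    return X, wide_r.index.to_numpy()


def cluster_bins(signals: SignalTable, bins: Bins,
                 max_components: int = MAX_COMPONENTS,
                 seed: int = 0,
                 n_restarts: int = N_RESTARTS,
                 min_cluster_fraction: float = MIN_CLUSTER_FRACTION) -> ClusterAssignment:
    """Fit a DP Gaussian mixture (diagonal covariance) on all bins jointly.

    Features are standardized per column before the fit; labels are the MAP
    assignment; empty components are dropped. Clusters whose genomic length
    is below ``min_cluster_fraction`` of the clustered genome are dissolved
    into the nearest surviving centroid. Deterministic given ``seed``.
    """
    if not signals.samples:
        raise ValueError("no samples in signal table")
    X, bin_ids = _features(signals)
    if len(X) == 0:
        raise ValueError("all bins masked; nothing to cluster")
    n_comp = int(min(max_components, len(X)))
    mu = X.mean(axis=0)
    # floor the scale: near-constant features must not have their noise
    # amplified to unit variance by the standardization
    sd = np.maximum(X.std(axis=0), 0.02)
    Z = (X - mu) / sd
    model = BayesianGaussianMixture(
        n_components=n_comp,
        covariance_type="diag",
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=CONCENTRATION_PRIOR,
        n_init=n_restarts,
        max_iter=300,
        random_state=seed,
    )
    raw = model.fit_predict(Z)
    labels_arr = _relabel(raw)
    labels = dict(zip(bin_ids.tolist(), labels_arr.tolist()))
    centroids = pool_signals(signals, labels, bins)
    assignment = ClusterAssignment(labels, centroids)
    return _dissolve_small(assignment, signals, bins, min_cluster_fraction)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Compact labels to 0..m-1 preserving first-appearance order."""
    uniq = pd.unique(labels)
    remap = {int(v): i for i, v in enumerate(uniq)}
    return np.asarray([remap[int(v)] for v in labels])


def _dissolve_small(assignment: ClusterAssignment, signals: SignalTable,
                    bins: Bins, min_fraction: float) -> ClusterAssignment:
    """Reassign bins of clusters below the length floor to nearest centroid."""
    total = assignment.lengths.sum()
    small = assignment.lengths[assignment.lengths < min_fraction * total].index
    if len(small) == 0 or len(small) == len(assignment.lengths):
        return assignment
    R, Beta, _, ids, samples = assignment.matrices()
    keep_pos = [j for j, cid in enumerate(ids) if cid not in set(small)]
    kept_ids = [ids[j] for j in keep_pos]
    df = signals.unmasked()
    wide_r = df.pivot(index="BIN", columns="SAMPLE", values="RDR")[samples]
    wide_b = df.pivot(index="BIN", columns="SAMPLE", values="BAF")[samples]
    feats = np.hstack([wide_r.to_numpy(), wide_b.to_numpy()])
    cent = np.hstack([R[keep_pos], Beta[keep_pos]])
    labels = dict(assignment.labels)
    for bin_id, lab in assignment.labels.items():
        if lab in set(small):
            row = feats[wide_r.index.get_loc(bin_id)]
            labels[bin_id] = kept_ids[int(np.argmin(np.abs(cent - row).sum(axis=1)))]
    labels_arr = _relabel(np.asarray([labels[b] for b in sorted(labels)]))
    labels = dict(zip(sorted(labels), labels_arr.tolist()))
    centroids = pool_signals(signals, labels, bins)
    return ClusterAssignment(labels, centroids)


def merge_clusters(assignment: ClusterAssignment, signals: SignalTable,
                   bins: Bins, tol_r: float = TOL_R,
                   tol_baf: float = TOL_BAF) -> ClusterAssignment:
    """Iteratively merge cluster pairs indistinguishable in every sample.

    A pair qualifies when centroid RDRs differ by < tol_r and BAFs by
    < tol_baf in every sample; the closest qualifying pair (by worst-sample
    normalized gap) merges first, and centroids are re-pooled after each
    merge, until no pair qualifies.
    """
    if tol_r < 0 or tol_baf < 0:
        raise ValueError("tolerances must be non-negative")
    labels = dict(assignment.labels)
    while True:
        centroids = pool_signals(signals, labels, bins)
        current = ClusterAssignment(labels, centroids)
        R, Beta, _, ids, _ = current.matrices()
        m = len(ids)
        best, best_gap = None, np.inf
        for a in range(m):
            for b in range(a + 1, m):
                dr = np.abs(R[a] - R[b])
                db = np.abs(Beta[a] - Beta[b])
                if (dr < tol_r).all() and (db < tol_baf).all():
                    gap = max(dr.max() / max(tol_r, 1e-12),
                              db.max() / max(tol_baf, 1e-12))
                    if gap < best_gap:
                        best, best_gap = (ids[a], ids[b]), gap
        if best is None:
            return current
        keep, drop = best
        for bin_id, lab in labels.items():
            if lab == drop:
                labels[bin_id] = keep
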