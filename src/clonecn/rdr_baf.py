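"""Per-bin read-depth ratios and mirrored B-allele frequencies.

The read-depth ratio (RDR) of a bin in a tumor sample is the tumor read
share of the bin divided by its matched-normal read share; it is directly
proportional to the bin's fractional copy number. The B-allele frequency
(BAF) is the pooled minor-allele read fraction over the heterozygous
germline SNPs in the bin, mirrored into [0, 0.5]. Because the minor allele
is unknown per SNP, naive min(ref, alt) pooling biases the estimate
downward near balanced bins; a two-component binomial EM assigns each SNP's
"B side" before pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import BinCountTable, Bins, SNPCountTable

__all__ = ["BinSignal", "SignalTable", "compute_rdr", "compute_baf", "pool_signals"]

MIN_SNPS_PER_BIN = 5
EM_ITERATIONS = 20


@dataclass(frozen=True)
class BinSignal:
    """RDR and mirrored BAF of one (bin, sample) with supporting counts."""

    r: float
    beta: float
    snp_reads: int
    bin_reads: int


@dataclass
class SignalTable:
    """Long-format per-(bin, sample) signals with a MASKED flag.

    Columns: BIN, SAMPLE, RDR, BAF, SNP_READS, B_READS, BIN_READS, MASKED.
    B_READS is the pooled count on the EM-assigned minor side, kept so that
    cluster-level BAFs can be re-pooled from raw counts.
    """

    df: pd.DataFrame
    samples: list
    #: per-SNP counts with BIN assignment, kept so cluster-level BAFs can be
    #: re-estimated from raw counts (the per-bin mirrored estimate is biased
    #: low near 0.5 by the folding; at cluster depth the bias is negligible)
    snp_df: pd.DataFrame | None = None

    def unmasked(self) -> pd.DataFrame:
        return self.df[~self.df["MASKED"]]


def compute_rdr(counts: BinCountTable, bins: Bins | None = None,
                correction: np.ndarray | None = None) -> pd.DataFrame:
    """RDR per (bin, sample): (tumor share of bin) / (normal share of bin).

    Bins with zero normal coverage are flagged MASKED instead of propagating
    NaN. ``correction`` is an optional per-bin multiplicative factor (e.g. a
    GC/mappability correction) applied to the tumor share, indexed like the
    bin order of ``counts``.
    """
    df = counts.df.copy()
    totals = counts.tumor_totals
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"samples with no tumor reads: {bad}")
    normal_total = counts.normal_total
    if normal_total <= 0:
        raise ValueError("normal sample has no reads")
    tumor_share = df["TUMOR_READS"] / df["SAMPLE"].map(totals)
    normal_share = df["NORMAL_READS"] / normal_total
    with np.errstate(divide="ignore", invalid="ignore"):
        rdr = (tumor_share / normal_share).to_numpy()
    if correction is not None:
        key = df.groupby(["CHROM", "START", "END"], sort=False).ngroup().to_numpy()
        rdr = rdr * np.asarray(correction)[key]
    out = df[["CHROM", "START", "END", "SAMPLE"]].copy()
    out["RDR"] = rdr
    out["BIN_READS"] = df["TUMOR_READS"]
    out["NORM_READS"] = df["NORMAL_READS"]
    out["MASKED"] = ~np.isfinite(rdr)
    out.loc[out["MASKED"], "RDR"] = 0.0
    return out


def _em_minor_fraction(ref: np.ndarray, alt: np.ndarray,
                       iterations: int = EM_ITERATIONS) -> tuple[float, np.ndarray]:
    """Two-component binomial EM for the shared minor-allele fraction.

    Each SNP's alt allele either is the bin's minor allele (probability beta
    of a read) or is the major allele (probability 1 - beta). Returns the
    mirrored fraction and the pooled minor-side read count per SNP.
    Initialized from min-side pooling; fixed 50/50 prior on the side.
    """
    total = ref + alt
    T = total.sum()
    if T == 0:
        return np.nan, np.zeros_like(ref, dtype=float)
    beta = min(np.minimum(ref, alt).sum() / T, 0.5)
    for _ in range(iterations):
        b = np.clip(beta, 1e-6, 0.5)
        # log-likelihood ratio of "alt is minor" vs "ref is minor"
        llr = (alt - ref) * (np.log(b) - np.log1p(-b))
        gamma = 1.0 / (1.0 + np.exp(-llr))
        minor_reads = gamma * alt + (1.0 - gamma) * ref
        beta = min(minor_reads.sum() / T, 0.5)
    b = np.clip(beta, 1e-6, 0.5)
    llr = (alt - ref) * (np.log(b) - np.log1p(-b))
    gamma = 1.0 / (1.0 + np.exp(-llr))
    minor = gamma * alt + (1.0 - gamma) * ref
    return beta, minor


def folded_moment_baf(ref: np.ndarray, alt: np.ndarray) -> float:
    """Mirrored BAF via an unbiased moment estimator of (beta - 1/2)^2.

    For counts alt_j ~ Binom(T_j, p_j) with p_j = beta or 1 - beta per SNP,
    E[(alt - T/2)^2 - T/4] = T(T-1) (beta - 1/2)^2 regardless of the side,
    so the pooled ratio estimates the squared imbalance without assigning
    sides. This avoids the vanishing-information pathology of the folded
    mixture likelihood at beta = 1/2 (where the EM estimate is biased low
    at any depth). Estimates within twice the null standard error of zero
    imbalance snap to exactly 0.5.
    """
    ref = np.asarray(ref, float)
    alt = np.asarray(alt, float)
    T = ref + alt
    ok = T > 1
    if ok.sum() == 0:
        return float("nan")
    x = (alt[ok] - T[ok] / 2) ** 2 - T[ok] / 4
    denom = float((T[ok] * (T[ok] - 1)).sum())
    d2 = float(x.sum()) / denom
    if len(x) > 1:
        se = float(x.std(ddof=1)) * np.sqrt(len(x)) / denom
        if d2 < 2 * se:
            return 0.5
    delta = np.sqrt(min(max(d2, 0.0), 0.25))
    return float(0.5 - delta)


def compute_baf(snps: SNPCountTable, bins: Bins,
                min_snps_per_bin: int = MIN_SNPS_PER_BIN) -> pd.DataFrame:
    """Mirrored BAF per (bin, sample) via per-bin binomial EM phase pooling.

    Bins with fewer than ``min_snps_per_bin`` covered SNPs are masked.
    """
    assigned = snps.assign_bins(bins)
    assigned = assigned[assigned["BIN"] >= 0]
    rows = []
    for (bin_id, sample), grp in assigned.groupby(["BIN", "SAMPLE"], sort=False):
        ref = grp["REF_READS"].to_numpy(dtype=float)
        alt = grp["ALT_READS"].to_numpy(dtype=float)
        covered = (ref + alt) > 0
        n_snps = int(covered.sum())
        if n_snps < min_snps_per_bin:
            rows.append((bin_id, sample, 0.0, 0, 0.0, True))
            continue
        beta, minor = _em_minor_fraction(ref[covered], alt[covered])
        total = int((ref[covered] + alt[covered]).sum())
        rows.append((bin_id, sample, beta, total, float(minor.sum()), False))
    return pd.DataFrame(
        rows, columns=["BIN", "SAMPLE", "BAF", "SNP_READS", "B_READS", "MASKED"]
    )


def build_signals(counts: BinCountTable, snps: SNPCountTable, bins: Bins,
                  min_snps_per_bin: int = MIN_SNPS_PER_BIN) -> SignalTable:
    """Join RDR and BAF into one per-(bin, sample) signal table.

    A (bin, sample) is masked if either signal is masked; non-autosomal bins
    are masked as well.

    The SNPs of each bin are split into two interleaved halves: per-bin BAF
    features (used for clustering) come from one half, while the other half
    is held out for cluster-level re-estimation in :func:`pool_signals`.
    Mirrored BAF estimates of balanced bins carry one-sided folding noise;
    without the held-out half, clusters formed by chasing that noise would
    have their biased centroids confirmed by the very SNPs that created
    them.
    """
    rdr = compute_rdr(counts, bins)
    key = bins.df.set_index(["CHROM", "START", "END"])["INDEX"]
    rdr["BIN"] = rdr.set_index(["CHROM", "START", "END"]).index.map(key).to_numpy()
    assigned_all = snps.assign_bins(bins)
    assigned_all = assigned_all[assigned_all["BIN"] >= 0].reset_index(drop=True)
    half = assigned_all.groupby(["BIN", "SAMPLE"], sort=False).cumcount() % 2
    feature_half = SNPCountTable(
        assigned_all[half == 0].drop(columns="BIN").reset_index(drop=True)
    )
    holdout_half = assigned_all[half == 1].reset_index(drop=True)
    baf = compute_baf(feature_half, bins, min_snps_per_bin=min_snps_per_bin)
    df = rdr.merge(baf, on=["BIN", "SAMPLE"], how="left", suffixes=("", "_B"))
    df["BAF"] = df["BAF"].fillna(0.0)
    df["SNP_READS"] = df["SNP_READS"].fillna(0).astype(np.int64)
    df["B_READS"] = df["B_READS"].fillna(0.0)
    masked_b = df["MASKED_B"].astype("boolean").fillna(True).astype(bool)
    df["MASKED"] = df["MASKED"].astype(bool) | masked_b
    autosomal = bins.df.set_index("INDEX")["AUTOSOME"]
    df["MASKED"] |= ~df["BIN"].map(autosomal)
    df["MASKED"] = df["MASKED"].astype(bool)
    samples = sorted(df["SAMPLE"].unique())
    cols = ["BIN", "SAMPLE", "RDR", "BAF", "SNP_READS", "B_READS", "BIN_READS",
            "NORM_READS", "MASKED"]
    return SignalTable(df[cols + ["CHROM", "START", "END"]], samples, holdout_half)


def pool_signals(signals: SignalTable, labels: np.ndarray | dict,
                 bins: Bins) -> pd.DataFrame:
    """Summarize signals per (cluster, sample).

    Cluster RDR is the length-weighted mean of member-bin RDRs; cluster BAF
    re-pools the EM-assigned minor-side counts of member bins and re-mirrors.
    Empty clusters are dropped. Returns columns CLUSTER/SAMPLE/RDR/BAF/
    SNP_READS/BIN_READS/LENGTH.
    """
    df = signals.unmasked().copy()
    if isinstance(labels, dict):
        df["CLUSTER"] = df["BIN"].map(labels)
    else:
        lab = pd.Series(np.asarray(labels), index=bins.df["INDEX"].to_numpy())
        df["CLUSTER"] = df["BIN"].map(lab)
    df = df[df["CLUSTER"].notna()]
    df["CLUSTER"] = df["CLUSTER"].astype(int)
    lengths = pd.Series(bins.lengths, index=bins.df["INDEX"].to_numpy())
    df["LEN"] = df["BIN"].map(lengths)
    snp_df = signals.snp_df
    if snp_df is not None:
        bin2cluster = {b: c for b, c in zip(df["BIN"], df["CLUSTER"])}
        snp_df = snp_df.copy()
        snp_df["CLUSTER"] = snp_df["BIN"].map(bin2cluster)
        snp_df = snp_df[snp_df["CLUSTER"].notna()]
    rows = []
    for (cluster, sample), grp in df.groupby(["CLUSTER", "SAMPLE"], sort=True):
        grp = grp.sort_values("BIN")
        w = grp["LEN"].to_numpy(dtype=float)
        rvals = grp["RDR"].to_numpy()
        r = float(np.average(rvals, weights=w))
        # split-half variance of the centroid: even vs odd member bins
        half = np.arange(len(grp)) % 2
        if half.sum() and (1 - half).sum():
            r0 = float(np.average(rvals[half == 0], weights=w[half == 0]))
            r1 = float(np.average(rvals[half == 1], weights=w[half == 1]))
            var_r = (r0 - r1) ** 2 / 4.0
        else:
            var_r = 0.0
        if snp_df is not None:
            sel = snp_df[(snp_df["CLUSTER"] == cluster) & (snp_df["SAMPLE"] == sample)]
            ref = sel["REF_READS"].to_numpy(dtype=float)
            alt = sel["ALT_READS"].to_numpy(dtype=float)
            snp_reads = int((ref + alt).sum())
            beta = folded_moment_baf(ref, alt)
            beta = 0.0 if np.isnan(beta) else beta
            # split-half variance of the BAF estimate itself
            if len(ref) >= 4:
                s = np.arange(len(ref)) % 2
                b0 = folded_moment_baf(ref[s == 0], alt[s == 0])
                b1 = folded_moment_baf(ref[s == 1], alt[s == 1])
                var_b = (b0 - b1) ** 2 / 4.0 if np.isfinite(b0 + b1) else 0.0
            else:
                var_b = 0.0
        else:
            snp_reads = int(grp["SNP_READS"].sum())
            minor = grp["B_READS"].sum()
            beta = (
                float(min(minor / snp_reads, 1 - minor / snp_reads))
                if snp_reads else 0.0
            )
            var_b = 0.25 / snp_reads if snp_reads else 0.0
        norm_reads = int(grp["NORM_READS"].sum()) if "NORM_READS" in grp else 0
        rows.append((cluster, sample, r, beta, snp_reads,
                     int(grp["BIN_READS"].sum()), norm_reads, int(w.sum()),
                     var_r, var_b))
    return pd.DataFrame(
        rows,
        columns=["CLUSTER", "SAMPLE", "RDR", "BAF", "SNP_READS", "BIN_READS",
                 "NORM_READS", "LENGTH", "VAR_R", "VAR_B"],
    )
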