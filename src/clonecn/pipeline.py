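"""End-to-end orchestration of the inference pipeline.

Five stages: per-bin RDR/BAF computation, global clustering, dual-
hypothesis scaling to fractional copy numbers, factorization over the
model grid, and model selection. Every artifact (signals, clusters, clone
profile, per-sample summary, resolved configuration) is written to the
output directory; a fixed seed makes the run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import genome_model, rdr_baf
from .deconvolution import Solution
from .fractional_scaling import candidate_hypotheses
from .global_cluster import TOL_BAF, TOL_R, cluster_bins, merge_clusters
from .model_selection import (build_model_grid, choose_hypothesis,
                              select_solution, summarize)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("clonecn")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    tumor_counts: str
    snp_counts: str
    out_dir: str
    bin_width: int = 50_000
    min_snps_per_bin: int = 5
    max_components: int = 50
    cluster_restarts: int = 10
    tol_r: float = TOL_R
    tol_baf: float = TOL_BAF
    c_max: int = 12
    u_min: float = 0.03
    tau_elbow: float = 0.05
    n_max: int = 6
    solver_restarts: int = 24
    seed: int = 0

    def validate(self) -> None:
        if self.bin_width <= 0 or self.c_max < 2:
            raise ValueError("invalid bin width or c_max")
        if not 0 < self.u_min < 1:
            raise ValueError("u_min must be in (0, 1)")
        if self.n_max < 2:
            raise ValueError("n_max must be at least 2")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return deco


@_stage("rdr_baf")
def _load_signals(config: RunConfig):
    counts = genome_model.read_bin_counts(config.tumor_counts)
    snps = genome_model.read_snp_counts(config.snp_counts)
    bin_frame = counts.df[["CHROM", "START", "END"]].drop_duplicates()
    bin_frame = bin_frame.sort_values(["CHROM", "START"]).reset_index(drop=True)
    bin_frame["INDEX"] = np.arange(len(bin_frame))
    bins = genome_model.Bins(bin_frame)
    tumor_samples = [s for s in counts.samples]
    snps_t = genome_model.SNPCountTable(
        snps.df[snps.df["SAMPLE"].isin(tumor_samples)].reset_index(drop=True)
    )
    signals = rdr_baf.build_signals(counts, snps_t, bins,
                                    min_snps_per_bin=config.min_snps_per_bin)
    return bins, signals


@_stage("global_cluster")
def _cluster(config: RunConfig, bins, signals):
    assignment = cluster_bins(signals, bins, max_components=config.max_components,
                              seed=config.seed, n_restarts=config.cluster_restarts)
    return merge_clusters(assignment, signals, bins,
                          tol_r=config.tol_r, tol_baf=config.tol_baf)


@_stage("fractional_scaling")
def _scale(config: RunConfig, assignment):
    pairs = candidate_hypotheses(assignment, tol_baf=config.tol_baf)
    if not pairs:
        raise ValueError("no feasible scaling hypothesis")
    return pairs


@_stage("deconvolution")
def _factorize(config: RunConfig, pairs, lengths):
    chosen = choose_hypothesis(pairs, lengths)
    return build_model_grid([chosen], lengths, c_max=config.c_max,
                            u_min=config.u_min, n_max=config.n_max,
                            tau=config.tau_elbow,
                            restarts=config.solver_restarts, seed=config.seed)


@_stage("model_selection")
def _select(config: RunConfig, grid) -> Solution:
    return select_solution(grid, tau=config.tau_elbow)


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write artifacts; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        with open(out / "config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        bins, signals = _load_signals(config)
        signals.df.to_csv(out / "signals.tsv", sep="\t", index=False,
                          float_format="%.6g")
        assignment = _cluster(config, bins, signals)
        _write_clusters(out, bins, assignment)
        pairs = _scale(config, assignment)
        for pair in pairs:
            hyp = pair.hypothesis
            logger.info(
                "hypothesis %s: anchor=%s omega=%s gamma=%s",
                "WGD" if hyp.wgd else "noWGD", hyp.anchor1,
                (hyp.omega1, hyp.omega2), np.round(hyp.gamma, 4),
            )
        _, _, lengths, ids, _ = assignment.matrices()
        grid = _factorize(config, pairs, lengths)
        solution = _select(config, grid)
        _write_solution(out, bins, assignment, solution)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


def _write_clusters(out: Path, bins, assignment) -> None:
    lab = pd.Series(assignment.labels, name="CLUSTER")
    df = bins.df.merge(lab.rename_axis("INDEX").reset_index(), on="INDEX", how="inner")
    df[["CHROM", "START", "END", "CLUSTER"]].to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    assignment.centroids.to_csv(out / "centroids.tsv", sep="\t", index=False,
                                float_format="%.6g")


def _write_solution(out: Path, bins, assignment, solution: Solution) -> None:
    # map cluster ids to solution rows for the BED-like profile
    row_of = {cid: i for i, cid in enumerate(solution.cluster_ids)}
    lab = pd.Series(assignment.labels, name="CID").rename_axis("INDEX").reset_index()
    seg = bins.df.merge(lab, on="INDEX", how="inner")
    seg = seg[seg["CID"].isin(row_of)]
    seg["CLUSTER"] = seg["CID"].map(row_of)
    genome_model.write_clone_profile(
        solution, seg[["CHROM", "START", "END", "CLUSTER"]], out / "clone_profile.tsv"
    )
    summarize(solution).to_csv(out / "summary.tsv", sep="\t", index=False,
                               float_format="%.6g")
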