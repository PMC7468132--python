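"""In-memory evaluation harnesses used by the test suite and scripts.

These run the full inference pipeline (signals -> clustering -> scaling ->
factorization -> model selection) on simulated patients without touching
the filesystem, and score the per-sample whole-genome-duplication call
against the simulated truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bulk_sim import SimConfig, simulate_patient
from .fractional_scaling import candidate_hypotheses
from .global_cluster import cluster_bins, merge_clusters
from .model_selection import build_model_grid, choose_hypothesis, select_solution
from .rdr_baf import build_signals

__all__ = ["infer_patient", "patient_config", "wgd_benchmark", "precision_recall"]

BENCH_GENOME = 100_000_000
BENCH_COVERAGE = 30.0


def infer_patient(patient, c_max: int = 12, u_min: float = 0.03,
                  n_max: int = 6, seed: int = 0, solver_restarts: int = 24,
                  cluster_restarts: int = 10):
    """Full pipeline on a simulated patient's count tables; returns the
    selected solution."""
    bins = patient.bins
    signals = build_signals(patient.bin_counts, patient.snp_counts, bins)
    assignment = cluster_bins(signals, bins, seed=seed,
                              n_restarts=cluster_restarts)
    assignment = merge_clusters(assignment, signals, bins)
    pairs = candidate_hypotheses(assignment)
    _, _, lengths, _, _ = assignment.matrices()
    chosen = choose_hypothesis(pairs, lengths)
    grid = build_model_grid([chosen], lengths, c_max=c_max, u_min=u_min,
                            n_max=n_max, restarts=solver_restarts, seed=seed)
    solution = select_solution(grid)
    return solution, assignment, grid


def patient_config(seed: int, wgd: bool, genome_length: int = BENCH_GENOME,
                   coverage: float = BENCH_COVERAGE) -> SimConfig:
    """Benchmark patient: 2-4 clones and 2-3 samples drawn from the seed."""
    rng = np.random.default_rng(seed)
    return SimConfig(
        n_clones=int(rng.integers(2, 5)),
        n_samples=int(rng.integers(2, 4)),
        wgd=wgd,
        coverage=coverage,
        genome_length=genome_length,
        seed=seed,
    )


def wgd_benchmark(seeds_wgd, seeds_nowgd, genome_length: int = BENCH_GENOME,
                  coverage: float = BENCH_COVERAGE, **infer_kwargs) -> pd.DataFrame:
    """Simulate one patient per seed, run the pipeline, score the WGD call.

    Returns one row per sample with TRUE_WGD and CALLED_WGD; the call is
    per patient (the model applies one hypothesis to all samples jointly),
    replicated over its samples for per-sample scoring.
    """
    rows = []
    for wgd, seeds in ((True, seeds_wgd), (False, seeds_nowgd)):
        for seed in seeds:
            config = patient_config(seed, wgd, genome_length, coverage)
            patient = simulate_patient(config)
            solution, _, _ = infer_patient(patient, seed=seed, **infer_kwargs)
            called = bool(solution.hypothesis.wgd)
            for sample in patient.samples:
                rows.append((seed, sample, wgd, called))
    return pd.DataFrame(rows, columns=["SEED", "SAMPLE", "TRUE_WGD", "CALLED_WGD"])


def precision_recall(scores: pd.DataFrame) -> dict:
    """Per-class precision and recall of the WGD presence/absence call."""
    t = scores["TRUE_WGD"].to_numpy()
    c = scores["CALLED_WGD"].to_numpy()
    out = {}
    for label, cls in (("presence", True), ("absence", False)):
        called = c == cls
        true = t == cls
        tp = int((called & true).sum())
        out[f"precision_{label}"] = tp / called.sum() if called.sum() else np.nan
        out[f"recall_{label}"] = tp / true.sum() if true.sum() else np.nan
    return out
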