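"""Counts-level simulation of multi-sample bulk tumor sequencing.

Simulates a patient as a random clone phylogeny on which copy-number
events (focal to whole-chromosome, optionally one clonal WGD) accumulate,
then draws per-bin read counts for each bulk sample. The critical
correction is that a clone's share of the reads is not its cell fraction:
clones have different genome lengths L_i, so the read proportion of clone
i in sample p is

    v_{i,p} = u_{i,p} L_i / sum_j u_{j,p} L_j,

and the read share of segment s within clone i is
v_{s,i} = l_s c_{s,i} u_{i,p} / sum_j u_{j,p} L_j. Bin-level tumor counts
are multinomial with these segment shares aggregated over clones; the
matched normal is uniform over the diploid genome. SNP and somatic
mutation counts are binomial at the depth implied by the local genome
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (
    BinCountTable,
    Bins,
    MutationTable,
    SNPCountTable,
    make_bins,
)

__all__ = ["SimConfig", "CloneGenome", "SimulatedPatient",
           "simulate_patient", "read_proportions", "simulate_mutations"]

#: hg19 autosome lengths (bp), used as relative chromosome proportions
HG19_AUTOSOMES = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566,
}

#: CNA size classes (bp ranges; arm/chromosome are fractions of the chromosome)
EVENT_SIZES = {
    "focal": (100_000, 1_000_000),
    "small": (3_000_000, 5_000_000),
    "medium": (10_000_000, 20_000_000),
}
DEFAULT_EVENT_COUNTS = {"focal": 6, "small": 4, "medium": 3, "arm": 2, "chromosome": 1}


@dataclass
class SimConfig:
    n_clones: int = 3            # including the normal clone (2-4 typical)
    n_samples: int = 3
    wgd: bool = False
    coverage: float = 30.0       # haploid-genome-equivalent coverage per sample
    read_length: int = 100
    genome_length: int = 3_000_000_000
    bin_width: int = 50_000
    snp_spacing: int = 2_000     # one heterozygous SNP per this many bp
    event_counts: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_COUNTS))
    u_min: float = 0.03
    n_mutations: int = 0
    mutation_coverage: float | None = None  # defaults to ``coverage``
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 2:
            raise ValueError("need the normal clone plus at least one tumor clone")
        if self.n_samples < 1 or self.coverage <= 0 or self.genome_length <= 0:
            raise ValueError("inconsistent simulation config")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class CloneGenome:
    """Per-bin allele-specific copy numbers of one clone."""

    a: np.ndarray  # per-bin copies of the first haplotype
    b: np.ndarray  # per-bin copies of the second haplotype

    @property
    def c(self) -> np.ndarray:
        return self.a + self.b

    def genome_length(self, bin_lengths: np.ndarray) -> float:
        """L_i = sum over bins of total copy number times bin length."""
        return float(self.c @ bin_lengths)


@dataclass
class SimulatedPatient:
    config: SimConfig
    bins: Bins
    clones: list          # CloneGenome per clone; clone 0 is normal
    tree_parent: list     # parent clone index per clone (-1 for the root)
    U: np.ndarray         # true clone proportions, n x k
    samples: list
    bin_counts: BinCountTable
    snp_counts: SNPCountTable
    event_log: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        """Per-bin true states per clone (long format) for serialization."""
        rows = []
        for i, clone in enumerate(self.clones):
            df = self.bins.df[["CHROM", "START", "END"]].copy()
            df["CLONE"] = i + 1
            df["STATE"] = [f"{a}|{b}" for a, b in zip(clone.a, clone.b)]
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def _scaled_genome(total: int) -> dict:
    """22 autosomes with hg19 relative sizes scaled to ``total`` bp."""
    full = sum(HG19_AUTOSOMES.values())
    return {c: max(1, int(round(L * total / full))) for c, L in HG19_AUTOSOMES.items()}


def _random_tree(n_tumor: int, rng: np.random.Generator) -> list:
    """Parent index per tumor clone; clone 0 (first tumor) hangs off normal."""
    parents = [-1, 0] if n_tumor >= 1 else [-1]
    for i in range(2, n_tumor + 1):
        parents.append(int(rng.integers(1, i)))  # attach to a random tumor clone
    return parents


def _place_events(bins: Bins, config: SimConfig, rng: np.random.Generator,
                  branch: int) -> list:
    """Draw the CNA events for one tumor branch (spans in bp, bin-resolved)."""
    events = []
    chroms = bins.df["CHROM"].unique()
    chrom_span = {
        c: (int(g["START"].min()), int(g["END"].max()))
        for c, g in bins.df.groupby("CHROM")
    }
    for kind, count in config.event_counts.items():
        for _ in range(count):
            chrom = chroms[rng.integers(len(chroms))]
            lo, hi = chrom_span[chrom]
            clen = hi - lo
            if kind == "chromosome":
                start, end = lo, hi
            elif kind == "arm":
                mid = lo + clen // 2
                start, end = (lo, mid) if rng.random() < 0.5 else (mid, hi)
            else:
                smin, smax = EVENT_SIZES[kind]
                size = int(rng.integers(smin, smax + 1))
                size = min(size, clen)
                start = lo + int(rng.integers(0, max(clen - size, 0) + 1))
                end = start + size
            allele = "a" if rng.random() < 0.5 else "b"
            delta = 1 if rng.random() < 0.5 else -1
            events.append(dict(branch=branch, kind=kind, chrom=chrom,
                               start=start, end=end, allele=allele, delta=delta))
    return events


def _apply_events(parent: CloneGenome, events: list, bins: Bins,
                  wgd: bool) -> CloneGenome:
    """Child genome: parent states, optional WGD, then the branch events."""
    a, b = parent.a.copy(), parent.b.copy()
    if wgd:
        a *= 2
        b *= 2
    df = bins.df
    for ev in events:
        mask = (
            (df["CHROM"] == ev["chrom"])
            & (df["START"] < ev["end"])
            & (df["END"] > ev["start"])
        ).to_numpy()
        target = a if ev["allele"] == "a" else b
        if ev["delta"] > 0:
            # an absent allele cannot be amplified
            target[mask & (target > 0)] += 1
        else:
            target[mask] = np.maximum(target[mask] - 1, 0)
    return CloneGenome(a, b)


def read_proportions(u: np.ndarray, clones: list, bin_lengths: np.ndarray):
    """Clone and per-(bin, clone) read proportions for one sample.

    Returns (v, V) with v[i] = u_i L_i / sum_j u_j L_j and
    V[s, i] = l_s c_{s,i} u_i / sum_j u_j L_j, so that V.sum(axis=0) == v
    and v.sums to 1.
    """
    u = np.asarray(u, float)
    L = np.array([cl.genome_length(bin_lengths) for cl in clones])
    denom = float(u @ L)
    if denom <= 0:
        raise ValueError("zero total genome content in sample")
    v = u * L / denom
    C = np.stack([cl.c for cl in clones], axis=1)  # bins x clones
    V = bin_lengths[:, None] * C * u[None, :] / denom
    return v, V


def _draw_proportions(n: int, k: int, u_min: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Random sample compositions: normal always present, tumor clones a
    random subset with Dirichlet proportions floored at u_min."""
    n_tumor = n - 1
    U = np.zeros((n, k))
    for p in range(k):
        while True:
            present = rng.random(n_tumor) < 0.75
            if present.any():
                break
        u = rng.dirichlet(np.ones(int(present.sum()) + 1))
        col = np.zeros(n)
        col[0] = u[0]
        col[1:][present] = u[1:]
        col[1:][col[1:] < u_min] = 0.0
        if col[1:].sum() == 0:
            # keep at least the largest drawn tumor clone at the floor
            j = 1 + int(np.argmax(np.where(present, u[1:], -1)))
            col[j] = max(u_min, float(u[j]))
        U[:, p] = col / col.sum()
    # every tumor clone must appear somewhere; re-seat absent ones
    for i in range(1, n):
        if (U[i] == 0).all():
            p = int(rng.integers(k))
            U[i, p] = max(u_min, 0.1)
            U[:, p] /= U[:, p].sum()
    return U


def simulate_patient(config: SimConfig) -> SimulatedPatient:
    """Full counts-level simulation of one patient.

    Steps: random clone tree with CNA events per branch (the WGD, when
    simulated, on the branch to the first tumor clone so it is clonal);
    random sample compositions; multinomial bin counts at the configured
    coverage for tumor samples and the matched normal; binomial SNP counts
    at the haplotype mixture implied by the clone states.
    """
    rng = np.random.default_rng(config.seed)
    bins = make_bins(_scaled_genome(config.genome_length), config.bin_width)
    nb = len(bins)
    lengths = bins.lengths.astype(float)
    n = config.n_clones
    parents = _random_tree(n - 1, rng)
    normal = CloneGenome(np.ones(nb, dtype=np.int64), np.ones(nb, dtype=np.int64))
    clones = [normal]
    all_events = []
    for i in range(1, n):
        events = _place_events(bins, config, rng, branch=i)
        all_events.extend(events)
        is_truncal = parents[i] == 0
        child = _apply_events(clones[parents[i]], events, bins,
                              wgd=config.wgd and is_truncal)
        clones.append(child)
    U = _draw_proportions(n, config.n_samples, config.u_min, rng)
    samples = [f"S{p + 1}" for p in range(config.n_samples)]

    total_reads = int(config.coverage * config.genome_length / config.read_length)
    rows = []
    # matched normal: uniform over the diploid genome
    normal_counts = rng.multinomial(total_reads, lengths / lengths.sum())
    for p, name in enumerate(samples):
        _, V = read_proportions(U[:, p], clones, lengths)
        probs = V.sum(axis=1)
        counts = rng.multinomial(total_reads, probs / probs.sum())
        df = bins.df[["CHROM", "START", "END"]].copy()
        df["SAMPLE"] = name
        df["TUMOR_READS"] = counts
        df["NORMAL_READS"] = normal_counts
        rows.append(df)
    bin_counts = BinCountTable(pd.concat(rows, ignore_index=True))

    snp_counts = _simulate_snps(bins, clones, U, samples, config, rng)
    event_log = pd.DataFrame(all_events)
    return SimulatedPatient(config, bins, clones, parents, U, samples,
                            bin_counts, snp_counts, event_log)


def _simulate_snps(bins: Bins, clones: list, U: np.ndarray, samples: list,
                   config: SimConfig, rng: np.random.Generator) -> SNPCountTable:
    """Binomial SNP counts; each SNP's alt allele sits on one haplotype."""
    lengths = bins.lengths.astype(float)
    A = np.stack([cl.a for cl in clones], axis=1)  # bins x clones
    B = np.stack([cl.b for cl in clones], axis=1)
    C = A + B
    # SNP placement: one per snp_spacing window with random offset
    n_per_bin = (bins.lengths // config.snp_spacing).astype(int)
    snp_bin = np.repeat(bins.df["INDEX"].to_numpy(), n_per_bin)
    starts = np.repeat(bins.df["START"].to_numpy(), n_per_bin)
    offset_slot = np.concatenate([np.arange(c) for c in n_per_bin]) if len(snp_bin) else np.array([], int)
    jitter = rng.integers(0, config.snp_spacing, size=len(snp_bin))
    positions = starts + offset_slot * config.snp_spacing + jitter + 1
    chroms = np.repeat(bins.df["CHROM"].to_numpy(), n_per_bin)
    alt_on_a = rng.random(len(snp_bin)) < 0.5
    Lg = np.array([cl.genome_length(lengths) for cl in clones])

    frames = []
    for p, name in enumerate(samples):
        u = U[:, p]
        fa = (A @ u)[snp_bin]
        fb = (B @ u)[snp_bin]
        f = (C @ u)[snp_bin]
        Ltot = float(u @ Lg)
        depth = config.coverage * config.genome_length / Ltot * f
        T = rng.poisson(depth)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_alt = np.where(alt_on_a, fa, fb) / np.where(f > 0, f, 1.0)
        alt = rng.binomial(T, np.clip(p_alt, 0, 1))
        frames.append(pd.DataFrame({
            "CHROM": chroms, "POS": positions, "SAMPLE": name,
            "REF_READS": T - alt, "ALT_READS": alt,
        }))
    # matched normal: balanced alleles at the same coverage
    Tn = rng.poisson(config.coverage, size=len(snp_bin))
    altn = rng.binomial(Tn, 0.5)
    frames.append(pd.DataFrame({
        "CHROM": chroms, "POS": positions, "SAMPLE": "normal",
        "REF_READS": Tn - altn, "ALT_READS": altn,
    }))
    return SNPCountTable(pd.concat(frames, ignore_index=True))


def simulate_mutations(patient: SimulatedPatient, n_mutations: int | None = None,
                       coverage: float | None = None,
                       rng: np.random.Generator | None = None):
    """Somatic mutations with clone-resolved multiplicities and read counts.

    Each mutation is placed on a random tumor tree branch, a random bin and
    one haplotype, mutating a single copy; the mutated-copy count is then
    propagated down the tree, following the net copy-number changes of that
    haplotype on each branch (a gained copy duplicates a uniformly random
    existing copy, a loss removes one; a WGD doubles the mutated count).
    Observed variant reads are Binomial(T, expected VAF) at the read depth
    implied by the local genome content.

    Returns (MutationTable, truth DataFrame) with per-clone multiplicities.
    """
    config = patient.config
    if n_mutations is None:
        n_mutations = config.n_mutations
    if coverage is None:
        coverage = config.mutation_coverage or config.coverage
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    bins = patient.bins
    lengths = bins.lengths.astype(float)
    n = len(patient.clones)
    children = {i: [] for i in range(n)}
    for i, par in enumerate(patient.tree_parent):
        if par >= 0:
            children[par].append(i)

    A = np.stack([cl.a for cl in patient.clones], axis=1)
    B = np.stack([cl.b for cl in patient.clones], axis=1)
    rows, truth_rows = [], []
    for mid in range(n_mutations):
        branch = int(rng.integers(1, n))  # a tumor clone's incoming branch
        s = int(rng.integers(len(bins)))
        hap = "a" if rng.random() < 0.5 else "b"
        H = A if hap == "a" else B
        if H[s, branch] == 0:
            # the mutated haplotype must exist in the originating clone
            hap = "b" if hap == "a" else "a"
            H = A if hap == "a" else B
            if H[s, branch] == 0:
                continue
        def _replay(k_from: int, k_to: int, mcur: int) -> int:
            # net copy-number change of the haplotype: each gain duplicates a
            # uniformly random copy, each loss removes one
            kk = k_from
            while kk < k_to and kk > 0:
                if rng.random() < mcur / kk:
                    mcur += 1
                kk += 1
            while kk > k_to and kk > 0:
                if rng.random() < mcur / kk:
                    mcur -= 1
                kk -= 1
            return min(mcur, k_to)

        mult = np.zeros(n, dtype=np.int64)
        # timing on the originating branch: with prob 1/2 the mutation
        # precedes the branch's own events (incl. a truncal WGD) and its
        # copy is carried through them, otherwise it lands after them
        k_parent = int(H[s, patient.tree_parent[branch]])
        if rng.random() < 0.5 and k_parent > 0:
            mult[branch] = _replay(k_parent, int(H[s, branch]), 1)
        else:
            mult[branch] = 1
        # propagate the mutated copies to descendant clones
        stack = list(children[branch])
        while stack:
            child = stack.pop()
            par = patient.tree_parent[child]
            mult[child] = _replay(int(H[s, par]), int(H[s, child]), int(mult[par]))
            stack.extend(children[child])
        pos = int(bins.df["START"].iloc[s]) + 1 + int(rng.integers(bins.lengths[s]))
        chrom = bins.df["CHROM"].iloc[s]
        for p, name in enumerate(patient.samples):
            u = patient.U[:, p]
            c_tot = float((A[s] + B[s]) @ u)
            vaf = float(mult @ u) / c_tot if c_tot > 0 else 0.0
            Ltot = sum(cl.genome_length(lengths) * ui
                       for cl, ui in zip(patient.clones, u))
            depth = coverage * config.genome_length / Ltot * c_tot
            T = int(rng.poisson(depth))
            v = int(rng.binomial(T, min(vaf, 1.0))) if T > 0 else 0
            rows.append((chrom, pos, name, v, T))
            truth_rows.append((chrom, pos, name, branch + 1, hap,
                               ";".join(map(str, mult)), vaf))
    table = MutationTable(
        pd.DataFrame(rows, columns=["CHROM", "POS", "SAMPLE", "VAR_READS", "TOTAL_READS"])
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["CHROM", "POS", "SAMPLE", "ORIGIN_CLONE", "HAPLOTYPE",
                 "MULTIPLICITIES", "TRUE_VAF"],
    )
    return table, truth
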