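"""Genome coordinates, tabular input/output, and the core domain tables.

Coordinates are 0-based half-open (BED convention) everywhere internally.
SNP and somatic-mutation positions are 1-based (VCF convention) in files and
converted on load. All readers validate the type invariants and raise
:class:`ParseError` naming the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomeBin",
    "Bins",
    "BinCountTable",
    "SNPCountTable",
    "MutationTable",
    "make_bins",
    "read_bin_counts",
    "write_bin_counts",
    "read_snp_counts",
    "write_snp_counts",
    "read_mutations",
    "write_mutations",
    "write_clone_profile",
    "read_clone_profile",
]

#: chromosome names excluded from clustering/scaling by default
NON_AUTOSOMES = frozenset(
    {"chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT"}
)

DEFAULT_BIN_WIDTH = 50_000


class ParseError(ValueError):
    """Malformed or invariant-violating tabular input."""


@dataclass(frozen=True)
class GenomeBin:
    """A genomic bin [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty bin {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class Bins:
    """Ordered collection of non-overlapping bins tiling each chromosome.

    Wraps a DataFrame with columns CHROM/START/END/INDEX plus an AUTOSOME
    flag; non-autosomal bins are created but flagged so downstream steps can
    exclude them.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"CHROM", "START", "END", "INDEX"}
        if not required.issubset(df.columns):
            raise ValueError(f"bins frame missing columns {required - set(df.columns)}")
        self.df = df.reset_index(drop=True)
        if "AUTOSOME" not in self.df.columns:
            self.df["AUTOSOME"] = ~self.df["CHROM"].isin(NON_AUTOSOMES)
        for chrom, grp in self.df.groupby("CHROM", sort=False):
            starts = grp["START"].to_numpy()
            ends = grp["END"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError(f"empty bin on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield GenomeBin(row.CHROM, int(row.START), int(row.END), int(row.INDEX))

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["END"] - self.df["START"]).to_numpy()

    @property
    def autosomal(self) -> np.ndarray:
        return self.df["AUTOSOME"].to_numpy()

    def locate(self, chrom: str, pos0: int) -> int:
        """Return the INDEX of the bin containing 0-based position, or -1."""
        sel = self.df[
            (self.df["CHROM"] == chrom)
            & (self.df["START"] <= pos0)
            & (self.df["END"] > pos0)
        ]
        if sel.empty:
            return -1
        return int(sel["INDEX"].iloc[0])


def make_bins(chrom_lengths: Mapping[str, int], width: int = DEFAULT_BIN_WIDTH) -> Bins:
    """Tile each chromosome left to right with fixed-width bins.

    The last bin of a chromosome is truncated to the chromosome end, so the
    bin lengths on a chromosome always sum to the chromosome length.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    if not chrom_lengths:
        raise ValueError("empty chromosome map")
    rows = []
    index = 0
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length), index))
            index += 1
    return Bins(pd.DataFrame(rows, columns=["CHROM", "START", "END", "INDEX"]))


def _read_tsv(path, columns: Sequence[str], int_columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot read TSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: malformed header, missing columns {missing}")
    df = df[list(columns)]
    for col in int_columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ParseError(f"{path}: line {line}: non-integer value in {col}")
        neg = values < 0
        if neg.any():
            line = int(np.flatnonzero(neg.to_numpy())[0]) + 2
            raise ParseError(f"{path}: line {line}: negative value in {col}")
        df[col] = values.astype(np.int64)
    return df


@dataclass
class BinCountTable:
    """Per-bin tumor read counts for each sample plus matched-normal counts.

    ``df`` has one row per (bin, sample) with columns CHROM/START/END/SAMPLE/
    TUMOR_READS/NORMAL_READS; the normal counts are repeated across samples
    for a bin and must agree. Per-sample totals are the column sums.
    """

    df: pd.DataFrame
    samples: list = field(init=False)

    def __post_init__(self) -> None:
        required = ["CHROM", "START", "END", "SAMPLE", "TUMOR_READS", "NORMAL_READS"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ParseError(f"bin count table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        self.samples = sorted(self.df["SAMPLE"].unique())
        key = ["CHROM", "START", "END"]
        per_bin = self.df.groupby(key)["SAMPLE"].nunique()
        if per_bin.nunique() > 1 or (len(per_bin) and per_bin.iloc[0] != len(self.samples)):
            raise ParseError("every bin must be present for every sample")
        normal_nunique = self.df.groupby(key)["NORMAL_READS"].nunique()
        if (normal_nunique > 1).any():
            raise ParseError("normal counts disagree across samples for a bin")

    @property
    def tumor_totals(self) -> pd.Series:
        return self.df.groupby("SAMPLE")["TUMOR_READS"].sum()

    @property
    def normal_total(self) -> int:
        key = ["CHROM", "START", "END"]
        return int(self.df.drop_duplicates(key)["NORMAL_READS"].sum())


@dataclass
class SNPCountTable:
    """Ref/alt read counts at heterozygous germline SNPs per sample.

    POS is stored 1-based as in the file. SNPs are assumed heterozygous in
    the matched normal by construction of the input.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["CHROM", "POS", "SAMPLE", "REF_READS", "ALT_READS"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ParseError(f"SNP count table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if self.df.duplicated(["CHROM", "POS", "SAMPLE"]).any():
            raise ParseError("duplicate SNP position within a sample")

    @property
    def samples(self) -> list:
        return sorted(self.df["SAMPLE"].unique())

    def assign_bins(self, bins: Bins) -> pd.DataFrame:
        """Return df with a BIN column mapping each SNP to its containing bin.

        SNPs outside any bin get BIN = -1. Positions are converted from the
        1-based file convention to 0-based before the interval lookup.
        """
        out = self.df.copy()
        out["BIN"] = -1
        for chrom, grp in out.groupby("CHROM", sort=False):
            cbins = bins.df[bins.df["CHROM"] == chrom]
            if cbins.empty:
                continue
            starts = cbins["START"].to_numpy()
            ends = cbins["END"].to_numpy()
            idx = cbins["INDEX"].to_numpy()
            pos0 = grp["POS"].to_numpy() - 1
            j = np.searchsorted(starts, pos0, side="right") - 1
            ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
            assigned = np.where(ok, idx[np.clip(j, 0, len(idx) - 1)], -1)
            out.loc[grp.index, "BIN"] = assigned
        return out


@dataclass
class MutationTable:
    """Somatic-mutation read counts: variant reads v out of total reads T."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["CHROM", "POS", "SAMPLE", "VAR_READS", "TOTAL_READS"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ParseError(f"mutation table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if (self.df["VAR_READS"] > self.df["TOTAL_READS"]).any():
            raise ParseError("VAR_READS exceeds TOTAL_READS")


def read_bin_counts(path) -> BinCountTable:
    df = _read_tsv(
        path,
        ["CHROM", "START", "END", "SAMPLE", "TUMOR_READS", "NORMAL_READS"],
        ["START", "END", "TUMOR_READS", "NORMAL_READS"],
    )
    return BinCountTable(df)


def write_bin_counts(table: BinCountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_snp_counts(path) -> SNPCountTable:
    df = _read_tsv(
        path,
        ["CHROM", "POS", "SAMPLE", "REF_READS", "ALT_READS"],
        ["POS", "REF_READS", "ALT_READS"],
    )
    return SNPCountTable(df)


def write_snp_counts(table: SNPCountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> MutationTable:
    df = _read_tsv(
        path,
        ["CHROM", "POS", "SAMPLE", "VAR_READS", "TOTAL_READS"],
        ["POS", "VAR_READS", "TOTAL_READS"],
    )
    return MutationTable(df)


def write_mutations(table: MutationTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def write_clone_profile(solution, segments: pd.DataFrame, path) -> None:
    """Serialize a deconvolution solution as a BED-like clone-profile TSV.

    ``segments`` maps clusters to genomic intervals (CHROM/START/END/CLUSTER,
    CLUSTER indexing rows of A and B). Each data row carries the per-clone
    "a|b" copy-number states; clone-proportion columns (one per sample) are
    repeated on every row so the file is self-contained. Re-reading with
    :func:`read_clone_profile` reproduces A, B, U exactly.
    """
    A, B, U = solution.A, solution.B, solution.U
    n = A.shape[1]
    samples = list(solution.samples)
    header = ["CHROM", "START", "END", "CLUSTER"]
    header += [f"STATE_CLONE{i + 1}" for i in range(n)]
    header += [f"U_{s}" for s in samples]
    rows = []
    for row in segments.sort_values(["CHROM", "START"]).itertuples(index=False):
        s = int(row.CLUSTER)
        states = [f"{A[s, i]}|{B[s, i]}" for i in range(n)]
        # proportions serialized per sample: all clones joined by ","
        uvals = [",".join(f"{U[i, p]:.10g}" for i in range(n)) for p in range(len(samples))]
        rows.append([row.CHROM, int(row.START), int(row.END), s] + states + uvals)
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


def read_clone_profile(path):
    """Read a clone-profile TSV back into (A, B, U, samples, segments)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "CLUSTER" not in df.columns:
        raise ParseError(f"{path}: malformed clone profile header")
    state_cols = [c for c in df.columns if c.startswith("STATE_CLONE")]
    u_cols = [c for c in df.columns if c.startswith("U_")]
    samples = [c[2:] for c in u_cols]
    n = len(state_cols)
    clusters = df["CLUSTER"].astype(int)
    m = clusters.max() + 1
    A = np.zeros((m, n), dtype=np.int64)
    B = np.zeros((m, n), dtype=np.int64)
    for row in df.itertuples(index=False):
        s = int(row.CLUSTER)
        for i, col in enumerate(state_cols):
            a, b = getattr(row, col).split("|")
            A[s, i], B[s, i] = int(a), int(b)
    U = np.zeros((n, len(samples)))
    first = df.iloc[0]
    for p, col in enumerate(u_cols):
        U[:, p] = [float(x) for x in first[col].split(",")]
    segments = df[["CHROM", "START", "END", "CLUSTER"]].astype(
        {"START": np.int64, "END": np.int64, "CLUSTER": np.int64}
    )
    return A, B, U, samples, segments
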