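"""Reading, writing, and minimal preprocessing of binned copy-number data.

Bin coordinates follow the BED convention (0-based, half-open) everywhere
internally.  Matrices are bins x patients; small matrices travel as TSV,
large ones as HDF5.  Preprocessing is deliberately minimal: raw bin read
counts are only rescaled per patient so the genome-wide mean is 1 (relative
copy number, diploid baseline ~1).  No per-bin normalization and no GC
correction is applied — separating the GC artifact is the decomposition's
job, not the loader's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .core_gsvd import ProfilePair
from .errors import DataMismatchError

__all__ = [
    "BinTable",
    "CohortTable",
    "ProfileMatrix",
    "load_profile",
    "save_profile",
    "preprocess_counts",
    "match_pair",
    "gc_from_fasta",
]

SEX_CHROMOSOMES = {"X", "chrX", "Y", "chrY"}
_DROPPED_CHROMS = {"Y", "chrY"}


@dataclass
class BinTable:
    """Genomic bins: chromosome, 0-based half-open span, optional GC fraction."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.df.columns)
        if missing:
            raise DataMismatchError(f"bin table lacks columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if "gc" not in df.columns:
            df["gc"] = np.nan
        if (df["end"] <= df["start"]).any():
            raise DataMismatchError("bins must satisfy end > start")
        gc = df["gc"].to_numpy(dtype=float)
        finite = np.isfinite(gc)
        if np.any((gc[finite] < 0) | (gc[finite] > 1)):
            raise DataMismatchError("gc_fraction must lie in [0, 1]")
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(np.diff(starts) < 0):
                raise DataMismatchError(f"bins on {chrom} are not sorted by start")
            if np.any(ends[:-1] > starts[1:]):
                raise DataMismatchError(f"bins on {chrom} overlap")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def start(self) -> np.ndarray:
        return self.df["start"].to_numpy()

    @property
    def end(self) -> np.ndarray:
        return self.df["end"].to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=float)

    def autosome_mask(self) -> np.ndarray:
        return ~np.isin(self.chrom, list(SEX_CHROMOSOMES))

    def x_mask(self) -> np.ndarray:
        return np.isin(self.chrom, ["X", "chrX"])

    @classmethod
    def read_bed(cls, path) -> "BinTable":
        """Read bins from BED; optional 4th column name, 5th column gc_fraction.

        Chromosome Y and non-canonical contigs are dropped with a warning
        (the analysis covers the autosomes and the X chromosome).
        """
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
        if df.shape[1] >= 5:
            df["gc"] = pd.to_numeric(df[4], errors="coerce")
        df["chrom"] = df["chrom"].astype(str)
        canonical = [str(i) for i in range(1, 23)] + ["X"]
        canonical += [f"chr{c}" for c in canonical]
        keep = df["chrom"].isin(canonical)
        if not keep.all():
            dropped = sorted(df.loc[~keep, "chrom"].unique())
            warnings.warn(f"dropping bins on non-canonical chromosomes: {dropped}")
            df = df[keep]
        cols = ["chrom", "start", "end"] + (["gc"] if "gc" in df.columns else [])
        return cls(df[cols])

    def to_bed(self, path) -> None:
        out = self.df.copy()
        out["name"] = [f"bin_{i:07d}" for i in range(len(out))]
        out["score"] = out["gc"].map(lambda g: f"{g:.6g}" if np.isfinite(g) else ".")
        out[["chrom", "start", "end", "name", "score"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class CohortTable:
    """Per-patient clinical and experimental labels.

    Requires unique ``patient_id``; ``survival_months`` and ``event`` must be
    jointly present or jointly absent per patient.  Any further columns
    (gender, age_at_diagnosis, grade, batch labels, treatment/test flags,
    synthetic ground-truth carrier flags) travel untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        if "patient_id" not in df.columns:
            raise DataMismatchError("cohort table lacks a patient_id column")
        df["patient_id"] = df["patient_id"].astype(str)
        if df["patient_id"].duplicated().any():
            dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
            raise DataMismatchError(f"duplicate patient ids: {dup}")
        if "survival_months" in df.columns or "event" in df.columns:
            surv = df.get("survival_months")
            ev = df.get("event")
            if surv is None or ev is None:
                raise DataMismatchError(
                    "survival_months and event must be provided together"
                )
            if (surv.isna() != ev.isna()).any():
                raise DataMismatchError(
                    "survival_months and event must be jointly present or absent"
                )
            if (surv.dropna() < 0).any():
                raise DataMismatchError("survival_months must be nonnegative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list[str]:
        return self.df["patient_id"].tolist()

    @classmethod
    def read_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class ProfileMatrix:
    """One dataset: bins x patients relative copy numbers with coordinates."""

    values: np.ndarray
    bins: BinTable
    patient_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.values.ndim != 2:
            raise DataMismatchError("profile matrix must be two-dimensional")
        if self.values.shape[0] != len(self.bins):
            raise DataMismatchError(
                f"matrix has {self.values.shape[0]} rows but the bin table has "
                f"{len(self.bins)} bins"
            )
        if self.values.shape[1] != len(self.patient_ids):
            raise DataMismatchError(
                f"matrix has {self.values.shape[1]} columns but "
                f"{len(self.patient_ids)} patient ids were given"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise DataMismatchError("duplicate patient ids in profile matrix")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]


def _read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def _write_matrix_tsv(values: np.ndarray, patient_ids: list[str], path) -> None:
    pd.DataFrame(values, columns=patient_ids).to_csv(path, sep="\t", index=False)


def _read_matrix_hdf5(path) -> tuple[np.ndarray, list[str]]:
    with h5py.File(path, "r") as h5:
        values = np.asarray(h5["values"], dtype=float)
        pids = [p.decode() if isinstance(p, bytes) else str(p) for p in h5["patient_ids"][...]]
    return values, pids


def _write_matrix_hdf5(values: np.ndarray, patient_ids: list[str], path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("values", data=values)
        h5.create_dataset(
            "patient_ids", data=np.array(patient_ids, dtype=h5py.string_dtype())
        )


def _is_hdf5(path) -> bool:
    return str(path).endswith((".h5", ".hdf5"))


def load_profile(matrix_path, bin_path, cohort_path=None) -> ProfileMatrix:
    """Load a profile matrix with its bin table, cross-checking all dimensions.

    The matrix may be TSV (header row = patient ids) or HDF5 (datasets
    ``values`` and ``patient_ids``).  When a cohort table is supplied, every
    matrix patient must appear in it.
    """
    bins = BinTable.read_bed(bin_path)
    values, pids = (_read_matrix_hdf5 if _is_hdf5(matrix_path) else _read_matrix_tsv)(matrix_path)
    if values.shape[0] != len(bins):
        raise DataMismatchError(
            f"matrix {matrix_path} has {values.shape[0]} rows but bin table "
            f"{bin_path} has {len(bins)} bins"
        )
    pm = ProfileMatrix(values=values, bins=bins, patient_ids=pids)
    if cohort_path is not None:
        cohort = CohortTable.read_tsv(cohort_path)
        missing = set(pids) - set(cohort.patient_ids)
        if missing:
            raise DataMismatchError(
                f"matrix patients absent from the cohort table: {sorted(missing)}"
            )
    return pm


def save_profile(pm: ProfileMatrix, matrix_path, bin_path) -> None:
    """Write a profile matrix (TSV or HDF5 by extension) and its BED bin table."""
    (_write_matrix_hdf5 if _is_hdf5(matrix_path) else _write_matrix_tsv)(
        pm.values, pm.patient_ids, matrix_path
    )
    pm.bins.to_bed(bin_path)


def preprocess_counts(raw_counts: np.ndarray, patient_ids: list[str] | None = None) -> np.ndarray:
    """Scale raw bin read counts to relative copy numbers (column mean 1).

    Each patient column is divided by its mean over bins, making the
    genome-wide average exactly 1 (diploid baseline).  Nothing else: no
    per-bin normalization, no GC correction.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.ndim != 2:
        raise DataMismatchError("count matrix must be two-dimensional")
    if np.any(raw < 0):
        raise DataMismatchError("read counts must be nonnegative")
    means = raw.mean(axis=0)
    zero = np.flatnonzero(means == 0)
    if zero.size:
        names = (
            [patient_ids[j] for j in zero] if patient_ids is not None else zero.tolist()
        )
        raise DataMismatchError(f"all-zero count column(s) for patient(s): {names}")
    return raw / means


def match_pair(tumor: ProfileMatrix, normal: ProfileMatrix) -> ProfilePair:
    """Align two profile matrices on their shared patients, tumor first.

    Columns are reordered to the shared id order (tumor order); rows are left
    untouched, so the two bin sets may differ in size and coordinates.
    Patients present in only one dataset are dropped with a warning.
    """
    normal_set = set(normal.patient_ids)
    shared = [p for p in tumor.patient_ids if p in normal_set]
    if not shared:
        raise DataMismatchError("tumor and normal datasets share no patient ids")
    dropped = (set(tumor.patient_ids) | normal_set) - set(shared)
    if dropped:
        warnings.warn(f"dropping unmatched patients: {sorted(dropped)}")
    t_idx = [tumor.patient_ids.index(p) for p in shared]
    n_idx = [normal.patient_ids.index(p) for p in shared]
    return ProfilePair(
        D1=tumor.values[:, t_idx],
        D2=normal.values[:, n_idx],
        patient_ids=shared,
        bins1=tumor.bins,
        bins2=normal.bins,
    )


def gc_from_fasta(bins: BinTable, fasta_path) -> BinTable:
    """Fill the gc_fraction column from a genome FASTA.

    ``gc = (G + C) / (A + C + G + T)`` per bin, case-insensitive; ambiguous
    bases are excluded from the denominator; a bin with no unambiguous bases
    gets NaN.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    missing = set(bins.chrom) - set(seqs)
    if missing:
        raise DataMismatchError(f"chromosomes absent from FASTA: {sorted(missing)}")
    gc_vals = np.empty(len(bins))
    for i, (chrom, start, end) in enumerate(zip(bins.chrom, bins.start, bins.end)):
        seq = seqs[chrom][start:end]
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        gc_vals[i] = gc / (gc + at) if gc + at > 0 else np.nan
    df = bins.df.copy()
    df["gc"] = gc_vals
    return BinTable(df)
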