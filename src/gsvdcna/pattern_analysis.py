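"""Genome-wide CNA patterns: CBS segmentation and segment classification.

A selected column basis vector, laid out along its bin coordinates, is a
genome-wide copy-number pattern.  Circular binary segmentation (CBS)
partitions each chromosome into constant segments: at every step the arc
pair (i, j) maximizing the two-sample t-statistic between the arc and its
complement is found; the split is accepted if its within-segment permutation
p-value falls below ``alpha``; accepted breakpoints are recursed on.  This
variant uses the unweighted t-statistic and no pruning/undo step, so results
are bit-reproducible given the seed.

Segments are then classified as amplified / unaltered / deleted by the
distance, in standard errors, between the segment mean and a reference mean
(all autosomal bins by default, or the segment's chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataMismatchError
from .genome_io import BinTable

__all__ = [
    "CopyNumberPattern",
    "SegmentCall",
    "cbs_segment",
    "classify_segments",
    "compare_patterns",
    "classify_over_segment_list",
    "segments_to_tsv",
    "read_segment_list",
]


@dataclass
class CopyNumberPattern:
    """One column basis vector with genomic coordinates, ready to segment."""

    values: np.ndarray
    bins: BinTable
    source: tuple[int, int] | None = None  # (dataset index, component index)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.bins):
            raise DataMismatchError(
                f"pattern has {self.values.size} values for {len(self.bins)} bins"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataMismatchError("pattern values must be finite")


@dataclass
class SegmentCall:
    """A genomic segment with its mean level and (optionally) a CNA call."""

    chrom: str
    start: int
    end: int
    n_bins: int
    mean_value: float
    z_score: float | None = None
    call: str | None = None  # amplified | unaltered | deleted


def _max_t_split(x: np.ndarray, min_width: int):
    """Best circular arc split of ``x``: (i, j, |t|) or None.

    Considers every arc x[i:j) with both the arc and its complement at least
    ``min_width`` bins long; the statistic is the two-sample t between arc
    and complement means with a pooled (whole-segment) variance.
    """
    n = x.size
    if n < 2 * min_width:
        return None
    var = x.var()
    if var <= 0:
        return None
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    idx = np.arange(n + 1)
    k = idx[None, :] - idx[:, None]  # arc lengths j - i
    valid = (k >= min_width) & (k <= n - min_width)
    kf = np.where(valid, k, 1).astype(float)
    diff = S[None, :] - S[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(diff / kf - (total - diff) / (n - kf)) / np.sqrt(
            var * (1.0 / kf + 1.0 / (n - kf))
        )
    t[~valid] = -np.inf
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return i, j, float(t[i, j])


def _split_significant(
    x: np.ndarray, t_obs: float, alpha: float, n_perm: int, min_width: int, rng
) -> bool:
    """Permutation test of the max-t split with early stopping.

    The p-value estimate is the conservative (1 + exceedances) / (1 + B); the
    loop stops as soon as the final estimate is guaranteed to reach alpha.
    """
    limit = alpha * (1 + n_perm) - 1
    exceed = 0
    for _ in range(n_perm):
        best = _max_t_split(rng.permutation(x), min_width)
        if best is not None and best[2] >= t_obs:
            exceed += 1
            if exceed > limit:
                return False
    return (1 + exceed) / (1 + n_perm) < alpha


def _segment_series(x: np.ndarray, alpha, n_perm, min_width, rng) -> list[int]:
    """Recursive CBS of one chromosome; returns interior breakpoints, sorted."""
    breakpoints: list[int] = []
    stack = [(0, x.size)]
    while stack:
        lo, hi = stack.pop(0)
        seg = x[lo:hi]
        best = _max_t_split(seg, min_width)
        if best is None:
            continue
        i, j, t_obs = best
        if not _split_significant(seg, t_obs, alpha, n_perm, min_width, rng):
            continue
        cuts = sorted({i, j} - {0, seg.size})
        if not cuts:
            continue
        breakpoints.extend(lo + c for c in cuts)
        edges = [lo] + [lo + c for c in cuts] + [hi]
        stack.extend((edges[m], edges[m + 1]) for m in range(len(edges) - 1))
    return sorted(breakpoints)


def cbs_segment(
    pattern: CopyNumberPattern,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> list[SegmentCall]:
    """Circular binary segmentation of a pattern, chromosome by chromosome.

    Returns segments tiling each chromosome (calls unset).  A chromosome
    with fewer than ``2 * min_width`` bins is returned as a single segment
    with a warning.  Deterministic given ``seed``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    segments: list[SegmentCall] = []
    chroms = pd.unique(pattern.bins.chrom)
    for chrom in chroms:
        mask = pattern.bins.chrom == chrom
        x = pattern.values[mask]
        starts = pattern.bins.start[mask]
        ends = pattern.bins.end[mask]
        if x.size < 2 * min_width:
            warnings.warn(
                f"chromosome {chrom} has only {x.size} bins (< 2*min_width); "
                "returned as a single segment"
            )
            bps: list[int] = []
        else:
            bps = _segment_series(x, alpha, n_perm, min_width, rng)
        edges = [0] + bps + [x.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            segments.append(
                SegmentCall(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_bins=hi - lo,
                    mean_value=float(x[lo:hi].mean()),
                )
            )
    return segments


def _segment_bin_mask(seg: SegmentCall, bins: BinTable) -> np.ndarray:
    return (bins.chrom == seg.chrom) & (bins.start < seg.end) & (bins.end > seg.start)


def classify_segments(
    segments: list[SegmentCall],
    pattern: CopyNumberPattern,
    reference: str = "autosome",
    z_threshold: float = 2.0,
) -> list[SegmentCall]:
    """Call each segment amplified / unaltered / deleted against a reference.

    ``z = (segment mean - reference mean) / (reference bin SD / sqrt(n_bins))``,
    i.e. the distance in standard errors of the segment mean; amplified when
    z >= z_threshold, deleted when z <= -z_threshold.  The reference is all
    autosomal bins (default) or the segment's own chromosome
    (``reference="per_chromosome"``).  z is invariant to affine rescaling of
    the pattern.
    """
    if reference not in ("autosome", "per_chromosome"):
        raise ValueError("reference must be 'autosome' or 'per_chromosome'")
    bins = pattern.bins
    if reference == "autosome":
        ref_mask = bins.autosome_mask()
        if not ref_mask.any():
            raise DataMismatchError("no autosomal bins available as reference")
        ref_mean = float(pattern.values[ref_mask].mean())
        ref_sd = float(pattern.values[ref_mask].std())
    out = []
    for seg in segments:
        if reference == "per_chromosome":
            ref_mask = bins.chrom == seg.chrom
            if not ref_mask.any():
                raise DataMismatchError(f"no bins on chromosome {seg.chrom}")
            ref_mean = float(pattern.values[ref_mask].mean())
            ref_sd = float(pattern.values[ref_mask].std())
        if ref_sd == 0:
            z = 0.0
        else:
            z = (seg.mean_value - ref_mean) / (ref_sd / np.sqrt(seg.n_bins))
        call = "amplified" if z >= z_threshold else "deleted" if z <= -z_threshold else "unaltered"
        out.append(replace(seg, z_score=float(z), call=call))
    return out


def compare_patterns(calls_a: list[SegmentCall], calls_b: list[SegmentCall]) -> dict:
    """Bounding comparison of two classified call lists over shared segments.

    Reports agreement counts per class, whether a's altered segments are a
    subset of b's (same alteration sign), magnitude comparisons on shared
    altered segments, and the fraction of a's altered segments consistent
    with "a bounded above by b" (b altered with the same sign and at least
    the magnitude).
    """
    if len(calls_a) != len(calls_b) or any(
        (a.chrom, a.start, a.end) != (b.chrom, b.start, b.end)
        for a, b in zip(calls_a, calls_b)
    ):
        raise DataMismatchError("call lists cover different segment coordinates")
    agree = sum(a.call == b.call for a, b in zip(calls_a, calls_b))
    per_class = {
        cls: sum(a.call == cls and b.call == cls for a, b in zip(calls_a, calls_b))
        for cls in ("amplified", "unaltered", "deleted")
    }
    altered_a = [i for i, a in enumerate(calls_a) if a.call in ("amplified", "deleted")]
    altered_b = {i for i, b in enumerate(calls_b) if b.call in ("amplified", "deleted")}
    subset = all(i in altered_b and calls_b[i].call == calls_a[i].call for i in altered_a)
    shared = [i for i in altered_a if i in altered_b and calls_b[i].call == calls_a[i].call]
    b_larger = sum(abs(calls_b[i].mean_value) >= abs(calls_a[i].mean_value) for i in shared)
    bounded = [
        i
        for i in altered_a
        if i in altered_b
        and calls_b[i].call == calls_a[i].call
        and abs(calls_b[i].mean_value) >= abs(calls_a[i].mean_value)
    ]
    return {
        "n_segments": len(calls_a),
        "n_agree": agree,
        "agreement_fraction": agree / len(calls_a) if calls_a else 1.0,
        "per_class_agreement": per_class,
        "altered_a": len(altered_a),
        "altered_b": len(altered_b),
        "a_subset_of_b": subset,
        "shared_altered": len(shared),
        "b_magnitude_geq_a": b_larger,
        "bounded_fraction": len(bounded) / len(altered_a) if altered_a else 1.0,
    }


def classify_over_segment_list(
    pattern: CopyNumberPattern,
    external_segments: pd.DataFrame,
    reference: str = "autosome",
    z_threshold: float = 2.0,
) -> list[SegmentCall]:
    """Classify a supplied fixed segment list over a pattern.

    Enables cross-technology comparison on a common segment set instead of
    CBS output.  Segments reaching outside the bin range are clipped with a
    warning; segments covering no bins are dropped with a warning.
    """
    segs: list[SegmentCall] = []
    for _, row in external_segments.iterrows():
        chrom, start, end = str(row["chrom"]), int(row["start"]), int(row["end"])
        on_chrom = pattern.bins.chrom == chrom
        if not on_chrom.any():
            warnings.warn(f"segment {chrom}:{start}-{end} covers no bins; dropped")
            continue
        lo = int(pattern.bins.start[on_chrom].min())
        hi = int(pattern.bins.end[on_chrom].max())
        if start < lo or end > hi:
            warnings.warn(f"segment {chrom}:{start}-{end} clipped to [{lo}, {hi})")
            start, end = max(start, lo), min(end, hi)
        mask = on_chrom & (pattern.bins.start < end) & (pattern.bins.end > start)
        if not mask.any():
            warnings.warn(f"segment {chrom}:{start}-{end} covers no bins; dropped")
            continue
        segs.append(
            SegmentCall(
                chrom=chrom,
                start=start,
                end=end,
                n_bins=int(mask.sum()),
                mean_value=float(pattern.values[mask].mean()),
            )
        )
    return classify_segments(segs, pattern, reference=reference, z_threshold=z_threshold)


def segments_to_tsv(segments: list[SegmentCall], path) -> None:
    """Write segment calls as a BED-compatible TSV with a header."""
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "mean_value": [s.mean_value for s in segments],
            "z_score": [s.z_score for s in segments],
            "call": [s.call for s in segments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_segment_list(path) -> pd.DataFrame:
    """Read an external segment list (BED without header, or TSV with one)."""
    first = open(path).readline()
    if first.lower().startswith("chrom"):
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None).rename(
            columns={0: "chrom", 1: "start", 2: "end"}
        )
    df["chrom"] = df["chrom"].astype(str)
    return df[["chrom", "start", "end"]].astype({"start": int, "end": int})
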