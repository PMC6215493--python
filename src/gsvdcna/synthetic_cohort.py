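"""Synthetic patient-matched tumor/normal cohorts with planted ground truth.

The generator emulates the structure of a WGS astrocytoma-style cohort at
desk scale: two column-matched matrices of binned relative copy numbers with
unequal row counts (the normal bin set carries a few extra bins), a
tumor-exclusive genome-wide CNA pattern carried by a patient subset and
linked to shorter survival, a male-specific deletion of the X chromosome
common to tumor and normal, a GC-content-dependent read-count depression
whose magnitude varies by (independent) tumor- and normal-side experimental
batches, and negative-binomial count noise.

Defaults follow the emulated cohort: 85 patients, 52 of them pattern
carriers (the short-survival phenotype, planted median 12 vs 60 months),
53 male, ~20K 1K-nucleotide bins over the 22 autosomes plus X.  The GC
artifact is multiplicative, exp(slope * (gc - mean_gc)) with positive
slopes, so GC-poor bins show reduced counts (PCR underestimation); slopes
differ between batches, and tumor and normal batches are assigned
independently so the tumor- and normal-side artifacts separate into
distinct exclusive components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import association_tests, patient_classification
from .core_gsvd import GSVDResult, ProfilePair
from .errors import DataMismatchError
from .genome_io import BinTable, CohortTable, ProfileMatrix, preprocess_counts

__all__ = [
    "CnaSegment",
    "SimulationConfig",
    "GroundTruth",
    "generate",
    "evaluate_recovery",
    "simulate_survival_cohort",
]

_AUTOSOMES = tuple(str(i) for i in range(1, 23))


@dataclass(frozen=True)
class CnaSegment:
    """One planted alteration: chromosome, fractional span, copy change."""

    chrom: str
    start_frac: float
    end_frac: float
    delta_copies: float


#: the planted tumor-exclusive pattern: a glioma-like set of co-occurring
#: autosomal CNAs (whole-chromosome gain of 7, losses of 10 and 9p, partial
#: gains/losses elsewhere); the X chromosome is left unaltered.
DEFAULT_CNA_SEGMENTS = (
    CnaSegment("7", 0.0, 1.0, +1.0),
    CnaSegment("10", 0.0, 1.0, -1.0),
    CnaSegment("9", 0.0, 0.45, -1.0),
    CnaSegment("19", 0.4, 1.0, +0.6),
    CnaSegment("20", 0.0, 1.0, +0.6),
    CnaSegment("1", 0.55, 0.62, +1.0),
    CnaSegment("13", 0.2, 0.8, -0.5),
    CnaSegment("4", 0.3, 0.55, -0.5),
)


def default_segments_for(chromosomes) -> tuple[CnaSegment, ...]:
    """The default planted pattern restricted to the available chromosomes."""
    segs = tuple(s for s in DEFAULT_CNA_SEGMENTS if s.chrom in chromosomes)
    if not segs:
        raise DataMismatchError(
            "none of the default planted segments fall on the chosen "
            "chromosomes; supply cna_segments explicitly"
        )
    return segs


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_patients: int = 85
    chromosomes: tuple[str, ...] = _AUTOSOMES + ("X",)
    bins_per_chromosome: int = 870
    bin_size: int = 1000
    carrier_fraction: float = 52 / 85
    cna_segments: tuple[CnaSegment, ...] = DEFAULT_CNA_SEGMENTS
    cna_magnitude_scale: float = 1.0
    carrier_median_survival: float = 12.0
    noncarrier_median_survival: float = 60.0
    hazard_ratio: float | None = None  # overrides carrier median when set
    censoring_fraction: float = 0.2
    male_fraction: float = 53 / 85
    x_deletion_copies: float = 1.0
    gc_mean: float = 0.41
    gc_sd: float = 0.055
    # positive slope => counts rise with GC => GC-poor bins depressed
    tumor_batch_slopes: dict[str, float] = field(
        default_factory=lambda: {"GCC1": 1.8, "GCC2": 1.0, "GCC3": 0.3}
    )
    normal_batch_slopes: dict[str, float] = field(
        default_factory=lambda: {"TSS1": 1.7, "TSS2": 1.2, "TSS3": 0.7, "TSS4": 0.25}
    )
    slope_jitter_sd: float = 0.1
    noise: str = "nb"  # nb | gaussian | none
    nb_dispersion: float = 0.02
    gaussian_sd: float = 0.15
    mean_depth: float = 300.0
    extra_normal_bins: int = 25
    seed: int = 0

    def validate(self) -> None:
        for name in ("carrier_fraction", "male_fraction", "censoring_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataMismatchError(f"{name} must lie in [0, 1], got {v}")
        if len(self.chromosomes) < 2:
            raise DataMismatchError("at least two chromosomes are required")
        if self.n_patients < 2 or self.bins_per_chromosome < 1:
            raise DataMismatchError("cohort and bin counts must be positive")
        if self.noise not in ("nb", "gaussian", "none"):
            raise DataMismatchError("noise must be 'nb', 'gaussian', or 'none'")
        for seg in self.cna_segments:
            if not (0.0 <= seg.start_frac < seg.end_frac <= 1.0):
                raise DataMismatchError(f"bad fractional span in {seg}")
            if seg.chrom not in self.chromosomes:
                raise DataMismatchError(f"planted segment on unknown chromosome {seg.chrom}")
            if not np.isfinite(seg.delta_copies):
                raise DataMismatchError("planted magnitudes must be finite")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery evaluation."""

    carrier: np.ndarray  # bool per patient
    gender: np.ndarray  # "male"/"female" per patient
    tumor_batch: np.ndarray
    normal_batch: np.ndarray
    true_median_survival: np.ndarray  # planted median per patient (months)
    pattern: np.ndarray  # relative copy-number deviation per tumor bin
    pattern_mask: np.ndarray  # bool per tumor bin
    breakpoints: dict[str, list[int]]  # per-chromosome bin-index breakpoints
    gc: np.ndarray  # per normal bin (tumor bins are the first M1 of these)
    expected_copies_tumor: np.ndarray
    expected_copies_normal: np.ndarray


def _make_bins(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    m, sd = config.gc_mean, config.gc_sd
    nu = m * (1 - m) / sd**2 - 1
    a, b = m * nu, (1 - m) * nu
    rows = []
    for chrom in config.chromosomes:
        n = config.bins_per_chromosome
        if chrom == config.chromosomes[-1]:
            n += config.extra_normal_bins
        starts = np.arange(n) * config.bin_size
        gc = rng.beta(a, b, size=n)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + config.bin_size, "gc": gc}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _pattern_vector(config: SimulationConfig, bins: pd.DataFrame) -> tuple[np.ndarray, dict]:
    delta = np.zeros(len(bins))
    breakpoints: dict[str, set] = {}
    for seg in config.cna_segments:
        on = np.flatnonzero(bins["chrom"].to_numpy() == seg.chrom)
        n = on.size
        lo, hi = int(round(seg.start_frac * n)), int(round(seg.end_frac * n))
        delta[on[lo:hi]] += seg.delta_copies * config.cna_magnitude_scale
        bps = breakpoints.setdefault(seg.chrom, set())
        if lo > 0:
            bps.add(lo)
        if hi < n:
            bps.add(hi)
    return delta, {c: sorted(b) for c, b in breakpoints.items()}


def _censoring_horizon(lams, weights, fraction):
    """Uniform-censoring horizon c with E[censored fraction] = ``fraction``.

    For exponential event times with rate lam and independent C ~ U(0, c),
    P(censored) = (1 - exp(-lam c)) / (lam c); the mixture over groups is
    monotone in c, solved by bisection.
    """

    def expected_fraction(c):
        return sum(
            w * (1 - np.exp(-l * c)) / (l * c) for l, w in zip(lams, weights)
        ) - fraction

    return brentq(expected_fraction, 1e-9, 1e9)


def _draw_survival(rng, lam, censoring_fraction):
    """Exponential event times under independent uniform censoring."""
    t_event = rng.exponential(1.0 / lam)
    if censoring_fraction <= 0:
        return t_event, np.ones(lam.size, dtype=int)
    lams, counts = np.unique(lam, return_counts=True)
    c_max = _censoring_horizon(lams, counts / lam.size, censoring_fraction)
    c = rng.uniform(0.0, c_max, lam.size)
    return np.minimum(t_event, c), (t_event <= c).astype(int)


def _counts(copies, gc_dev, slopes, config, rng):
    mu = config.mean_depth * (copies / 2.0) * np.exp(np.outer(gc_dev, slopes))
    if config.noise == "none":
        return mu
    if config.noise == "gaussian":
        return np.maximum(mu * (1.0 + rng.normal(0.0, config.gaussian_sd, mu.shape)), 0.0)
    lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * mu)
    return rng.poisson(lam).astype(float)


def generate(
    config: SimulationConfig | None = None,
) -> tuple[ProfileMatrix, ProfileMatrix, CohortTable, GroundTruth]:
    """Generate a matched tumor/normal cohort; fully reproducible from the seed."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    all_bins = _make_bins(config, rng)
    m2 = len(all_bins)
    m1 = m2 - config.extra_normal_bins
    tumor_bins = BinTable(all_bins.iloc[:m1])
    normal_bins = BinTable(all_bins)
    gc = all_bins["gc"].to_numpy()
    gc_dev = gc - config.gc_mean

    n = config.n_patients
    ids = [f"P{i + 1:03d}" for i in range(n)]
    n_carriers = int(round(config.carrier_fraction * n))
    carrier = np.zeros(n, dtype=bool)
    carrier[rng.choice(n, n_carriers, replace=False)] = True
    n_males = int(round(config.male_fraction * n))
    male = np.zeros(n, dtype=bool)
    male[rng.choice(n, n_males, replace=False)] = True

    t_batches = list(config.tumor_batch_slopes)
    n_batches = list(config.normal_batch_slopes)
    tumor_batch = rng.choice(t_batches, size=n)
    normal_batch = rng.choice(n_batches, size=n)
    t_slopes = np.array(
        [config.tumor_batch_slopes[b] for b in tumor_batch]
    ) + rng.normal(0.0, config.slope_jitter_sd, n)
    n_slopes = np.array(
        [config.normal_batch_slopes[b] for b in normal_batch]
    ) + rng.normal(0.0, config.slope_jitter_sd, n)

    x_mask_all = (all_bins["chrom"] == "X").to_numpy()
    copies_normal = np.full((m2, n), 2.0)
    copies_normal[np.ix_(x_mask_all, male)] -= config.x_deletion_copies

    pattern_delta, breakpoints = _pattern_vector(config, all_bins.iloc[:m1])
    copies_tumor = copies_normal[:m1].copy()
    copies_tumor[:, carrier] += pattern_delta[:, None]
    copies_tumor = np.maximum(copies_tumor, 0.1)

    tumor_counts = _counts(copies_tumor, gc_dev[:m1], t_slopes, config, rng)
    normal_counts = _counts(copies_normal, gc_dev, n_slopes, config, rng)
    tumor = ProfileMatrix(preprocess_counts(tumor_counts, ids), tumor_bins, ids)
    normal = ProfileMatrix(preprocess_counts(normal_counts, ids), normal_bins, ids)

    # survival: exponential per group under independent uniform censoring
    # calibrated to the configured expected censoring fraction
    lam0 = np.log(2.0) / config.noncarrier_median_survival
    lam1 = (
        lam0 * config.hazard_ratio
        if config.hazard_ratio is not None
        else np.log(2.0) / config.carrier_median_survival
    )
    lam = np.where(carrier, lam1, lam0)
    time, event = _draw_survival(rng, lam, config.censoring_fraction)

    age = np.clip(rng.normal(55.0, 12.0, n), 18, 90).round(1)
    grade_p = np.where(carrier[:, None], [[0.1, 0.2, 0.7]], [[0.35, 0.35, 0.3]])
    grade = np.array([rng.choice(["II", "III", "IV"], p=p) for p in grade_p])

    cohort = CohortTable(
        pd.DataFrame(
            {
                "patient_id": ids,
                "survival_months": np.round(time, 2),
                "event": event,
                "gender": np.where(male, "male", "female"),
                "age_at_diagnosis": age,
                "grade": grade,
                "gcc_batch": tumor_batch,
                "tss_batch": normal_batch,
                "carrier": carrier.astype(int),
            }
        )
    )
    truth = GroundTruth(
        carrier=carrier,
        gender=np.where(male, "male", "female"),
        tumor_batch=np.asarray(tumor_batch),
        normal_batch=np.asarray(normal_batch),
        true_median_survival=np.where(
            carrier, np.log(2.0) / lam1, config.noncarrier_median_survival
        ),
        pattern=pattern_delta / 2.0,
        pattern_mask=pattern_delta != 0,
        breakpoints=breakpoints,
        gc=gc,
        expected_copies_tumor=copies_tumor,
        expected_copies_normal=copies_normal,
    )
    return tumor, normal, cohort, truth


@dataclass
class RecoveryReport:
    """How well the decomposition recovered the planted effects."""

    pattern_component: int
    pattern_r: float
    pattern_theta: float
    gc_component: tuple[int, int]  # (dataset, component)
    gc_r: float
    gender_component: int
    gender_theta: float
    gender_enrichment_p: float
    classification_accuracy: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _abs_pearson_with(U: np.ndarray, target: np.ndarray) -> np.ndarray:
    Uc = U - U.mean(axis=0)
    tc = target - target.mean()
    denom = np.linalg.norm(Uc, axis=0) * np.linalg.norm(tc)
    return np.abs(Uc.T @ tc) / denom


def evaluate_recovery(
    result: GSVDResult,
    truth: GroundTruth,
    pair: ProfilePair | None = None,
) -> RecoveryReport:
    """Match components to the planted effects and score the recovery.

    The pattern component is the tumor column basis vector most correlated
    (|Pearson r|) with the planted pattern; the GC component the basis
    vector (either dataset) most correlated with its bin GC; the gender
    component the one whose row basis vector's sign split is most enriched
    for one gender (hypergeometric).  Classification accuracy against the
    planted carrier flags is computed when the pair is supplied.
    """
    m1 = result.U1.shape[0]
    r_pattern = _abs_pearson_with(result.U1, truth.pattern)
    k_pat = int(np.argmax(r_pattern))

    r_gc1 = _abs_pearson_with(result.U1, truth.gc[:m1])
    r_gc2 = _abs_pearson_with(result.U2, truth.gc)
    if r_gc1.max() >= r_gc2.max():
        gc_comp, gc_r = (1, int(np.argmax(r_gc1))), float(r_gc1.max())
    else:
        gc_comp, gc_r = (2, int(np.argmax(r_gc2))), float(r_gc2.max())

    males = {i for i, g in enumerate(truth.gender) if g == "male"}
    females = set(range(truth.gender.size)) - males
    n = truth.gender.size
    best_p, k_gender = 1.1, 0
    for k in range(result.n_components):
        pos = set(np.flatnonzero(association_tests.sign_split(result.VT[k])))
        for side in (pos, set(range(n)) - pos):
            for gender_set in (males, females):
                p = association_tests.hypergeometric_enrichment(gender_set, side, n)
                if p < best_p:
                    best_p, k_gender = p, k
    accuracy = None
    if pair is not None:
        u = result.U1[:, k_pat].copy()
        if np.dot(u - u.mean(), truth.pattern - truth.pattern.mean()) < 0:
            u = -u
        coeffs = patient_classification.superposition_coefficients(pair.D1, u)
        corrs = patient_classification.pattern_correlations(pair.D1, u)
        labels = patient_classification.classify(corrs, coeffs).high_by_correlation
        accuracy = float(np.mean(labels == truth.carrier))
    return RecoveryReport(
        pattern_component=k_pat,
        pattern_r=float(r_pattern[k_pat]),
        pattern_theta=float(result.theta[k_pat]),
        gc_component=gc_comp,
        gc_r=gc_r,
        gender_component=k_gender,
        gender_theta=float(result.theta[k_gender]),
        gender_enrichment_p=float(best_p),
        classification_accuracy=accuracy,
    )


def simulate_survival_cohort(
    n_patients: int = 85,
    carrier_fraction: float = 52 / 85,
    noncarrier_median: float = 60.0,
    carrier_median: float | None = 12.0,
    hazard_ratio: float | None = None,
    censoring_fraction: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Survival-only cohort draw (no profiles) for Monte-Carlo calibration.

    Exponential event times with the planted group medians (or hazard
    ratio), uniform censoring of a ``censoring_fraction`` of patients.
    """
    rng = np.random.default_rng(seed)
    n_carriers = int(round(carrier_fraction * n_patients))
    carrier = np.zeros(n_patients, dtype=bool)
    carrier[rng.choice(n_patients, n_carriers, replace=False)] = True
    lam0 = np.log(2.0) / noncarrier_median
    lam1 = lam0 * hazard_ratio if hazard_ratio is not None else np.log(2.0) / carrier_median
    time, event = _draw_survival(rng, np.where(carrier, lam1, lam0), censoring_fraction)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n_patients)],
            "survival_months": time,
            "event": event,
            "carrier": carrier.astype(int),
        }
    )
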