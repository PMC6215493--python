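"""Classify patients by the weight of a tumor pattern in their profiles.

Two routes, which the data should make agree: (1) superposition coefficients,
the projections of each (bin-centered) tumor profile on the unit pattern —
across patients this vector is proportional to the corresponding row basis
vector of the GSVD when the profiles are column-centered; (2) Pearson
correlations of each tumor profile with the pattern.  Patients are called
"high" (pattern carriers, the short-survival phenotype) by a correlation
cutoff of 0.15; the coefficient cutoff is the same threshold transported to
the coefficient scale via the norms of the two vectors, so that the two
rules coincide exactly whenever coefficients are proportional to
correlations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataMismatchError

__all__ = [
    "ClassificationResult",
    "superposition_coefficients",
    "pattern_correlations",
    "classify",
]

DEFAULT_CORRELATION_CUTOFF = 0.15


@dataclass
class ClassificationResult:
    """Per-patient coefficients, correlations, and high/low labels."""

    coefficients: np.ndarray
    correlations: np.ndarray
    high_by_coefficient: np.ndarray
    high_by_correlation: np.ndarray
    correlation_cutoff: float
    coefficient_cutoff: float
    patient_ids: list[str] | None = None

    def agreement(self) -> float:
        """Fraction of patients labeled identically by the two rules."""
        return float(np.mean(self.high_by_coefficient == self.high_by_correlation))

    def to_frame(self) -> pd.DataFrame:
        ids = self.patient_ids or [str(i) for i in range(self.coefficients.size)]
        return pd.DataFrame(
            {
                "patient_id": ids,
                "coefficient": self.coefficients,
                "correlation": self.correlations,
                "high_coeff": self.high_by_coefficient.astype(int),
                "high_corr": self.high_by_correlation.astype(int),
            }
        )

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "correlation_cutoff": self.correlation_cutoff,
                        "coefficient_cutoff": self.coefficient_cutoff,
                    },
                    fh,
                    indent=2,
                )


def superposition_coefficients(
    D_tumor: np.ndarray, pattern_vector: np.ndarray, center: bool = True
) -> np.ndarray:
    """Projection of each patient's profile on the unit-normalized pattern.

    With ``center=True`` (default) both the pattern and every profile are
    centered over bins first, so coefficients differ from Pearson
    correlations only by per-patient norm factors.
    """
    D = np.asarray(D_tumor, dtype=float)
    v = np.asarray(pattern_vector, dtype=float)
    if D.ndim != 2 or v.ndim != 1 or D.shape[0] != v.size:
        raise DataMismatchError(
            f"profile matrix rows ({D.shape[0] if D.ndim == 2 else '?'}) must "
            f"match pattern length ({v.size})"
        )
    if center:
        v = v - v.mean()
        D = D - D.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise DataMismatchError("pattern vector is constant; no direction to project on")
    return D.T @ (v / norm)


def pattern_correlations(D_tumor: np.ndarray, pattern_vector: np.ndarray) -> np.ndarray:
    """Pearson correlation of every patient profile with the pattern.

    Constant profiles get NaN with a warning; a constant pattern is an error.
    """
    D = np.asarray(D_tumor, dtype=float)
    v = np.asarray(pattern_vector, dtype=float)
    if D.ndim != 2 or D.shape[0] != v.size:
        raise DataMismatchError("profile matrix rows must match pattern length")
    vc = v - v.mean()
    v_norm = np.linalg.norm(vc)
    if v_norm == 0:
        raise DataMismatchError("pattern vector is constant; correlation undefined")
    Dc = D - D.mean(axis=0)
    norms = np.linalg.norm(Dc, axis=0)
    const = norms == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant profile(s); correlation set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Dc.T @ vc) / (norms * v_norm)
    r[const] = np.nan
    return r


def classify(
    correlations: np.ndarray,
    coefficients: np.ndarray,
    correlation_cutoff: float = DEFAULT_CORRELATION_CUTOFF,
    rule: str = "normalized",
    patient_ids: list[str] | None = None,
) -> ClassificationResult:
    """Label patients high/low by correlation and by coefficient.

    high_by_correlation: r_j >= correlation_cutoff (signed, not absolute —
    high means positively carrying the pattern).  high_by_coefficient under
    the default ``rule="normalized"``: c_j / ||c|| >= correlation_cutoff /
    ||r||, the reading under which the two rules coincide exactly when
    c is proportional to r.  ``rule="literal"`` instead thresholds c_j at
    correlation_cutoff * ||r|| (the plain product reading).
    """
    r = np.asarray(correlations, dtype=float)
    c = np.asarray(coefficients, dtype=float)
    if r.shape != c.shape or r.ndim != 1 or r.size < 2:
        raise DataMismatchError("correlations and coefficients must be equal-length vectors (N >= 2)")
    c_norm = float(np.linalg.norm(c))
    if c_norm == 0:
        raise DataMismatchError("coefficient vector is all zero")
    r_norm = float(np.linalg.norm(r[np.isfinite(r)]))
    if r_norm == 0:
        raise DataMismatchError("correlation vector is all zero")
    if rule == "normalized":
        coefficient_cutoff = correlation_cutoff * c_norm / r_norm
    elif rule == "literal":
        coefficient_cutoff = correlation_cutoff * r_norm
    else:
        raise ValueError("rule must be 'normalized' or 'literal'")
    with np.errstate(invalid="ignore"):
        high_corr = np.where(np.isfinite(r), r >= correlation_cutoff, False)
    return ClassificationResult(
        coefficients=c,
        correlations=r,
        high_by_coefficient=c >= coefficient_cutoff,
        high_by_correlation=high_corr,
        correlation_cutoff=float(correlation_cutoff),
        coefficient_cutoff=float(coefficient_cutoff),
        patient_ids=patient_ids,
    )
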