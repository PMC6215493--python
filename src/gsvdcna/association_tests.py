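"""Associate basis vectors with experimental and biological labels.

The decomposition is blind to all labels; these tests are how recovered
components are interpreted afterwards: Pearson correlation of a column basis
vector with per-bin GC content (the PCR-dependent sequencing artifact
depresses GC-poor bins), Mann-Whitney-Wilcoxon rank-sum comparisons
(GC-poor vs GC-rich bins, X vs autosomal bins, expression between patient
groups), and hypergeometric enrichment of patient subsets (batch, gender)
in the sign-classes of a row basis vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataMismatchError
from .genome_io import BinTable

__all__ = [
    "AssociationReport",
    "mww_test",
    "hypergeometric_enrichment",
    "correlate_vector_with_gc",
    "x_deletion_test",
    "expression_consistency",
    "sign_split",
]

#: exact MWW enumeration is used when n_a * n_b does not exceed this
EXACT_MWW_LIMIT = 400


@dataclass
class AssociationReport:
    """One association between a component and a label."""

    component: int
    dataset: int
    label: str
    statistic_type: str  # pearson | mww | hypergeometric
    statistic: float
    p_value: float
    direction: str | None = None


def mww_test(values_a, values_b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney-Wilcoxon rank-sum test: (U statistic, p-value).

    Exact enumeration when ``n_a * n_b <= 400`` and there are no ties;
    otherwise the tie-corrected normal approximation with continuity
    correction.  A fully tied comparison returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataMismatchError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (a.size * b.size <= EXACT_MWW_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def hypergeometric_enrichment(label_positive, class_positive, n_total: int) -> float:
    """Upper-tail P(X >= observed overlap) for the hypergeometric law.

    ``label_positive`` and ``class_positive`` are patient subsets of a cohort
    of ``n_total``; the margins are their sizes.
    """
    label = set(label_positive)
    cls = set(class_positive)
    if len(label) > n_total or len(cls) > n_total:
        raise DataMismatchError("a subset exceeds the cohort size")
    overlap = len(label & cls)
    return float(stats.hypergeom.sf(overlap - 1, n_total, len(label), len(cls)))


def sign_split(row_basis_vector) -> np.ndarray:
    """Default patient-group conversion of a row basis vector: sign >= 0."""
    return np.asarray(row_basis_vector, dtype=float) >= 0


def correlate_vector_with_gc(basis_vector, bins: BinTable) -> dict:
    """Pearson r of a column basis vector with bin GC, plus a GC-quartile MWW.

    The MWW compares vector entries of the lowest-GC quartile of bins
    against the highest-GC quartile, capturing spikes of reduced copy
    numbers in GC-poor bins.
    """
    v = np.asarray(basis_vector, dtype=float)
    gc = bins.gc
    if v.size != len(bins):
        raise DataMismatchError("basis vector length must match the bin table")
    if not np.all(np.isfinite(gc)):
        raise DataMismatchError("gc_fraction must be present for all bins")
    if np.unique(gc).size == 1:
        raise DataMismatchError("GC content is constant; correlation undefined")
    r, p = stats.pearsonr(v, gc)
    q1, q3 = np.quantile(gc, [0.25, 0.75])
    u, p_mww = mww_test(v[gc <= q1], v[gc >= q3])
    poor, rich = v[gc <= q1].mean(), v[gc >= q3].mean()
    return {
        "pearson_r": float(r),
        "pearson_p": float(p),
        "mww_u": u,
        "mww_p": p_mww,
        "gc_poor_mean": float(poor),
        "gc_rich_mean": float(rich),
        "direction": "gc_poor_lower" if poor < rich else "gc_poor_higher",
    }


def x_deletion_test(basis_vector, bins: BinTable) -> dict:
    """MWW of X-chromosome vs autosomal entries of a column basis vector.

    Direction reports 'deletion' when X entries run lower than autosomal
    ones, 'amplification' when higher, None when indistinguishable.
    """
    v = np.asarray(basis_vector, dtype=float)
    if v.size != len(bins):
        raise DataMismatchError("basis vector length must match the bin table")
    x_mask = bins.x_mask()
    auto_mask = bins.autosome_mask()
    if not x_mask.any():
        raise DataMismatchError("bin table contains no X-chromosome bins")
    if not auto_mask.any():
        raise DataMismatchError("bin table contains no autosomal bins")
    u, p = mww_test(v[x_mask], v[auto_mask])
    mx, ma = v[x_mask].mean(), v[auto_mask].mean()
    if mx < ma:
        direction = "deletion"
    elif mx > ma:
        direction = "amplification"
    else:
        direction = None
    return {"mww_u": u, "mww_p": p, "direction": direction, "x_mean": float(mx), "autosome_mean": float(ma)}


def expression_consistency(
    expression_matrix: pd.DataFrame,
    group_labels,
    cna_calls_per_gene: dict[str, str],
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-gene MWW between patient groups and CNA-consistency summary.

    ``expression_matrix`` is genes x patients; ``group_labels`` a boolean
    carrier flag per patient column; ``cna_calls_per_gene`` maps gene to
    amplified/unaltered/deleted.  A gene is consistent when it is
    significantly higher in carriers and amplified, or lower and deleted.
    Returns the per-gene table and the consistent fraction among significant
    genes (a Bonferroni-adjusted column is included as a convenience; the
    summary uses raw p-values).
    """
    labels = np.asarray(group_labels, dtype=bool)
    if labels.size != expression_matrix.shape[1]:
        raise DataMismatchError("group labels must match the patient columns")
    if labels.all() or not labels.any():
        raise DataMismatchError("both patient groups must be nonempty")
    rows = []
    n_genes = len(expression_matrix)
    for gene, expr in expression_matrix.iterrows():
        vals = expr.to_numpy(dtype=float)
        if np.unique(vals).size == 1:
            warnings.warn(f"gene {gene} has constant expression; skipped")
            continue
        u, p = mww_test(vals[labels], vals[~labels])
        direction = "up" if np.median(vals[labels]) > np.median(vals[~labels]) else "down"
        call = cna_calls_per_gene.get(str(gene), "unaltered")
        significant = p < p_threshold
        consistent = significant and (
            (direction == "up" and call == "amplified")
            or (direction == "down" and call == "deleted")
        )
        rows.append(
            {
                "gene": gene,
                "mww_u": u,
                "mww_p": p,
                "mww_p_bonferroni": min(1.0, p * n_genes),
                "direction": direction,
                "cna_call": call,
                "significant": significant,
                "consistent": consistent,
            }
        )
    table = pd.DataFrame(rows)
    n_sig = int(table["significant"].sum()) if len(table) else 0
    fraction = float(table["consistent"].sum() / n_sig) if n_sig else float("nan")
    return table, fraction
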