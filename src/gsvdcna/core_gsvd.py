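"""Comparative spectral decomposition (GSVD) of two column-matched matrices.

Given two real matrices ``D1`` (M1 x N) and ``D2`` (M2 x N) whose columns are
matched one-to-one (here: patients) but whose rows are independent (here:
genomic bins from two different bin sets), the generalized singular value
decomposition is the exact simultaneous factorization

    D_i = U_i @ Sigma_i @ VT,          i = 1, 2,

with ``U_i`` column-wise orthonormal (M_i x N), ``Sigma_i`` diagonal with
positive generalized singular values ``sigma_{i,n}``, and ``VT`` (N x N)
invertible with unit-norm rows shared by both datasets.  Components are
ordered by decreasing ratio ``sigma_{1,n} / sigma_{2,n}``, so the most
D1-exclusive components come first and the most D2-exclusive last.

The per-component "angular distance"

    theta_n = arctan(sigma_{1,n} / sigma_{2,n}) - pi/4,   -pi/4 < theta_n < pi/4,

derived from the cosine-sine decomposition, measures exclusivity: theta near
+pi/4 means the component is almost absent from D2 (exclusive to D1), near
-pi/4 exclusive to D2, and near 0 common to both.  Per-dataset "generalized
fractions" (significance weights proportional to a power of sigma) and their
normalized Shannon entropy summarize how concentrated each dataset's
information is across components.

Algorithm: each D_i is reduced by a thin QR factorization to an N x N
triangular factor; the small GSVD of the stacked factor pair is solved through
the cosine-sine decomposition (computed via an SVD of one block of the
stacked orthonormal factor) and back-transformed.  No M_i x M_i object is
ever materialized, so the routine scales to millions of bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import DataMismatchError, NumericalError, RankDeficiencyError

__all__ = [
    "ProfilePair",
    "GSVDResult",
    "ComponentCall",
    "gsvd",
    "angular_distance",
    "generalized_fractions",
    "generalized_entropy",
    "call_components",
    "save_gsvd_hdf5",
    "load_gsvd_hdf5",
    "calls_to_tsv",
]

QUARTER_PI = np.pi / 4.0

#: default exclusivity threshold on |theta| for component calls (radians)
DEFAULT_THETA_THRESHOLD = np.pi / 8.0
#: default significance threshold on the generalized fraction
DEFAULT_FRACTION_THRESHOLD = 0.01


@dataclass
class ProfilePair:
    """Two column-matched, row-independent relative copy-number matrices.

    Columns (patients) are matched one-to-one and share ``patient_ids``;
    rows (bins) are independent, so ``M1 != M2`` is legal.  Optional bin
    tables carry the genomic coordinates of the rows of each matrix.
    """

    D1: np.ndarray
    D2: np.ndarray
    patient_ids: list[str]
    bins1: object | None = None  # genome_io.BinTable, kept untyped to avoid a cycle
    bins2: object | None = None

    def __post_init__(self) -> None:
        self.D1 = np.asarray(self.D1, dtype=float)
        self.D2 = np.asarray(self.D2, dtype=float)
        self.patient_ids = [str(p) for p in self.patient_ids]
        if self.D1.ndim != 2 or self.D2.ndim != 2:
            raise DataMismatchError("profile matrices must be two-dimensional")
        n = len(self.patient_ids)
        if len(set(self.patient_ids)) != n:
            raise DataMismatchError("patient_ids contain duplicates")
        if self.D1.shape[1] != n or self.D2.shape[1] != n:
            raise DataMismatchError(
                f"column counts ({self.D1.shape[1]}, {self.D2.shape[1]}) do not "
                f"match the {n} patient ids"
            )
        if n > min(self.D1.shape[0], self.D2.shape[0]):
            raise DataMismatchError(
                "more patients than bins: the GSVD requires N <= min(M1, M2)"
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class GSVDResult:
    """Exact GSVD of a :class:`ProfilePair`, ordered by decreasing sigma1/sigma2.

    ``fractions_i`` are the generalized fractions of dataset i (sum to 1) and
    ``entropy_i`` their normalized Shannon entropy in [0, 1].
    ``degenerate_groups`` lists index sets of components whose ratios are
    equal within tolerance; basis vectors inside such a subspace are valid
    but not unique.
    """

    U1: np.ndarray
    U2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    VT: np.ndarray
    theta: np.ndarray
    fractions1: np.ndarray
    fractions2: np.ndarray
    entropy1: float
    entropy2: float
    degenerate_groups: list[list[int]] = field(default_factory=list)
    patient_ids: list[str] | None = None
    fraction_exponent: int = 2

    @property
    def n_components(self) -> int:
        return self.sigma1.size

    @property
    def ratios(self) -> np.ndarray:
        return self.sigma1 / self.sigma2

    def reconstruct(self, dataset: int) -> np.ndarray:
        """Recompute ``D_i`` from the factors (dataset in {1, 2})."""
        if dataset == 1:
            return (self.U1 * self.sigma1) @ self.VT
        if dataset == 2:
            return (self.U2 * self.sigma2) @ self.VT
        raise ValueError("dataset must be 1 or 2")


@dataclass
class ComponentCall:
    """Exclusivity call for one component, determined by theta and fractions."""

    index: int
    call: str  # exclusive_to_1 | exclusive_to_2 | common | unassigned
    theta: float
    fraction1: float
    fraction2: float


def angular_distance(sigma1_n, sigma2_n):
    """Angular distance arctan(sigma1/sigma2) - pi/4, in (-pi/4, pi/4).

    Antisymmetric under exchange of the two arguments; 0 when the two
    generalized singular values are equal (component common to both
    datasets); approaches +-pi/4 as the ratio diverges (component exclusive
    to one dataset).  Accepts scalars or arrays.
    """
    s1 = np.asarray(sigma1_n, dtype=float)
    s2 = np.asarray(sigma2_n, dtype=float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("generalized singular values must be positive")
    out = np.arctan2(s1, s2) - QUARTER_PI
    return float(out) if out.ndim == 0 else out


def generalized_fractions(sigma, exponent: int = 2) -> np.ndarray:
    """Significance weight of each component in one dataset.

    ``p_n = sigma_n**k / sum_m sigma_m**k`` with k = ``exponent``; k=2 is the
    variance-like convention of the GSVD literature, k=1 weights by the
    generalized singular values themselves.  Order-preserving; sums to 1.
    """
    s = np.asarray(sigma, dtype=float)
    if np.any(s <= 0):
        raise ValueError("generalized singular values must be positive")
    if exponent not in (1, 2):
        raise ValueError("fraction exponent must be 1 or 2")
    w = s**exponent
    return w / w.sum()


def generalized_entropy(p) -> float:
    """Normalized Shannon entropy -sum p log p / log N, in [0, 1].

    0 when one component carries everything, 1 when all components are
    equally significant.  0*log(0) is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        raise ValueError("entropy needs at least two components (log N scale)")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("input must be a probability vector")
    pz = p[p > 0]
    return float(-(pz * np.log(pz)).sum() / np.log(p.size))


def _check_rank(R: np.ndarray, name: str, tol: float) -> np.ndarray:
    sv = np.linalg.svd(R, compute_uv=False)
    cutoff = tol * sv[0]
    if sv[-1] <= cutoff:
        rank = int(np.count_nonzero(sv > cutoff))
        raise RankDeficiencyError(
            f"{name} is numerically rank deficient: numerical rank {rank} < "
            f"{R.shape[1]} columns (smallest singular value {sv[-1]:.3e} <= "
            f"{cutoff:.3e})"
        )
    return sv


def _degenerate_groups(ratios: np.ndarray, rtol: float) -> list[list[int]]:
    groups: list[list[int]] = []
    current = [0]
    for i in range(1, ratios.size):
        if abs(ratios[i] - ratios[i - 1]) <= rtol * max(abs(ratios[i]), abs(ratios[i - 1])):
            current.append(i)
        else:
            if len(current) > 1:
                groups.append(current)
            current = [i]
    if len(current) > 1:
        groups.append(current)
    return groups


def gsvd(
    pair: ProfilePair,
    tol: float = 1e-12,
    fraction_exponent: int = 2,
    degeneracy_rtol: float = 1e-8,
) -> GSVDResult:
    """Exact GSVD of a column-matched pair, ordered by decreasing exclusivity.

    Parameters
    ----------
    pair
        The two matrices with matched patient columns.  Both must have full
        column rank (checked numerically; smallest singular value greater
        than ``tol`` times the largest).
    tol
        Relative rank tolerance.
    fraction_exponent
        Power of sigma used for the generalized fractions (1 or 2).
    degeneracy_rtol
        Components whose sigma1/sigma2 ratios agree within this relative
        tolerance are flagged as one degenerate (non-unique) subspace.

    Returns
    -------
    GSVDResult
        With the deterministic sign convention: each triplet
        ``(u_{1,n}, u_{2,n}, v_n)`` is oriented so that the largest-magnitude
        entry of ``v_n`` is positive (ties broken by lowest index).
    """
    D1, D2 = pair.D1, pair.D2
    n = pair.n_patients

    # thin QR reductions; rank checks on the small triangular factors
    Q1, R1 = np.linalg.qr(D1)
    Q2, R2 = np.linalg.qr(D2)
    _check_rank(R1, "D1", tol)
    _check_rank(R2, "D2", tol)

    # GSVD of the stacked N x N factor pair via the cosine-sine decomposition
    Z, R = np.linalg.qr(np.vstack([R1, R2]))
    Z1, Z2 = Z[:n], Z[n:]
    Uc, c, Wt = np.linalg.svd(Z1)  # Z1 = Uc @ diag(c) @ Wt, c descending
    c = np.clip(c, 0.0, 1.0)
    B = Z2 @ Wt.T  # columns orthogonal with norms s_n = sqrt(1 - c_n^2)
    s = np.linalg.norm(B, axis=0)
    if np.any(s <= np.finfo(float).eps * 10) or np.any(c <= np.finfo(float).eps * 10):
        raise NumericalError(
            "a generalized singular value underflowed; the pair is too close "
            "to rank deficiency for a reliable cosine-sine decomposition"
        )
    Us = B / s

    # back-transform and normalize the shared row basis
    X = Wt @ R  # N x N, invertible
    row_norms = np.linalg.norm(X, axis=1)
    VT = X / row_norms[:, None]
    sigma1 = c * row_norms
    sigma2 = s * row_norms
    U1 = Q1 @ Uc
    U2 = Q2 @ Us

    # order by decreasing ratio (stable; c descending already implies this)
    ratios = sigma1 / sigma2
    order = np.argsort(-ratios, kind="stable")
    U1, U2, VT = U1[:, order], U2[:, order], VT[order]
    sigma1, sigma2, ratios = sigma1[order], sigma2[order], ratios[order]

    # sign convention: largest-|entry| of each row of VT made positive
    lead = np.argmax(np.abs(VT), axis=1)
    flip = VT[np.arange(n), lead] < 0
    VT[flip] *= -1.0
    U1[:, flip] *= -1.0
    U2[:, flip] *= -1.0

    fractions1 = generalized_fractions(sigma1, fraction_exponent)
    fractions2 = generalized_fractions(sigma2, fraction_exponent)
    return GSVDResult(
        U1=U1,
        U2=U2,
        sigma1=sigma1,
        sigma2=sigma2,
        VT=VT,
        theta=angular_distance(sigma1, sigma2),
        fractions1=fractions1,
        fractions2=fractions2,
        entropy1=generalized_entropy(fractions1) if n > 1 else 0.0,
        entropy2=generalized_entropy(fractions2) if n > 1 else 0.0,
        degenerate_groups=_degenerate_groups(ratios, degeneracy_rtol),
        patient_ids=list(pair.patient_ids),
        fraction_exponent=fraction_exponent,
    )


def call_components(
    result: GSVDResult,
    theta_threshold: float = DEFAULT_THETA_THRESHOLD,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
) -> list[ComponentCall]:
    """Classify each component as exclusive to one dataset, common, or unassigned.

    A component is exclusive to dataset 1 when theta >= +theta_threshold and
    its dataset-1 fraction is significant; exclusive to dataset 2
    symmetrically; common when |theta| < theta_threshold and both fractions
    are significant; otherwise unassigned.
    """
    if not (0.0 < theta_threshold < QUARTER_PI):
        raise ValueError("theta_threshold must lie in (0, pi/4)")
    if not (0.0 < fraction_threshold < 1.0):
        raise ValueError("fraction_threshold must lie in (0, 1)")
    calls = []
    for i in range(result.n_components):
        th = float(result.theta[i])
        p1 = float(result.fractions1[i])
        p2 = float(result.fractions2[i])
        if th >= theta_threshold and p1 >= fraction_threshold:
            call = "exclusive_to_1"
        elif th <= -theta_threshold and p2 >= fraction_threshold:
            call = "exclusive_to_2"
        elif abs(th) < theta_threshold and p1 >= fraction_threshold and p2 >= fraction_threshold:
            call = "common"
        else:
            call = "unassigned"
        calls.append(ComponentCall(index=i, call=call, theta=th, fraction1=p1, fraction2=p2))
    return calls


def save_gsvd_hdf5(result: GSVDResult, path, metadata: dict | None = None) -> None:
    """Serialize a GSVDResult to HDF5 with a JSON metadata attribute."""
    meta = dict(metadata or {})
    meta.setdefault("fraction_exponent", result.fraction_exponent)
    with h5py.File(path, "w") as h5:
        for name in ("U1", "U2", "sigma1", "sigma2", "VT", "theta", "fractions1", "fractions2"):
            h5.create_dataset(name, data=getattr(result, name))
        h5.attrs["entropy1"] = result.entropy1
        h5.attrs["entropy2"] = result.entropy2
        h5.attrs["degenerate_groups"] = json.dumps(result.degenerate_groups)
        if result.patient_ids is not None:
            h5.create_dataset(
                "patient_ids", data=np.array(result.patient_ids, dtype=h5py.string_dtype())
            )
        h5.attrs["metadata"] = json.dumps(meta)


def load_gsvd_hdf5(path) -> tuple[GSVDResult, dict]:
    """Load a GSVDResult and its metadata dictionary from HDF5."""
    with h5py.File(path, "r") as h5:
        arrays = {
            name: np.asarray(h5[name])
            for name in ("U1", "U2", "sigma1", "sigma2", "VT", "theta", "fractions1", "fractions2")
        }
        pids = [p.decode() if isinstance(p, bytes) else str(p) for p in h5["patient_ids"][...]] if "patient_ids" in h5 else None
        meta = json.loads(h5.attrs.get("metadata", "{}"))
        result = GSVDResult(
            **arrays,
            entropy1=float(h5.attrs["entropy1"]),
            entropy2=float(h5.attrs["entropy2"]),
            degenerate_groups=json.loads(h5.attrs["degenerate_groups"]),
            patient_ids=pids,
            fraction_exponent=int(meta.get("fraction_exponent", 2)),
        )
    return result, meta


def calls_to_tsv(calls: list[ComponentCall], path) -> None:
    """Write component calls as a TSV table."""
    import pandas as pd

    pd.DataFrame(
        {
            "component": [c.index for c in calls],
            "call": [c.call for c in calls],
            "theta": [c.theta for c in calls],
            "fraction1": [c.fraction1 for c in calls],
            "fraction2": [c.fraction2 for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
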