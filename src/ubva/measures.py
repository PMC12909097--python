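"""Severity measures of multi-collinearity built on the SVD spectrum.

The right severity of variable ``j`` is the squared-loading weighted sum of
fourth powers of the singular values,

    SR_j = sum_i' v_{ji'}^2 d_{i'}^4,

which on a column-standardized matrix equals ``(n-1)^2 * sum_j' r_{jj'}^2``
(the sum of squared pairwise Pearson correlations, self term included).  The
scaled form ``sR_j = SR_j / (n-1)^2`` therefore lives in ``[1, p]``.  The dual
left severity ``SL_i = sum_i' u_{ii'}^2 d_{i'}^4`` is scaled by ``(p-1)^2``.

The global summary sRs mixes a bulk component (BsRs, the squared Red
indicator) with a local component (LsRs, excess severity normalized by the
maximal alignment with the top singular direction) using spectrum-derived
weights w1 and w2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "SVDSpectrum", "SeverityProfile", "GlobalSummary", "ComparisonProfile",
    "svd_spectrum", "right_severity", "left_severity", "severity_bounds",
    "expected_scaled_severity", "global_summary", "vif", "mp_support",
]

#: relative threshold below which a singular value counts as exactly zero
ZERO_TOL = 1e-10

#: recommended cutoff for sRs / BsRs / LsRs flags
SEVERITY_CUTOFF = 0.3


@dataclass
class SVDSpectrum:
    """Singular values and vectors of a standardized matrix.

    ``r = min(n-1, p)`` columns are retained for a column-standardized
    source (one degree of freedom is lost to centering); values below
    ``zero_tolerance * d_1`` are kept but treated as exact zeros, which is
    how rank-deficient (perfectly collinear) matrices are represented.
    """

    singular_values: np.ndarray   # (r,), nonincreasing
    left_vectors: np.ndarray      # (n, r)
    right_vectors: np.ndarray     # (p, r)
    n: int
    p: int
    zero_tolerance: float = ZERO_TOL

    @property
    def rank(self) -> int:
        d = self.singular_values
        if d.size == 0 or d[0] == 0:
            return 0
        return int(np.count_nonzero(d > self.zero_tolerance * d[0]))

    @property
    def nonzero_mask(self) -> np.ndarray:
        d = self.singular_values
        if d.size == 0 or d[0] == 0:
            return np.zeros_like(d, dtype=bool)
        return d > self.zero_tolerance * d[0]


@dataclass
class SeverityProfile:
    """Per-variable (axis="right") or per-sample (axis="left") severities."""

    axis: str                      # "right" | "left"
    raw: np.ndarray                # SR_j or SL_i
    scaled: np.ndarray             # raw / df^2
    method: str                    # "svd" | "pairwise" | "truncated"
    source_dims: tuple[int, int]   # (n, p)
    truncation_rank: int | None = None
    advisory: bool = False         # left severity on column-standardized data


@dataclass
class GlobalSummary:
    """The sRs bundle plus comparison diagnostics."""

    n: int
    p: int
    BsRs: float
    LsRs: float
    w1: float
    w2: float
    sRs: float
    red: float
    condition_number: float
    effective_df_sum: float
    effective_df_flag: bool
    severity_flags: dict = field(default_factory=dict)
    method: str = "svd"
    truncation_rank: int | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n, "p": self.p, "BsRs": self.BsRs, "LsRs": self.LsRs,
            "w1": self.w1, "w2": self.w2, "sRs": self.sRs, "red": self.red,
            "condition_number": self.condition_number,
            "effective_df_sum": self.effective_df_sum,
            "flags": {"effective_df": self.effective_df_flag,
                      **self.severity_flags},
            "method": self.method, "truncation_rank": self.truncation_rank,
        }


@dataclass
class ComparisonProfile:
    """Variance inflation factors; only defined in the data-rich n > p case."""

    vif: np.ndarray | None
    r_squared: np.ndarray | None
    valid: bool


def svd_spectrum(X: DataMatrix, zero_tolerance: float = ZERO_TOL) -> SVDSpectrum:
    """Full SVD of a standardized matrix, trimmed to the retained rank.

    For a column-standardized matrix the squared singular values sum to
    ``(n-1) * p``; centering guarantees rank at most ``min(n-1, p)``.
    """
    if not isinstance(X, DataMatrix):
        raise TypeError("svd_spectrum expects a DataMatrix (standardize first)")
    V = X.values
    if not np.isfinite(V).all():
        raise ValueError("non-finite entries in matrix")
    n, p = V.shape
    U, d, Vt = np.linalg.svd(V, full_matrices=False)
    if X.standardization == "columns":
        r = min(n - 1, p)
    elif X.standardization == "rows":
        r = min(n, p - 1)
    else:
        r = min(n, p)
    return SVDSpectrum(d[:r], U[:, :r], Vt[:r].T, n=n, p=p,
                       zero_tolerance=zero_tolerance)


def right_severity(spec: SVDSpectrum) -> SeverityProfile:
    """Per-variable severities SR_j = sum v^2 d^4 and sR_j = SR_j/(n-1)^2."""
    d4 = spec.singular_values ** 4
    raw = (spec.right_vectors ** 2) @ d4
    return SeverityProfile(axis="right", raw=raw,
                           scaled=raw / (spec.n - 1) ** 2, method="svd",
                           source_dims=(spec.n, spec.p))


def left_severity(spec: SVDSpectrum, row_standardized: bool = False) -> SeverityProfile:
    """Per-sample severities SL_i = sum u^2 d^4 and sL_i = SL_i/(p-1)^2.

    The scaled values carry their stated ``[1, n]`` range only when the
    source matrix was row-standardized; otherwise they are computed all the
    same but flagged advisory.
    """
    d4 = spec.singular_values ** 4
    raw = (spec.left_vectors ** 2) @ d4
    return SeverityProfile(axis="left", raw=raw,
                           scaled=raw / (spec.p - 1) ** 2, method="svd",
                           source_dims=(spec.n, spec.p),
                           advisory=not row_standardized)


def severity_bounds(spec: SVDSpectrum) -> np.ndarray:
    """Per-variable (lower, upper) bounds for sR_j on column-standardized data.

    Upper bound ``d_1^2/(n-1)`` (capped at p); lower bound
    ``1 / sum_i' v_{ji'}^2`` via Cauchy-Schwarz — equal to 1 when n > p
    (full row norms), strictly larger under n < p.

    Returns an array of shape (p, 2).
    """
    n = spec.n
    upper = min(spec.singular_values[0] ** 2 / (n - 1), float(spec.p))
    row_norms = (spec.right_vectors ** 2).sum(axis=1)
    zero = row_norms <= 0
    if zero.any():
        warnings.warn("variable(s) orthogonal to the retained spectrum; "
                      "lower bound reported as 1", RuntimeWarning)
    lower = np.where(zero, 1.0, 1.0 / np.where(zero, 1.0, row_norms))
    out = np.empty((spec.p, 2))
    out[:, 0] = lower
    out[:, 1] = upper
    return out


def expected_scaled_severity(Sigma: np.ndarray, n: int) -> np.ndarray:
    """Expected sR_j under rows i.i.d. N(0, Sigma) with unit-diagonal Sigma:

        E(sR_j) = p/(n-1) + n/(n-1) * Sigma_j' Sigma_j.

    Exact for n > p - 1; for n < p the sample cross-product no longer has a
    (nonsingular) Wishart distribution and the formula slightly
    underestimates the expectation — a warning is emitted.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    if Sigma.shape != (p, p) or not np.allclose(Sigma, Sigma.T, atol=1e-8):
        raise ValueError("Sigma must be a symmetric matrix")
    if not np.allclose(np.diag(Sigma), 1.0, atol=1e-8):
        raise ValueError("Sigma must have unit diagonal")
    if n < p:
        warnings.warn("n < p: expectation formula slightly underestimates "
                      "E(sR_j)", RuntimeWarning)
    col_sq = (Sigma ** 2).sum(axis=0)
    return p / (n - 1) + n / (n - 1) * col_sq


def _weights(spec: SVDSpectrum, w2_threshold: float | None) -> tuple[float, float]:
    d2 = spec.singular_values ** 2
    n, p = spec.n, spec.p
    tau = (n - p) ** 2 if w2_threshold is None else w2_threshold
    w1 = float(d2[d2 > p].sum() / d2.sum())
    pos = spec.nonzero_mask
    inv = 1.0 / d2[pos]
    denom = inv.sum()
    w2 = float(inv[d2[pos] > tau].sum() / denom) if denom > 0 else 0.0
    return w1, w2


def global_summary(profile: SeverityProfile, spec: SVDSpectrum, *,
                   w2_threshold: float | None = None,
                   cutoff: float = SEVERITY_CUTOFF) -> GlobalSummary:
    """Combine an exact right-severity profile into the sRs bundle.

    BsRs = (sum sR_j - p) / (p (p-1))           -- bulk, equals Red^2
    LsRs = (sum sR_j - p) / (p (d_1^2/(n-1)-1)) -- local
    sRs  = BsRs (w1+w2)/2 + LsRs (1 - (w1+w2)/2)

    with w1 the share of squared singular values exceeding p and w2 the
    share of inverse squared singular values exceeding ``w2_threshold``
    (default the printed ``(n-p)^2``; zero singular values are excluded from
    the inverse sums).
    """
    if profile.axis != "right" or profile.method == "truncated":
        raise ValueError("global_summary requires an exact right profile")
    n, p = spec.n, spec.p
    d = spec.singular_values
    excess = profile.scaled.sum() - p
    BsRs = excess / (p * (p - 1))
    BsRs = float(min(max(BsRs, 0.0), 1.0))
    ldenom = d[0] ** 2 / (n - 1) - 1.0
    if ldenom <= 0:
        if excess > 1e-8:
            warnings.warn("top singular value at/below the orthogonal-design "
                          "level; LsRs set to 0", RuntimeWarning)
        LsRs = 0.0
    else:
        LsRs = float(min(max(excess / (p * ldenom), 0.0), 1.0))
    w1, w2 = _weights(spec, w2_threshold)
    w = (w1 + w2) / 2.0
    sRs = BsRs * w + LsRs * (1.0 - w)
    red = float(np.sqrt(BsRs))
    d_min = d[min(n - 1, p) - 1]
    cond = float("inf") if d_min <= spec.zero_tolerance * d[0] else float(d[0] / d_min)
    eff = float(np.sum(1.0 / profile.scaled))
    return GlobalSummary(
        n=n, p=p, BsRs=BsRs, LsRs=LsRs, w1=w1, w2=w2, sRs=float(sRs), red=red,
        condition_number=cond, effective_df_sum=eff,
        effective_df_flag=bool(eff >= 0.3 * n),
        severity_flags={"sRs": bool(sRs >= cutoff), "BsRs": bool(BsRs >= cutoff),
                        "LsRs": bool(LsRs >= cutoff)},
        method=profile.method,
    )


def vif(X: DataMatrix) -> ComparisonProfile:
    """Variance inflation factors VIF_j = 1/(1 - R_j^2).

    R_j^2 comes from least-squares regression of column j on the other
    p - 1 columns.  Only meaningful for n > p; otherwise ``valid=False``
    is returned without values (every variable is perfectly explained).
    """
    if X.standardization != "columns":
        raise ValueError("vif expects a column-standardized matrix")
    n, p = X.values.shape
    if n <= p:
        return ComparisonProfile(vif=None, r_squared=None, valid=False)
    M = X.values
    r2 = np.empty(p)
    for j in range(p):
        others = np.delete(M, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, M[:, j], rcond=None)
        resid = M[:, j] - others @ beta
        r2[j] = 1.0 - resid @ resid / (M[:, j] @ M[:, j])
    r2 = np.clip(r2, 0.0, 1.0)
    near = r2 > 1.0 - 1e-12
    vals = np.where(near, np.inf, 1.0 / (1.0 - np.clip(r2, 0.0, 1.0 - 1e-12)))
    return ComparisonProfile(vif=vals, r_squared=r2, valid=True)


def mp_support(n: int, p: int) -> dict:
    """Marchenko-Pastur theoretical supports under an identity covariance.

    For i.i.d. standard-normal entries the scaled right severities
    concentrate on ``(p/n, (1 + sqrt(n/p))^2 * p/n)`` and the scaled left
    severities on ``(1, (1 + sqrt(n/p))^2)``.
    """
    edge = (1.0 + np.sqrt(n / p)) ** 2
    return {"sR": (p / n, edge * p / n), "sL": (1.0, edge)}
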