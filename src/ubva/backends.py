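"""Interchangeable strategies for computing the right-severity profile.

Three routes, algebraically equivalent on the exact side:

* ``svd`` — full SVD of the standardized matrix; O(n^2 p) time for n < p,
  gives the whole spectrum and hence the global summary for free.
* ``pairwise`` — blocked accumulation of sum_j' r_{jj'}^2; exact, with peak
  extra memory proportional to ``block_size * p`` rather than p^2.
* ``truncated`` — randomized truncated SVD keeping the top k singular
  triplets; underestimates sum sR_j (dropped terms are nonnegative) but
  approximates the bulk component well when the spectrum is spiked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .data import DataMatrix, standardize
from .measures import (GlobalSummary, SeverityProfile, SVDSpectrum,
                       global_summary, right_severity, svd_spectrum)

__all__ = ["BackendConfig", "severity_svd", "severity_pairwise",
           "severity_truncated", "compute"]

# auto-dispatch thresholds (engineering defaults, not method constants)
_AUTO_SVD_MAX = 2000      # exact SVD while min(n, p) <= this
_AUTO_PAIRWISE_MAX = 20000  # blocked pairwise while p <= this


@dataclass
class BackendConfig:
    method: str = "auto"          # auto | pairwise | svd | truncated
    truncation_rank: int = 100
    block_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"auto", "pairwise", "svd", "truncated"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.truncation_rank < 1:
            raise ValueError("truncation_rank must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")


def severity_svd(X: DataMatrix, cfg: BackendConfig | None = None
                 ) -> tuple[SeverityProfile, SVDSpectrum]:
    """Exact right severities via the full SVD; also returns the spectrum."""
    spec = svd_spectrum(X)
    return right_severity(spec), spec


def severity_pairwise(X: DataMatrix, cfg: BackendConfig | None = None
                      ) -> SeverityProfile:
    """Exact right severities as blocked sums of squared correlations.

    For column-standardized data r_{jj'} = x_j' x_{j'} / (n-1), so each
    block of ``block_size`` variables contributes one (p, block) slab of
    squared correlations to the running sums; nothing of size p x p is
    ever allocated.
    """
    if X.standardization != "columns":
        raise ValueError("pairwise backend expects a column-standardized matrix")
    cfg = cfg or BackendConfig()
    M = X.values
    n, p = M.shape
    acc = np.zeros(p)
    b = cfg.block_size
    for start in range(0, p, b):
        block = M[:, start:start + b]
        G = M.T @ block / (n - 1)        # (p, <=b) slab of correlations
        acc += (G * G).sum(axis=1)
    scaled = acc
    return SeverityProfile(axis="right", raw=scaled * (n - 1) ** 2,
                           scaled=scaled, method="pairwise",
                           source_dims=(n, p))


def severity_truncated(X: DataMatrix, cfg: BackendConfig | None = None
                       ) -> SeverityProfile:
    """Approximate right severities from the top-k randomized SVD.

    Contract: sum of the returned severities never exceeds the exact sum
    (dropped fourth-power terms are nonnegative); the bulk summary BsRs is
    well approximated when the spectrum is spiked, while fidelity of the
    local component degrades.
    """
    cfg = cfg or BackendConfig(method="truncated")
    n, p = X.values.shape
    r = min(n - 1, p)
    k = cfg.truncation_rank
    if k >= r:
        raise ValueError(
            f"truncation_rank k={k} must be < min(n-1, p)={r}; "
            "use the exact svd or pairwise backends instead")
    _, d, Vt = randomized_svd(X.values, n_components=k, n_oversamples=10,
                              n_iter=2, random_state=cfg.seed)
    raw = (Vt.T ** 2) @ d ** 4
    return SeverityProfile(axis="right", raw=raw, scaled=raw / (n - 1) ** 2,
                           method="truncated", source_dims=(n, p),
                           truncation_rank=k)


def _resolve_auto(n: int, p: int) -> str:
    if p > _AUTO_PAIRWISE_MAX:
        return "truncated"
    if min(n, p) <= _AUTO_SVD_MAX:
        return "svd"
    return "pairwise"


def _spectrum_values_only(X: DataMatrix) -> SVDSpectrum:
    """Singular values via the smaller Gram matrix (no vectors needed for
    the global summary's spectral weights)."""
    M = X.values
    n, p = M.shape
    G = M @ M.T if n <= p else M.T @ M
    ev = np.linalg.eigvalsh(G)[::-1]
    d = np.sqrt(np.clip(ev, 0.0, None))
    r = min(n - 1, p) if X.standardization == "columns" else min(n, p)
    return SVDSpectrum(d[:r], np.empty((n, 0)), np.empty((p, 0)), n=n, p=p)


def compute(X, cfg: BackendConfig | None = None, *, mode: str = "columns",
            w2_threshold: float | None = None
            ) -> tuple[SeverityProfile, GlobalSummary | None]:
    """Dispatch to a backend and, for exact methods, build the global summary.

    ``X`` may be raw (standardized here) or an existing DataMatrix.  The
    truncated backend returns a bulk-only approximate summary flagged by
    ``method="truncated"``; its LsRs/w2 fields are not trustworthy and the
    profile's truncation rank is recorded.
    """
    cfg = cfg or BackendConfig()
    if not isinstance(X, DataMatrix) or X.standardization == "none":
        X = standardize(X, mode)
    n, p = X.values.shape
    method = cfg.method if cfg.method != "auto" else _resolve_auto(n, p)
    if method == "svd":
        profile, spec = severity_svd(X, cfg)
        return profile, global_summary(profile, spec, w2_threshold=w2_threshold)
    if method == "pairwise":
        profile = severity_pairwise(X, cfg)
        spec = _spectrum_values_only(X)
        return profile, global_summary(profile, spec, w2_threshold=w2_threshold)
    profile = severity_truncated(X, cfg)
    excess = profile.scaled.sum() - p
    BsRs = float(min(max(excess / (p * (p - 1)), 0.0), 1.0))
    warnings.warn("truncated backend: global summary restricted to the "
                  "bulk approximation", RuntimeWarning)
    approx = GlobalSummary(n=n, p=p, BsRs=BsRs, LsRs=float("nan"),
                           w1=float("nan"), w2=float("nan"), sRs=float("nan"),
                           red=float(np.sqrt(BsRs)),
                           condition_number=float("nan"),
                           effective_df_sum=float(np.sum(1.0 / np.maximum(
                               profile.scaled, 1e-300))),
                           effective_df_flag=False,
                           severity_flags={"BsRs": BsRs >= 0.3},
                           method="truncated",
                           truncation_rank=profile.truncation_rank)
    return profile, approx
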