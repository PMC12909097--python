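"""scikit-learn style front door for the severity measures.

``CollinearitySeverity`` is a fit-only diagnostic estimator in the mold of
``sklearn.covariance`` estimators: ``fit(X)`` standardizes, runs the chosen
backend and stores the per-variable severities and global summary as fitted
attributes.  It composes with ``sklearn.base.clone`` and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import backends
from .data import DataMatrix, standardize
from .measures import (left_severity, severity_bounds, svd_spectrum, vif)

__all__ = ["CollinearitySeverity"]


class CollinearitySeverity(BaseEstimator):
    """Per-variable and global severity of multi-collinearity.

    Parameters
    ----------
    method : {"auto", "svd", "pairwise", "truncated"}, default="auto"
        Backend for the right-severity profile.  ``auto`` picks the exact
        SVD when ``min(n, p)`` is small, blocked pairwise correlation for
        wide-but-moderate p, and the randomized truncated SVD otherwise.
    truncation_rank : int, default=100
        k for the truncated backend.
    block_size : int, default=1024
        Variables per slab in the pairwise accumulator.
    w2_threshold : float or None, default=None
        Threshold tau on squared singular values in the w2 weight; None
        uses ``(n - p)^2``.
    compute_left : bool, default=False
        Also compute the per-sample (left) severities; advisory under
        column standardization.
    random_state : int, default=0
        Seed for the randomized SVD.

    Attributes
    ----------
    severity_ : ndarray of shape (p,)
        Scaled right severities sR_j (sum of squared correlations with all
        variables, self term included); in [1, p] for exact methods.
    raw_severity_ : ndarray of shape (p,)
        Unscaled SR_j = sR_j * (n-1)^2.
    summary_ : GlobalSummary
        sRs / BsRs / LsRs / Red / condition number bundle (bulk-only
        approximation when ``method="truncated"``).
    bounds_ : ndarray of shape (p, 2) or None
        Per-variable (lower, upper) envelope for sR_j (exact SVD route only).
    left_severity_ : ndarray of shape (n,) or None
        Scaled left severities when ``compute_left=True``.
    vif_ : ndarray of shape (p,) or None
        Variance inflation factors when n > p, else None.
    method_ : str
        Backend actually used.
    n_samples_, n_features_in_ : int
    """

    def __init__(self, method: str = "auto", truncation_rank: int = 100,
                 block_size: int = 1024, w2_threshold: float | None = None,
                 compute_left: bool = False, compute_vif: bool = True,
                 random_state: int = 0):
        self.method = method
        self.truncation_rank = truncation_rank
        self.block_size = block_size
        self.w2_threshold = w2_threshold
        self.compute_left = compute_left
        self.compute_vif = compute_vif
        self.random_state = random_state

    def fit(self, X, y=None):
        """Standardize columns of X and compute the severity measures."""
        if isinstance(X, DataMatrix) and X.standardization == "columns":
            dm = X
        else:
            dm = standardize(X, "columns")
        cfg = backends.BackendConfig(method=self.method,
                                     truncation_rank=self.truncation_rank,
                                     block_size=self.block_size,
                                     seed=self.random_state)
        n, p = dm.values.shape
        method = (cfg.method if cfg.method != "auto"
                  else backends._resolve_auto(n, p))
        self.bounds_ = None
        self.left_severity_ = None
        if method == "svd":
            profile, spec = backends.severity_svd(dm, cfg)
            from .measures import global_summary
            summary = global_summary(profile, spec,
                                     w2_threshold=self.w2_threshold)
            self.bounds_ = severity_bounds(spec)
            if self.compute_left:
                self.left_severity_ = left_severity(spec).scaled
            self.spectrum_ = spec
        else:
            cfg.method = method
            profile, summary = backends.compute(
                dm, cfg, w2_threshold=self.w2_threshold)
            self.spectrum_ = None
            if self.compute_left and method != "truncated":
                self.left_severity_ = left_severity(svd_spectrum(dm)).scaled
        self.severity_ = profile.scaled
        self.raw_severity_ = profile.raw
        self.profile_ = profile
        self.summary_ = summary
        self.method_ = profile.method
        self.vif_ = None
        if self.compute_vif and n > p:
            cp = vif(dm)
            self.vif_ = cp.vif
        self.n_samples_ = n
        self.n_features_in_ = p
        self.variable_names_ = dm.variable_names
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the scaled right severities."""
        return self.fit(X).severity_
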