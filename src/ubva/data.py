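"""Standardized data matrices and delimited-text I/O.

All severity measures operate on a matrix whose columns (or rows) have been
standardized to sample mean 0 and variance 1 with the variance divisor
``n - 1``.  Standardization consumes one degree of freedom, which is why the
squared singular values of a column-standardized matrix sum to ``(n - 1) * p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DataMatrix", "standardize", "read_matrix"]

_MEAN_TOL = 1e-10
_VAR_TOL = 1e-8


@dataclass
class DataMatrix:
    """A numeric samples-by-variables matrix with standardization provenance.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_variables)
    standardization : {"columns", "rows", "none"}
        Which axis has been scaled to mean 0, variance 1 (divisor ``df``).
    df : int
        Degrees of freedom consumed by centering: ``n - 1`` for column mode,
        ``p - 1`` for row mode.
    variable_names, sample_names : optional lists of axis labels.
    """

    values: np.ndarray
    standardization: str = "none"
    variable_names: list[str] | None = None
    sample_names: list[str] | None = None
    df: int = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expected a 2-D matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("matrix contains missing or non-finite values")
        n, p = self.values.shape
        if self.standardization == "columns":
            self.df = n - 1
        elif self.standardization == "rows":
            self.df = p - 1
        elif self.standardization == "none":
            self.df = 0
        else:
            raise ValueError(f"unknown standardization {self.standardization!r}")
        if self.variable_names is not None and len(self.variable_names) != p:
            raise ValueError("variable_names length mismatch")
        if self.sample_names is not None and len(self.sample_names) != n:
            raise ValueError("sample_names length mismatch")
        self._check_invariants()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def _check_invariants(self) -> None:
        if self.standardization == "none":
            return
        axis = 0 if self.standardization == "columns" else 1
        means = self.values.mean(axis=axis)
        var = self.values.var(axis=axis, ddof=1)
        if np.abs(means).max() > _MEAN_TOL:
            raise ValueError("standardized axis has nonzero mean")
        if np.abs(var - 1.0).max() > _VAR_TOL:
            raise ValueError("standardized axis does not have unit variance")


def standardize(X, mode: str = "columns", *, variable_names=None,
                sample_names=None) -> DataMatrix:
    """Standardize each column (or row) of ``X`` to mean 0, variance 1.

    Parameters
    ----------
    X : array-like of shape (n_samples, n_variables)
        Raw numeric matrix; at least 3 rows and 2 columns, no missing values.
    mode : {"columns", "rows"}

    Returns
    -------
    DataMatrix

    Raises
    ------
    ValueError
        If any column (row) is constant — it cannot be scaled to unit
        variance — or if ``X`` contains missing values.
    """
    if isinstance(X, DataMatrix):
        variable_names = variable_names or X.variable_names
        sample_names = sample_names or X.sample_names
        X = X.values
    if isinstance(X, pd.DataFrame):
        variable_names = variable_names or [str(c) for c in X.columns]
        sample_names = sample_names or [str(i) for i in X.index]
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("expected a matrix with >= 3 rows and >= 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    axis = 0 if mode == "columns" else 1
    centered = X - X.mean(axis=axis, keepdims=True)
    sd = centered.std(axis=axis, ddof=1, keepdims=True)
    zero = (sd == 0).ravel()
    if zero.any():
        names = variable_names if mode == "columns" else sample_names
        which = [names[i] if names else str(i) for i in np.nonzero(zero)[0]]
        kind = "column" if mode == "columns" else "row"
        raise ValueError(
            f"constant {kind}(s) cannot be standardized to unit variance: "
            + ", ".join(which[:10])
        )
    return DataMatrix(centered / sd, standardization=mode,
                      variable_names=variable_names, sample_names=sample_names)


def read_matrix(path, *, sep: str | None = None) -> DataMatrix:
    """Read a delimited text matrix (header row of variable names; an
    optional first column of sample names is detected by non-numeric dtype).
    ``.npy`` files are loaded directly without names."""
    path = str(path)
    if path.endswith(".npy"):
        return DataMatrix(np.load(path))
    df = pd.read_csv(path, sep=sep, engine="python")
    sample_names = None
    first = df.columns[0]
    if not pd.api.types.is_numeric_dtype(df[first]):
        sample_names = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    return DataMatrix(df.to_numpy(dtype=float),
                      variable_names=[str(c) for c in df.columns],
                      sample_names=sample_names)
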