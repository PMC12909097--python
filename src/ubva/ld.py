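"""Windowed severity analogues used in statistical genetics.

LDadj(j) sums squared correlations between variant j and its t neighbours
on each side (self term included); with a full window it equals the scaled
right severity sR_j exactly.  LDscore replaces each r^2 with the
small-sample-unbiased r^2 - (1 - r^2)/(n - 2).  Windows are defined in
variant counts and clipped at chromosome edges; a genetic-map (centiMorgan)
window is not supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataMatrix

__all__ = ["LdProfile", "ld_adj", "ld_score"]


@dataclass
class LdProfile:
    values: np.ndarray
    window_radius: int
    kind: str                 # "ld_adj" | "ld_score"
    n: int | None = None      # sample size behind the bias correction


def _banded_r2(X: DataMatrix, t: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Off-diagonal squared correlations by offset, plus counts.

    Returns (r2_by_offset, ...) where r2_by_offset[off-1] holds
    r^2 between columns j and j+off for j = 0..p-1-off.  Columns must be
    ordered by genomic position.
    """
    if X.standardization != "columns":
        raise ValueError("ld measures expect a column-standardized matrix")
    M = X.values
    n, p = M.shape
    out = []
    for off in range(1, min(t, p - 1) + 1):
        r = (M[:, :-off] * M[:, off:]).sum(axis=0) / (n - 1)
        out.append(r ** 2)
    return out


def ld_adj(X: DataMatrix, t: int) -> LdProfile:
    """Adjacent-LD score: sum of r^2 over a +/- t variant window."""
    if t < 0:
        raise ValueError("window radius t must be >= 0")
    p = X.values.shape[1]
    vals = np.ones(p)
    for off_m1, r2 in enumerate(_banded_r2(X, t)):
        off = off_m1 + 1
        vals[:-off] += r2
        vals[off:] += r2
    return LdProfile(vals, window_radius=t, kind="ld_adj")


def ld_score(X: DataMatrix, t: int) -> LdProfile:
    """LD score with the (1 - r^2)/(n - 2) unbiasedness correction.

    The self term contributes exactly 1 (its correction vanishes at
    r^2 = 1).  Requires n > 3 for a stable correction.
    """
    if t < 0:
        raise ValueError("window radius t must be >= 0")
    n, p = X.values.shape
    if n <= 3:
        raise ValueError("ld_score requires n > 3")
    vals = np.ones(p)
    for off_m1, r2 in enumerate(_banded_r2(X, t)):
        off = off_m1 + 1
        adj = r2 - (1.0 - r2) / (n - 2)
        vals[:-off] += adj
        vals[off:] += adj
    return LdProfile(vals, window_radius=t, kind="ld_score", n=n)
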