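"""Multivariate-normal simulators for benchmark covariance structures.

Six population covariance families drive the test bed: identity, compound
symmetric (CS), first-order autoregressive (AR1), block-diagonal CS, and two
spiked (low-rank plus noise) constructions.  Rows of X are drawn i.i.d.
N(0, Sigma) through a symmetric square root, so exactly singular Sigma
(perfectly collinear composites) is supported.

The scenario registry reproduces the comparison settings used to contrast
sRs with the Red indicator, the condition number and VIF: an orthogonal
design, a single near-collinear pair, CS at moderate and extreme rho, the
pair embedded in a CS background, and a spiked covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .backends import BackendConfig, severity_svd
from .data import standardize
from .measures import (GlobalSummary, SeverityProfile, global_summary,
                       left_severity, vif)

__all__ = ["CovarianceSpec", "ScenarioResult", "make_covariance",
           "sample_gaussian", "run_scenario", "SCENARIOS",
           "DEFAULT_SCENARIO_SEED"]

DEFAULT_SCENARIO_SEED = 20250043

_STRUCTURES = {"identity", "compound_symmetric", "ar1", "block_diagonal",
               "spiked", "composite"}


@dataclass
class CovarianceSpec:
    """Declarative description of a population covariance structure.

    For ``spiked``: Sigma = L L' + noise * I with L = Q O, Q a uniformly
    random column-orthonormal p x k frame and O diagonal.  ``equal`` loading
    puts o_i = 10/sqrt(n_ref) for all i; ``exponential_decay`` solves a
    geometric sequence o_1^2 > ... > o_k^2 subject to o_k^2 = okk2 and
    sum o_i^2 + p * noise = p (trace p).
    """

    structure: str
    p: int
    rho: float | None = None
    blocks: list = field(default_factory=list)   # [(size, CovarianceSpec)]
    k: int = 10
    noise: float = 0.4
    loading_profile: str = "exponential_decay"
    okk2: float | None = None      # o_k^2 for the decay construction
    n_ref: int = 500               # n entering the equal-loading scale 10/sqrt(n)
    seed: int = 0                  # for the random orthonormal frame

    def __post_init__(self) -> None:
        if self.structure not in _STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; "
                             f"choose from {sorted(_STRUCTURES)}")


def _cs(p: int, rho: float) -> np.ndarray:
    if not (-1.0 / (p - 1) < rho < 1.0):
        raise ValueError(f"compound-symmetric rho={rho} outside "
                         f"(-1/(p-1), 1) for p={p}: matrix not PSD")
    return rho * np.ones((p, p)) + (1.0 - rho) * np.eye(p)


def _spiked(spec: CovarianceSpec) -> np.ndarray:
    p, k, z2 = spec.p, spec.k, spec.noise
    if k >= p:
        raise ValueError("spike rank k must be < p")
    if spec.loading_profile == "equal":
        o2 = np.full(k, 100.0 / spec.n_ref)
    elif spec.loading_profile == "exponential_decay":
        okk2 = (1.0 + z2) if spec.okk2 is None else spec.okk2
        target = p * (1.0 - z2)
        if target <= k * okk2:
            raise ValueError("decay constraints infeasible: need "
                             "sum o_i^2 = p(1-noise) > k * o_k^2")
        # geometric decay o_i^2 = okk2 * r^(k-i); solve sum = target
        def gap(r):
            return okk2 * (r ** k - 1.0) / (r - 1.0) - target
        r = brentq(gap, 1.0 + 1e-9, 1e6)
        o2 = okk2 * r ** np.arange(k - 1, -1, -1)
    else:
        raise ValueError(f"unknown loading_profile {spec.loading_profile!r}")
    rng = np.random.default_rng(spec.seed)
    Q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    return (Q * o2) @ Q.T + z2 * np.eye(p)


def make_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Build the population covariance matrix described by ``spec``."""
    p = spec.p
    if spec.structure == "identity":
        return np.eye(p)
    if spec.structure == "compound_symmetric":
        return _cs(p, spec.rho)
    if spec.structure == "ar1":
        idx = np.arange(p)
        return spec.rho ** np.abs(idx[:, None] - idx[None, :])
    if spec.structure in ("block_diagonal", "composite"):
        sizes = [s for s, _ in spec.blocks]
        if sum(sizes) != p:
            raise ValueError(f"block sizes {sizes} do not sum to p={p}")
        out = np.zeros((p, p))
        at = 0
        for size, sub in spec.blocks:
            if sub.p != size:
                raise ValueError("inner spec dimension != block size")
            out[at:at + size, at:at + size] = make_covariance(sub)
            at += size
        return out
    return _spiked(spec)


def sample_gaussian(Sigma: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw n i.i.d. rows from N(0, Sigma) via the symmetric square root.

    Exactly singular Sigma is allowed (eigenvalues clipped at zero), which
    makes perfectly collinear designs reproducible.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    w, V = np.linalg.eigh(Sigma)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(f"Sigma not PSD: min eigenvalue {w.min():.3g}")
    root = (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, Sigma.shape[0])) @ root


@dataclass
class ScenarioResult:
    name: str
    seed: int
    n: int
    p: int
    profile: SeverityProfile
    summary: GlobalSummary
    left_scaled: np.ndarray
    eigenvalues: np.ndarray          # sample eigenvalues d^2/(n-1)
    vif: np.ndarray | None
    distribution: dict

    def severity(self) -> np.ndarray:
        return self.profile.scaled


def _pair_block() -> CovarianceSpec:
    return CovarianceSpec("compound_symmetric", p=2, rho=0.99)


def _scenario_cov(name: str, p: int, rho: float | None) -> CovarianceSpec:
    half, quarter = p // 2, p // 4
    registry = {
        # comparison scenarios
        "identity": lambda: CovarianceSpec("identity", p=p),
        "collinear_pair": lambda: CovarianceSpec(
            "composite", p=p,
            blocks=[(2, _pair_block()),
                    (p - 2, CovarianceSpec("identity", p=p - 2))]),
        "cs": lambda: CovarianceSpec("compound_symmetric", p=p,
                                     rho=0.3 if rho is None else rho),
        "cs_rho0.3": lambda: CovarianceSpec("compound_symmetric", p=p, rho=0.3),
        "cs_rho0.99": lambda: CovarianceSpec("compound_symmetric", p=p, rho=0.99),
        "collinear_plus_cs": lambda: CovarianceSpec(
            "composite", p=p,
            blocks=[(2, _pair_block()),
                    (p - 2, CovarianceSpec("compound_symmetric", p=p - 2,
                                           rho=0.3 if rho is None else rho))]),
        "spiked": lambda: CovarianceSpec("spiked", p=p, k=10, noise=0.4,
                                         loading_profile="exponential_decay"),
        # covariance-structure presets (a)-(f)
        "cs_rho0.2": lambda: CovarianceSpec("compound_symmetric", p=p, rho=0.2),
        "ar1_list": lambda: CovarianceSpec("ar1", p=p, rho=0.8),
        "ar1_text": lambda: CovarianceSpec("ar1", p=p, rho=0.3),
        "block_three_cs": lambda: CovarianceSpec(
            "block_diagonal", p=p,
            blocks=[(half, CovarianceSpec("compound_symmetric", p=half, rho=0.1)),
                    (quarter, CovarianceSpec("compound_symmetric", p=quarter, rho=0.4)),
                    (p - half - quarter,
                     CovarianceSpec("compound_symmetric", p=p - half - quarter,
                                    rho=0.6))]),
        "spiked_equal": lambda: CovarianceSpec("spiked", p=p, k=10, noise=0.4,
                                               loading_profile="equal"),
        # alternate decay anchor o_k^2 = 2 + noise (contradictory variant
        # recorded in the source material; kept as its own preset)
        "spiked_alt": lambda: CovarianceSpec("spiked", p=p, k=10, noise=0.4,
                                             loading_profile="exponential_decay",
                                             okk2=2.4),
    }
    if name not in registry:
        raise ValueError(f"unknown scenario {name!r}; available: "
                         + ", ".join(sorted(registry)))
    return registry[name]()


SCENARIOS = ("identity", "collinear_pair", "cs", "cs_rho0.2", "cs_rho0.3",
             "cs_rho0.99", "collinear_plus_cs", "spiked", "spiked_equal",
             "spiked_alt", "ar1_list", "ar1_text", "block_three_cs")


def run_scenario(name: str, n: int, p: int,
                 seed: int = DEFAULT_SCENARIO_SEED,
                 rho: float | None = None,
                 w2_threshold: float | None = None) -> ScenarioResult:
    """Sample a scenario, standardize and compute the full severity bundle.

    VIF is included only in the data-rich (n > p) regime where it is
    defined.  Distribution summaries (min/quartiles/median/mean/max) of the
    scaled right severities are attached for figure-style reporting.
    """
    spec = _scenario_cov(name, p, rho)
    spec.seed = seed                      # frame of the spiked structure
    Sigma = make_covariance(spec)
    X = standardize(sample_gaussian(Sigma, n, seed), "columns")
    profile, sv = severity_svd(X, BackendConfig(method="svd"))
    summary = global_summary(profile, sv, w2_threshold=w2_threshold)
    sl = left_severity(sv).scaled
    vprof = vif(X) if n > p else None
    s = profile.scaled
    dist = {"min": float(s.min()), "q1": float(np.quantile(s, 0.25)),
            "median": float(np.median(s)), "mean": float(s.mean()),
            "q3": float(np.quantile(s, 0.75)), "max": float(s.max())}
    return ScenarioResult(
        name=name, seed=seed, n=n, p=p, profile=profile, summary=summary,
        left_scaled=sl, eigenvalues=sv.singular_values ** 2 / (n - 1),
        vif=vprof.vif if (vprof and vprof.valid) else None,
        distribution=dist)
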