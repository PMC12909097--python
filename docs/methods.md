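# Methods

## Model and definitions

All measures are functions of the column-standardized data matrix
X ∈ ℝ^(n×p): each column is centered and scaled to sample variance 1 with
divisor n−1. Centering costs one degree of freedom, so the SVD X = UDVᵀ is
kept to r = min(n−1, p) triplets and Σ d² = (n−1)p exactly; singular values
below 1e−10·d₁ (relative) are retained but treated as exact zeros, which is
how rank deficiency — perfect collinearity — is represented.

Per-variable right severity and its scaled form:

    SR_j = Σ_{i′} v²_{ji′} d⁴_{i′},     sR_j = SR_j/(n−1)² = Σ_{j′} r²_{jj′} ∈ [1, p],

where r_{jj′} is the sample Pearson correlation of columns j and j′ (the
self term contributes 1). The dual left severity SL_i = Σ u²_{ii′} d⁴_{i′}
is scaled by (p−1)²; its [1, n] range only holds under row standardization,
so on column-standardized input the scaled values are flagged advisory.
Both sums conserve: Σ_j SR_j = Σ_i SL_i = Σ d⁴.

Per-variable envelope (column-standardized source): upper bound
d₁²/(n−1), capped at p; lower bound 1/(Σ_{i′} v²_{ji′}) by Cauchy–Schwarz
from Σ_{i′} v²_{ji′} d²_{i′} = n−1. When n > p the row norms of V are full
and the lower bound is 1; under n < p it is strictly larger — spurious
correlation floor. When a variable is orthogonal to the whole retained
spectrum (zero row norm in V) the bound is reported as 1 with a warning.

## Global summary

    BsRs = (Σ_j sR_j − p) / (p(p−1))                       (bulk; = Red²)
    LsRs = (Σ_j sR_j − p) / (p(d₁²/(n−1) − 1))             (local)
    sRs  = BsRs·(w1+w2)/2 + LsRs·(1 − (w1+w2)/2) ∈ [0, 1]

with w1 = Σ_{d²>p} d² / Σ d² and w2 = Σ_{d²>τ} d⁻² / Σ d⁻². Zero singular
values are excluded from the inverse sums. The threshold τ defaults to
(n−p)² and is exposed as a parameter (`w2_threshold`): because
Σ d² = (n−1)p, no d² can exceed (n−p)² once |n−p| is large, so the default
makes w2 = 0 in essentially every non-square design. We keep the default as
stated and configurable rather than invent an alternative; note that with
w2 = 0 the summary's sensitivity to a single strong local pair is limited
(see "Known limitations"). Degenerate denominator: if d₁² ≤ n−1 (only
possible for at-or-below-identity spectra, e.g. exact orthogonal designs)
LsRs is defined as 0, with a warning if the numerator is not also ~0.

Red is reported as +√BsRs. The condition number is d₁/d_min with
d_min = d_{min(n−1,p)}; it is +∞ when d_min falls below the zero tolerance.
The effective-degrees-of-freedom proxy Σ_j 1/sR_j is flagged against 0.3·n.
Severity flags compare sRs, BsRs and LsRs against the 0.3 cutoff; both the
weighted sRs and its unweighted components are flagged because the cutoff
is calibrated on the components.

Expectation under rows i.i.d. N(0, Σ), unit-diagonal Σ:
E(sR_j) = p/(n−1) + n/(n−1)·Σ_jᵀΣ_j, exact for centered Gaussian
cross-products (Wishart) with n > p−1. Two caveats are surfaced as
warnings/documentation rather than silently absorbed: for n < p the
singular-Wishart case makes it a slight underestimate, and sample
standardization pins the null E(r²) at exactly 1/(n−1), so under
independence the true mean of sR_j is 1 + (p−1)/(n−1), an O(1/n) offset of
2/(n−1) from the formula. Tests account for the latter explicitly.

VIF_j = 1/(1 − R²_j) from least squares of column j on the rest; computed
only for n > p (otherwise `valid=False`), with R² clamped to [0, 1−1e−12]
and near-perfect fits reported as +∞.

## Backends

* `svd`: full SVD; the reference route, also yields bounds, left severity
  and the full summary.
* `pairwise`: blocked accumulation of Σ r² in slabs of `block_size`
  variables (default 1024); exact, never allocates p×p. The summary's
  spectral weights are recovered from the eigenvalues of the smaller Gram
  matrix.
* `truncated`: scikit-learn randomized SVD with k components (default 100),
  10 oversamples and 2 power iterations, seeded. It underestimates Σ sR_j
  (dropped fourth-power terms are nonnegative, so the total is nondecreasing
  in k), approximates BsRs well for spiked spectra, and cannot support the
  local component — it returns a bulk-only summary flagged `truncated`.
  k ≥ min(n−1, p) is rejected in favor of the exact backends.

`auto` picks svd when min(n, p) ≤ 2000 and p ≤ 20000, pairwise for larger n
while p ≤ 20000, and truncated beyond; thresholds are desk-hardware
engineering choices, configurable. The O(np³) per-variable OLS route is
deliberately not offered as a backend.

## Simulator

`make_covariance` builds identity, compound-symmetric (ρ constrained to
(−1/(p−1), 1)), AR1, block-diagonal CS, and spiked Σ = QO²Qᵀ + ζ²I
structures. For the spiked family Q is a uniformly random p×k orthonormal
frame (QR of a seeded Gaussian matrix — the spectrum is invariant to the
choice of frame). Equal loadings use o² = 100/n_ref with ζ² = 0.4; the
exponential-decay mode solves a geometric sequence with o_k² = 1+ζ² and
trace p. Two printed variants from the source material conflict, so both
are kept as presets: AR1 ρ = 0.8 (`ar1_list`) vs 0.3 (`ar1_text`), and
decay anchor o_k² = 1+ζ² (`spiked`) vs 2+ζ² (`spiked_alt`).

Sampling uses the symmetric square root of Σ (eigendecomposition, negative
eigenvalues clipped at −1e−8 tolerance), so exactly singular covariances —
duplicated variables, perfect collinearity — sample correctly and
reproducibly from an explicit seed.

The scenario registry (identity, collinear_pair, cs at ρ=0.3/0.99,
collinear_plus_cs, spiked, plus the structure presets) reproduces the
benchmark comparisons at n ∈ {100, 500} with p = 1000 (high-dimensional) or
p = 50 (data-rich). What the simulator does *not* emulate: non-Gaussian
margins, heavy tails, discrete genotype distributions, or LD decay along a
genetic map — so green simulation tests say nothing about robustness to
those features of real data; the genomics path is instead exercised on
generated genotype fixtures with known ground truth.

## Genotype front-end

Dosage is the alternate-allele count in {0, 1, 2}, NaN for missing. VCF is
read through cyvcf2; PLINK 1.9 bed/bim/fam through a minimal SNP-major
2-bit codec (A1 = alternate, so the two encodings of one panel agree).
Only biallelic SNPs are kept. QC applies, in order, MAF < 0.01 removal,
any-missingness removal, and the exact conditional Hardy-Weinberg test at
p < 1e−5 — each variant charged to the first filter it fails; the exact
test (rather than the chi-square approximation) is the field standard and
more conservative at rare genotype counts. Severities are computed per
chromosome on the standardized dosage matrix, plus one genome-wide summary.
Windowed LD measures use a variant-count radius t with edge clipping; a
centiMorgan window would need a genetic map the package does not ingest —
documented limitation. The LDadj/LDscore windows include the index
variant's self term (1 and exactly 1 respectively).

## Numerical choices

* Variance divisor n−1 everywhere; this is what makes Σ d² = (n−1)p and
  r_jj = 1 exact.
* Zero tolerance 1e−10 relative to d₁ for rank decisions, condition-number
  infinities and w2's inverse sums.
* w1/w2 thresholds use strict inequality.
* BsRs and LsRs are clipped to [0, 1] against −1e−16-scale rounding;
  LsRs ≤ 1 holds analytically via the upper bound on Σ sR_j.
* SVD sign ambiguity is irrelevant (only squared entries enter); no
  singular-value tie-breaking is needed (all formulas are symmetric in the
  spectrum).
* Constant columns are an error at standardization, not silently dropped;
  the CLI offers `--drop-constant` with a logged count.
* CLI tables are written with 17 significant digits so files round-trip to
  the in-memory doubles.

## Problem sizes in tests

The test and acceptance workloads use the native study conditions where
they are cheap (n=500, p=1000 single draws; 200-replicate expectation
checks at n=500, p=50) and small synthetic panels (hundreds of samples,
tens of variants) for the genomics path; the full suite runs in well under
a minute on one CPU.

## Known limitations

* With the printed default τ = (n−p)², w2 = 0 away from n ≈ p, so sRs
  responds to a single near-collinear pair essentially only through Σ sR_j
  — barely more than Red does. Users probing local structure should inspect
  the per-variable sR_j (where the pair is plainly visible) or the
  condition number, or set `w2_threshold` deliberately.
* The expectation formula carries the O(1/n) standardization offset noted
  above; at n=500, p=50 it is ~0.004 against a null mean of ~1.098.
* Left-severity scaling is advisory on column-standardized data.
* No X-chromosome sex-ratio handling, no imputation or phasing, no
  genetic-map windows, no response-dependent diagnostics (CVIF), and no
  distribution theory for sR_j — point summaries only.
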