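import numpy as np
import pytest

from ubva.data import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_standardized(rng):
    """A generic 30 x 6 column-standardized Gaussian matrix."""
    return standardize(rng.standard_normal((30, 6)), "columns")


def make_correlated_pair(n: int, r: float, seed: int = 0) -> np.ndarray:
    """Two columns with exact sample correlation r (constructed, not drawn)."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    a = (a - a.mean()) / a.std(ddof=1)
    # orthogonalize b against a, then mix to hit r exactly
    b = b - b.mean()
    b -= (b @ a) / (a @ a) * a
    b /= b.std(ddof=1)
    x2 = r * a + np.sqrt(1 - r ** 2) * b
    return np.column_stack([a, x2])


def write_vcf(path, variants, genotypes, samples=None):
    """Write a minimal VCF 4.2 text file.

    variants: list of (chrom, pos, vid, ref, alt) where alt may hold commas
    (multi-allelic).  genotypes: list of per-variant lists of GT strings.
    """
    samples = samples or [f"S{i+1}" for i in range(len(genotypes[0]))]
    lines = ["##fileformat=VCFv4.2"]
    chroms = {v[0] for v in variants}
    for c in sorted(chroms):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for (chrom, pos, vid, ref, alt), gts in zip(variants, genotypes):
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts))
    path = str(path)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def dosage_to_gts(column):
    """Map a dosage column (0/1/2/np.nan) to VCF GT strings."""
    table = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    return [table.get(float(d), "./.") if not np.isnan(d) else "./."
            for d in column]
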