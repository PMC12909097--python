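"""Genotype-panel ingestion, SNP quality control and severity scans.

Dosage coding is the count of the alternate (A1) allele in {0, 1, 2}, with
NaN for missing calls.  Supported formats: VCF 4.x (plain or bgzipped, read
through cyvcf2) and PLINK 1.9 bed/bim/fam triples (a minimal SNP-major
2-bit codec implemented here).  Quality control mirrors standard GWAS
practice: drop non-biallelic records, then filter on minor allele
frequency, missingness and the Hardy-Weinberg exact test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .backends import BackendConfig, compute
from .data import standardize
from .measures import GlobalSummary, SeverityProfile

__all__ = ["GenotypePanel", "QcReport", "load_genotypes", "write_plink",
           "hwe_exact_test", "qc_filter", "chromosome_scan",
           "intersect_variants", "subset_samples"]

logger = logging.getLogger(__name__)

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypePanel:
    """Dosage matrix (samples x variants) plus variant/sample metadata."""

    dosage: np.ndarray                 # float, entries in {0,1,2, nan}
    variants: pd.DataFrame             # columns chrom, pos, id, ref, alt
    samples: list[str]
    build: str = "GRCh37/hg19"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError("dosage shape inconsistent with metadata")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant, missing calls ignored."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class QcReport:
    input_variants: int
    removed_maf: int = 0
    removed_missing: int = 0
    removed_hwe: int = 0
    removed_non_biallelic: int = 0
    retained: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _sort_panel(dosage, variants, samples, build) -> GenotypePanel:
    order = variants.sort_values(["chrom", "pos"], kind="stable").index
    if not np.array_equal(order.to_numpy(), np.arange(len(variants))):
        warnings.warn("variants were not sorted by (chrom, pos); sorting",
                      RuntimeWarning)
        dosage = dosage[:, order]
        variants = variants.loc[order].reset_index(drop=True)
    return GenotypePanel(dosage, variants.reset_index(drop=True), samples,
                         build=build)


def _load_vcf(path: str) -> tuple[GenotypePanel, int]:
    from cyvcf2 import VCF
    vcf = VCF(path)
    samples = list(vcf.samples)
    cols, rows, dropped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped += 1
            continue
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(rec.gt_types, dtype=float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0],
                        default=np.nan)
        cols.append(dos)
        rows.append((str(rec.CHROM), int(rec.POS),
                     rec.ID or f"{rec.CHROM}:{rec.POS}", rec.REF, rec.ALT[0]))
    if not cols:
        raise ValueError(f"no biallelic SNPs found in {path}")
    dosage = np.column_stack(cols)
    variants = pd.DataFrame(rows, columns=_VARIANT_COLS)
    return _sort_panel(dosage, variants, samples, "GRCh37/hg19"), dropped


def _load_plink(prefix: str) -> tuple[GenotypePanel, int]:
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"iid": str})
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != b"\x6c\x1b\x01":
        raise ValueError(f"{prefix}.bed: bad magic or not SNP-major")
    n, m = len(fam), len(bim)
    stride = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != stride * m:
        raise ValueError(f"{prefix}.bed: truncated (expected {stride * m} "
                         f"bytes, found {body.size})")
    codes = body.reshape(m, stride)
    # unpack 2-bit pairs, low bits first
    bits = np.stack([(codes >> (2 * i)) & 0b11 for i in range(4)], axis=-1)
    bits = bits.reshape(m, stride * 4)[:, :n]        # (variants, samples)
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosage = lut[bits].T
    variants = bim[["chrom", "pos", "id"]].assign(ref=bim["a2"], alt=bim["a1"])
    return _sort_panel(dosage, variants[_VARIANT_COLS],
                       fam["iid"].tolist(), "GRCh37/hg19"), 0


def load_genotypes(path, format: str | None = None) -> GenotypePanel:
    """Load a genotype panel from VCF or PLINK bed/bim/fam.

    Only biallelic SNPs are kept (multi-allelic and indel records are
    dropped with a logged count).  Dosage counts the alternate allele
    (PLINK A1).
    """
    path = str(path)
    if format is None:
        format = "plink" if path.endswith((".bed", ".bim", ".fam")) \
            or Path(path + ".bed").exists() else "vcf"
    if format == "vcf":
        panel, dropped = _load_vcf(path)
    elif format == "plink":
        panel, dropped = _load_plink(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if dropped:
        logger.info("dropped %d non-biallelic/non-SNP records", dropped)
    panel._non_biallelic_dropped = dropped
    return panel


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as a PLINK 1.9 SNP-major bed/bim/fam triple
    (A1 = alternate allele, so dosage coding round-trips)."""
    prefix = str(prefix)
    n, m = panel.n_samples, panel.n_variants
    v = panel.variants
    bim = pd.DataFrame({"chrom": v["chrom"], "id": v["id"], "cm": 0,
                        "pos": v["pos"], "a1": v["alt"], "a2": v["ref"]})
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": panel.samples, "iid": panel.samples,
                        "pat": 0, "mat": 0, "sex": 0, "pheno": -9})
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    inv = {2.0: 0, 1.0: 2, 0.0: 3}                 # dosage -> 2-bit code
    stride = (n + 3) // 4
    out = np.zeros((m, stride * 4), dtype=np.uint8)
    d = panel.dosage.T                              # (variants, samples)
    codes = np.where(np.isnan(d), 1, 0).astype(np.uint8)
    for dos, code in inv.items():
        codes[d == dos] = code
    out[:, :n] = codes
    packed = (out.reshape(m, stride, 4)
              * np.array([1, 4, 16, 64], dtype=np.uint8)).sum(
                  axis=-1, dtype=np.uint8)
    Path(prefix + ".bed").write_bytes(b"\x6c\x1b\x01" + packed.tobytes())


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Sums, under the conditional distribution of heterozygote count given
    the allele counts, the probabilities of all heterozygote configurations
    no more likely than the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be nonnegative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of the conditional distribution
    from scipy.special import gammaln
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (hets * np.log(2.0)
            - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def qc_filter(panel: GenotypePanel, maf_min: float = 0.01,
              max_missing: float = 0.0, hwe_p_min: float = 1e-5
              ) -> tuple[GenotypePanel, QcReport]:
    """Apply the MAF / missingness / HWE filters in that order.

    Each variant is charged to the first filter it fails.  Defaults follow
    common practice for reference-panel LD analyses: MAF < 0.01 removed,
    any missingness removed, HWE exact p < 1e-5 removed.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    if not (0.0 <= hwe_p_min <= 1.0):
        raise ValueError("hwe_p_min must be in [0, 1]")
    d = panel.dosage
    report = QcReport(input_variants=panel.n_variants,
                      removed_non_biallelic=getattr(
                          panel, "_non_biallelic_dropped", 0),
                      thresholds={"maf_min": maf_min,
                                  "max_missing": max_missing,
                                  "hwe_p_min": hwe_p_min})
    fail_maf = panel.maf() < maf_min
    miss = np.isnan(d).mean(axis=0)
    fail_miss = (miss > max_missing) & ~fail_maf
    keep_so_far = ~(fail_maf | fail_miss)
    fail_hwe = np.zeros(panel.n_variants, dtype=bool)
    for j in np.nonzero(keep_so_far)[0]:
        col = d[:, j]
        col = col[~np.isnan(col)]
        counts = [int((col == g).sum()) for g in (0.0, 1.0, 2.0)]
        if hwe_exact_test(*counts) < hwe_p_min:
            fail_hwe[j] = True
    keep = keep_so_far & ~fail_hwe
    report.removed_maf = int(fail_maf.sum())
    report.removed_missing = int(fail_miss.sum())
    report.removed_hwe = int(fail_hwe.sum())
    report.retained = int(keep.sum())
    out = GenotypePanel(d[:, keep],
                        panel.variants.loc[keep].reset_index(drop=True),
                        panel.samples, build=panel.build)
    return out, report


def chromosome_scan(panel: GenotypePanel,
                    backend: BackendConfig | None = None
                    ) -> tuple[pd.DataFrame, dict[str, GlobalSummary]]:
    """Per-chromosome severity scan in Manhattan-ready form.

    Severities are computed within each chromosome independently on the
    column-standardized dosage matrix; the returned table is ordered by
    (chrom, pos) and carries chrom, pos, id, maf, sR columns.  A
    genome-wide summary over all retained variants is included under the
    key ``"genome"``.
    """
    backend = backend or BackendConfig()
    if np.isnan(panel.dosage).any():
        raise ValueError("panel contains missing calls; run qc_filter first")
    frames, summaries = [], {}
    maf = panel.maf()
    for chrom, grp in panel.variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if idx.size < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 variants, "
                          "skipped", RuntimeWarning)
            continue
        dm = standardize(panel.dosage[:, idx], "columns",
                         variable_names=grp["id"].tolist())
        profile, summary = compute(dm, backend)
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": grp["pos"].to_numpy(),
            "id": grp["id"].to_numpy(), "maf": maf[idx],
            "sR": profile.scaled}))
        summaries[str(chrom)] = summary
    if not frames:
        raise ValueError("no chromosome had >= 2 variants")
    table = pd.concat(frames, ignore_index=True)
    if panel.n_variants >= 2 and len(summaries) >= 1:
        dm_all = standardize(panel.dosage, "columns")
        _, summaries["genome"] = compute(dm_all, backend)
    return table, summaries


def intersect_variants(panels: list[GenotypePanel]) -> list[GenotypePanel]:
    """Restrict each panel to the variant ids present in all panels
    (harmonization step for cross-population comparisons)."""
    shared = set(panels[0].variants["id"])
    for p in panels[1:]:
        shared &= set(p.variants["id"])
    out = []
    for p in panels:
        keep = p.variants["id"].isin(shared).to_numpy()
        out.append(GenotypePanel(p.dosage[:, keep],
                                 p.variants.loc[keep].reset_index(drop=True),
                                 p.samples, build=p.build))
    return out


def subset_samples(panel: GenotypePanel, sample_ids: list[str]) -> GenotypePanel:
    """Per-population subsetting by sample id (order taken from the panel)."""
    wanted = set(sample_ids)
    keep = [i for i, s in enumerate(panel.samples) if s in wanted]
    if not keep:
        raise ValueError("no requested samples found in panel")
    return GenotypePanel(panel.dosage[keep, :], panel.variants.copy(),
                         [panel.samples[i] for i in keep], build=panel.build)
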