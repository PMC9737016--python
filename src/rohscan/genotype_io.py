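"""VCF ingestion, population-level site filtering, and VCF/report output.

Reading goes through cyvcf2 (htslib); only biallelic SNP records with a GT
field are ingested.  Filtering reproduces the population-based quality
control common in resequencing studies of livestock: restrict to autosomes,
then require site quality, per-site missingness, minor allele frequency and
Hardy-Weinberg equilibrium to clear their thresholds.  Each removed site is
attributed to the *first* criterion it fails, in the fixed order

    non-biallelic -> non-autosome -> quality -> missingness -> MAF -> HWE

so that the report's counts always reconcile with the input site count.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .hwe import hwe_chisq_test, hwe_exact_test
from .panel import MISSING, SITE_COLUMNS, GenotypePanel

__all__ = [
    "FilterConfig",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "default_autosomes",
]

# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_CODE = np.array([0, 1, MISSING, 2], dtype=np.int8)

FILTER_ORDER = ["non_biallelic", "non_autosome", "quality", "missingness", "maf", "hwe"]


def default_autosomes(n: int = 29) -> frozenset[str]:
    """Autosome label set "1".."n" (cattle: 29)."""
    return frozenset(str(i) for i in range(1, n + 1))


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix; VCF dialects disagree on it."""
    return label[3:] if label.lower().startswith("chr") else label


def _chrom_sort_key(label: str):
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the population-level site filters.

    MAF, missingness and HWE comparisons are strict, matching the usual
    "MAF > 0.05, missing rate < 0.1, HWE p > 1e-6" phrasing: a site at
    exactly the threshold is removed.  ``site_quality_min`` is inclusive and
    only applied to sites that carry a quality value.
    """

    maf_min: float = 0.05
    max_missing_rate: float = 0.1
    hwe_p_min: float = 1e-6
    autosomes: frozenset[str] = field(default_factory=default_autosomes)
    site_quality_min: float | None = 20.0
    hwe_method: str = "exact"  # "exact" (Levene) or "chisq"
    impute_missing: bool = False  # naive modal-genotype imputation after filtering

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.site_quality_min is not None and self.site_quality_min < 0:
            raise ValueError("site_quality_min must be >= 0")
        if self.hwe_method not in ("exact", "chisq"):
            raise ValueError(f"unknown hwe_method {self.hwe_method!r}")


@dataclass
class FilterReport:
    """Site accounting of one filtering pass: input = retained + removed."""

    n_input_sites: int
    n_removed: dict[str, int]
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_input_sites != self.n_retained + sum(self.n_removed.values()):
            raise ValueError("filter report does not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input_sites)]
        rows += [(f"removed_{k}", self.n_removed.get(k, 0)) for k in FILTER_ORDER]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["criterion", "n_sites"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_vcf(
    path,
    autosomes: set[str] | frozenset[str] | None = None,
    min_genotype_depth: int | None = None,
) -> GenotypePanel:
    """Read a multi-sample VCF into a GenotypePanel.

    Only biallelic SNP records are ingested; if ``autosomes`` is given,
    records on other chromosomes are dropped during reading (without
    accounting — use :func:`apply_site_filters` on an unrestricted panel for
    a reconciled report).  Phased and unphased genotypes are coded
    identically.  ``min_genotype_depth`` masks individual genotype calls
    whose FORMAT DP is not greater than the threshold, when DP is present.

    Raises ``ValueError`` on a sample-less VCF, duplicate (chrom, pos)
    records, or a record that cannot be parsed (named by record index).
    """
    allowed = None if autosomes is None else {normalize_chrom(a) for a in autosomes}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")
    site_rows: list[tuple] = []
    geno_cols: list[np.ndarray] = []
    record_idx = 0
    while True:
        try:
            variant = next(vcf, None)
        except Exception as exc:  # htslib parse failure
            raise ValueError(f"{path}: malformed VCF record #{record_idx + 1}: {exc}") from exc
        if variant is None:
            break
        record_idx += 1
        if len(variant.ALT) != 1 or not variant.is_snp:
            continue
        chrom = normalize_chrom(variant.CHROM)
        if allowed is not None and chrom not in allowed:
            continue
        codes = _GT_TYPE_TO_CODE[variant.gt_types]
        if min_genotype_depth is not None:
            depth = variant.format("DP")
            if depth is not None:
                codes = codes.copy()
                codes[depth[:, 0] <= min_genotype_depth] = MISSING
        site_rows.append((chrom, variant.POS, variant.REF, variant.ALT[0], variant.QUAL))
        geno_cols.append(codes)
    vcf.close()
    sites = pd.DataFrame(site_rows, columns=SITE_COLUMNS)
    if len(sites):
        dup = sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            first = sites.loc[dup.idxmax()]
            raise ValueError(f"{path}: duplicate record at {first.chrom}:{first.pos}")
        order = sorted(
            range(len(sites)),
            key=lambda i: (_chrom_sort_key(site_rows[i][0]), site_rows[i][1]),
        )
        sites = sites.iloc[order].reset_index(drop=True)
        genotypes = np.stack([geno_cols[i] for i in order], axis=1)
    else:
        genotypes = np.empty((len(samples), 0), dtype=np.int8)
    sites["pos"] = sites["pos"].astype(np.int64)
    return GenotypePanel(sites=sites, individuals=samples, genotypes=genotypes)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as VCF v4.2 (gzip if the path ends in .gz).

    Round-trips exactly through :func:`read_vcf` on (chrom, pos, alleles,
    genotype codes).  Missing genotypes are written as ``./.``.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscan\n")
        for chrom in panel.chromosomes:
            sl = panel.chromosome_slice(chrom)
            max_pos = int(panel.sites["pos"].iloc[sl.stop - 1]) if sl.stop > sl.start else 1
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        quals = panel.sites["qual"]
        for j, row in enumerate(panel.sites.itertuples(index=False)):
            q = quals.iloc[j]
            qual_str = "." if q is None or (isinstance(q, float) and np.isnan(q)) else f"{q:g}"
            gts = "\t".join(gt_strings[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{qual_str}\t.\t.\tGT\t{gts}\n"
            )


def _site_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site counts of (hom-ref, het, hom-alt, missing)."""
    n0 = (genotypes == 0).sum(axis=0)
    n1 = (genotypes == 1).sum(axis=0)
    n2 = (genotypes == 2).sum(axis=0)
    nm = (genotypes == MISSING).sum(axis=0)
    return n0, n1, n2, nm


def apply_site_filters(
    panel: GenotypePanel, cfg: FilterConfig | None = None
) -> tuple[GenotypePanel, FilterReport]:
    """Apply the population-level site filters; return filtered panel + report.

    Retained sites satisfy, in this order of attribution: biallelic SNP
    (guaranteed by the panel type), autosomal chromosome, site quality >=
    ``site_quality_min`` (when a quality value is present), missing fraction
    < ``max_missing_rate``, MAF > ``maf_min`` and HWE p > ``hwe_p_min``.
    An emptied panel is a warning, not an error.
    """
    if cfg is None:
        cfg = FilterConfig()
    if panel.n_sites == 0:
        raise ValueError("cannot filter an empty panel")
    n_sites = panel.n_sites
    removed = dict.fromkeys(FILTER_ORDER, 0)
    # sites are biallelic SNPs by construction of the panel type
    undecided = np.ones(n_sites, dtype=bool)

    allowed = {normalize_chrom(a) for a in cfg.autosomes}
    chrom_ok = panel.sites["chrom"].map(normalize_chrom).isin(allowed).to_numpy()
    removed["non_autosome"] = int((~chrom_ok & undecided).sum())
    undecided &= chrom_ok

    if cfg.site_quality_min is not None:
        quals = pd.to_numeric(panel.sites["qual"], errors="coerce").to_numpy(dtype=float)
        qual_ok = np.isnan(quals) | (quals >= cfg.site_quality_min)
        removed["quality"] = int((~qual_ok & undecided).sum())
        undecided &= qual_ok

    n0, n1, n2, nm = _site_counts(panel.genotypes)
    n_ind = panel.n_individuals
    miss_ok = nm / n_ind < cfg.max_missing_rate
    removed["missingness"] = int((~miss_ok & undecided).sum())
    undecided &= miss_ok

    called = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = (2 * n2 + n1) / (2 * called)
    maf = np.minimum(alt_freq, 1 - alt_freq)
    maf_ok = (called > 0) & (maf > cfg.maf_min)
    removed["maf"] = int((~maf_ok & undecided).sum())
    undecided &= maf_ok

    test = hwe_exact_test if cfg.hwe_method == "exact" else hwe_chisq_test
    hwe_ok = undecided.copy()
    for j in np.flatnonzero(undecided):
        hwe_ok[j] = test(int(n0[j]), int(n1[j]), int(n2[j])) > cfg.hwe_p_min
    removed["hwe"] = int((undecided & ~hwe_ok).sum())
    keep = undecided & hwe_ok

    out = panel.subset_sites(keep)
    if out.n_sites == 0:
        warnings.warn("all sites removed by filtering; returning an empty panel")
    if cfg.impute_missing and out.n_sites:
        out = _impute_modal(out)
    report = FilterReport(
        n_input_sites=n_sites, n_removed=removed, n_retained=int(keep.sum())
    )
    return out, report


def _impute_modal(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing codes with the site's most frequent genotype (ties -> lowest code)."""
    geno = panel.genotypes.copy()
    n0, n1, n2, nm = _site_counts(geno)
    modal = np.argmax(np.stack([n0, n1, n2]), axis=0).astype(np.int8)
    miss = geno == MISSING
    geno[miss] = np.broadcast_to(modal, geno.shape)[miss]
    return GenotypePanel(sites=panel.sites, individuals=panel.individuals, genotypes=geno)
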