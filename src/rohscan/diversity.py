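"""Per-site diversity statistics, individual heterozygosity, and the GRM.

Per-site nucleotide diversity follows the unbiased estimator

    pi = n/(n-1) * (1 - sum_i x_i^2)

with ``n`` the number of non-missing allele copies at the site and ``x_i``
the observed frequency of allele ``i`` — equal to the probability that two
allele copies drawn without replacement differ.  The pairwise relatedness
matrix is the allele-frequency-standardized genomic relationship matrix of
Yang et al. (2010) / GCTA:

    A_jk = 1/N * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))
    A_jj = 1 + 1/N * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

with genotype dosages x in {0,1,2}, sample alternate-allele frequencies p_i,
and N the number of sites where both pair members are called (pairwise
complete).  Monomorphic sites are excluded from the sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

__all__ = [
    "SiteDiversity",
    "IndividualHet",
    "site_maf",
    "site_pi",
    "site_diversity",
    "site_diversity_table",
    "individual_het",
    "individual_het_table",
    "relatedness_matrix",
]


@dataclass(frozen=True)
class SiteDiversity:
    maf: float
    pi: float
    n_sequences: int  # non-missing allele copies (the estimator's n)
    alt_freq: float


@dataclass(frozen=True)
class IndividualHet:
    individual: str
    ho: float
    n_called: int


def _allele_counts(column: np.ndarray) -> tuple[int, int]:
    """(alt allele copies, total non-missing allele copies) of one site column."""
    column = np.asarray(column)
    called = column != MISSING
    return int(column[called].sum()), int(2 * called.sum())


def site_maf(column: np.ndarray) -> float:
    """Minor-allele frequency of one genotype column; NaN if no calls."""
    n_alt, n_seq = _allele_counts(column)
    if n_seq == 0:
        return float("nan")
    p = n_alt / n_seq
    return min(p, 1.0 - p)


def site_pi(column: np.ndarray) -> float:
    """Per-site nucleotide diversity; NaN with fewer than 2 allele copies."""
    n_alt, n_seq = _allele_counts(column)
    if n_seq < 2:
        return float("nan")
    p = n_alt / n_seq
    return n_seq / (n_seq - 1) * (1.0 - (p**2 + (1.0 - p) ** 2))


def site_diversity(column: np.ndarray) -> SiteDiversity:
    n_alt, n_seq = _allele_counts(column)
    if n_seq == 0:
        return SiteDiversity(float("nan"), float("nan"), 0, float("nan"))
    p = n_alt / n_seq
    pi = float("nan") if n_seq < 2 else n_seq / (n_seq - 1) * (1 - p**2 - (1 - p) ** 2)
    return SiteDiversity(maf=min(p, 1 - p), pi=pi, n_sequences=n_seq, alt_freq=p)


def site_diversity_table(panel: GenotypePanel) -> pd.DataFrame:
    """Vectorized per-site table: chrom, pos, maf, pi, n_sequences, alt_freq."""
    g = panel.genotypes
    called = g != MISSING
    n_seq = 2 * called.sum(axis=0)
    n_alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_seq > 0, n_alt / np.maximum(n_seq, 1), np.nan)
        pi = np.where(
            n_seq >= 2,
            n_seq / np.maximum(n_seq - 1, 1) * (1 - p**2 - (1 - p) ** 2),
            np.nan,
        )
    return pd.DataFrame(
        {
            "chrom": panel.sites["chrom"],
            "pos": panel.sites["pos"],
            "maf": np.minimum(p, 1 - p),
            "pi": pi,
            "n_sequences": n_seq,
            "alt_freq": p,
        }
    )


def individual_het(row: np.ndarray, individual: str = "") -> IndividualHet:
    """Observed heterozygosity of one individual over its called genotypes."""
    row = np.asarray(row)
    called = row != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        return IndividualHet(individual, float("nan"), 0)
    ho = float((row[called] == 1).sum() / n_called)
    return IndividualHet(individual, ho, n_called)


def individual_het_table(panel: GenotypePanel) -> pd.DataFrame:
    called = panel.genotypes != MISSING
    n_called = called.sum(axis=1)
    n_het = (panel.genotypes == 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    return pd.DataFrame(
        {"individual": panel.individuals, "ho": ho, "n_called": n_called}
    )


def relatedness_matrix(panel: GenotypePanel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """GCTA-style genomic relationship matrix with pairwise-complete sites.

    Returns ``(A, N)``: the relatedness matrix and the per-pair count of
    sites used, both as square DataFrames indexed by sample id.  Allele
    frequencies come from the panel itself; monomorphic sites contribute
    nothing.  A pair sharing no called site gets NaN.
    """
    if panel.n_individuals < 2:
        raise ValueError("relatedness requires at least 2 individuals")
    g = panel.genotypes.astype(np.float64)
    called = panel.genotypes != MISSING

    n_seq = 2 * called.sum(axis=0)
    n_alt = np.where(called, g, 0.0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_seq > 0, n_alt / np.maximum(n_seq, 1), np.nan)
    poly = called.any(axis=0) & (p > 0) & (p < 1)

    gp = g[:, poly]
    m = called[:, poly]
    pv = p[poly]
    denom = 2.0 * pv * (1.0 - pv)

    z = np.where(m, (gp - 2.0 * pv) / np.sqrt(denom), 0.0)
    num = z @ z.T
    n_pair = m.astype(np.int64) @ m.astype(np.int64).T
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(n_pair > 0, num / np.maximum(n_pair, 1), np.nan)

    # diagonal uses the dedicated GCTA self-relatedness estimator
    diag_terms = np.where(m, (gp**2 - (1.0 + 2.0 * pv) * gp + 2.0 * pv**2) / denom, 0.0)
    n_self = m.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        diag = np.where(n_self > 0, 1.0 + diag_terms.sum(axis=1) / np.maximum(n_self, 1), np.nan)
    np.fill_diagonal(a, diag)

    ids = panel.individuals
    return (
        pd.DataFrame(a, index=ids, columns=ids),
        pd.DataFrame(n_pair, index=ids, columns=ids),
    )
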