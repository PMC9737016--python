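"""Hardy-Weinberg equilibrium tests on genotype counts.

The exact test conditions on the observed allele counts and evaluates the
Levene distribution of the heterozygote count: given ``n`` diploid
individuals with ``n_rare`` copies of the rarer allele, the probability of
observing ``h`` heterozygotes is

    P(h) = n! / (n_AA! n_Aa! n_aa!) * n_A! n_a! / (2n)! * 2^h

and the two-sided p-value sums P(h') over all configurations no more
probable than the observed one (Levene 1949; Wigginton et al. 2005).  A
chi-square alternative with 1 df is provided for parity with array-era
pipelines but the exact test is the default everywhere in this package.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = ["hwe_exact_test", "hwe_chisq_test"]


def _levene_log_probs(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log-probabilities of each admissible heterozygote count.

    Returns (het_counts, log_probs); het counts share the parity of n_rare
    and satisfy 0 <= h <= n_rare and (n_rare - h)/2 <= n - ... (implied by
    the multinomial support).
    """
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    n_aa = (n_rare - hs) // 2
    n_AA = n - hs - n_aa
    valid = n_AA >= 0
    hs, n_aa, n_AA = hs[valid], n_aa[valid], n_AA[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA + 1)
        - gammaln(hs + 1)
        - gammaln(n_aa + 1)
        + hs * np.log(2.0)
    )
    return hs, logp


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact HWE p-value for one site's genotype counts.

    Parameters are the counts of homozygous-reference, heterozygous and
    homozygous-alternate individuals (non-missing calls only).  Returns a
    p-value in (0, 1]; a monomorphic site returns 1.0.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one called genotype required for the HWE test")
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    n_rare = min(n_ref, n_alt)
    if n_rare == 0:
        return 1.0
    hs, logp = _levene_log_probs(n, n_rare)
    logp = logp - logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hs, n_het)]
    # tolerance guards against unequal rounding of tied configurations
    p = float(probs[probs <= obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square goodness-of-fit HWE p-value (no continuity correction)."""
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one called genotype required for the HWE test")
    p = (2 * n_hom_alt + n_het) / (2 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    stat = float(((np.array(counts) - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, df=1))
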