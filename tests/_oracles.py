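"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from first principles (exact
rational arithmetic, exhaustive enumeration) and share no code with the
implementation they check.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational Levene enumeration of the two-sided HWE p-value."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n_hom_ref + n_het
    n_rare = min(n_ref, n_alt)
    if n_rare == 0:
        return 1.0
    probs: dict[int, Fraction] = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        n_rare_hom = (n_rare - h) // 2
        n_common_hom = n - h - n_rare_hom
        if n_common_hom < 0:
            continue
        probs[h] = Fraction(2) ** h * comb(n, h) * comb(n - h, n_rare_hom)
    total = sum(probs.values())
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs) / total)


def pi_pairwise_oracle(column: np.ndarray) -> float:
    """Mean pairwise allele difference over all pairs of non-missing allele copies."""
    alleles: list[int] = []
    for g in column:
        if g == -1:
            continue
        alleles.extend({0: (0, 0), 1: (0, 1), 2: (1, 1)}[int(g)])
    if len(alleles) < 2:
        return float("nan")
    pairs = list(combinations(range(len(alleles)), 2))
    diff = sum(1 for i, j in pairs if alleles[i] != alleles[j])
    return diff / len(pairs)


def window_flags_oracle(codes, window_size, max_het, max_missing, threshold,
                        edge_mode="shrink", eps=1e-9):
    """Exhaustive enumeration of every window and every covering-window proportion.

    The >=-with-epsilon comparison is the documented pass convention shared
    with the implementation; everything upstream of that comparison is
    derived independently here.
    """
    codes = list(codes)
    n = len(codes)
    if n == 0:
        return np.zeros(0, dtype=bool)

    def homozygous(win):
        return (
            sum(1 for c in win if c == 1) <= max_het
            and sum(1 for c in win if c == -1) <= max_missing
        )

    if n < window_size:
        windows = [(0, n)]
    else:
        windows = [(s, s + window_size) for s in range(n - window_size + 1)]
    hom = [homozygous(codes[a:b]) for a, b in windows]
    flags = []
    for i in range(n):
        covering = [k for k, (a, b) in enumerate(windows) if a <= i < b]
        n_hom = sum(hom[k] for k in covering)
        denom = len(covering) if edge_mode == "shrink" else window_size
        flags.append(n_hom / denom + eps >= threshold)
    return np.array(flags, dtype=bool)


def overlap_join_oracle(islands, genes):
    """All-pairs interval overlap (1-based inclusive)."""
    out = []
    for isl in islands:
        hits = tuple(
            g
            for g in genes
            if g.chrom == isl.chrom and g.start <= isl.end_pos and g.end >= isl.start_pos
        )
        out.append(hits)
    return out
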