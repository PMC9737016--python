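"""In-memory genotype panel: individuals x ordered autosomal SNP sites.

Genotypes are coded per individual per site as

* ``0``  homozygous reference
* ``1``  heterozygous
* ``2``  homozygous alternate
* ``-1`` missing

The panel is the single container every downstream module consumes.  Sites
are kept in a pandas DataFrame (``chrom``, ``pos``, ``ref``, ``alt``,
``qual``) sorted by chromosome then position; the genotype matrix is a dense
``int8`` array of shape (n_individuals, n_sites) aligned to that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP site (1-based position, single-base alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"not a SNP: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("site quality must be non-negative")


@dataclass
class GenotypePanel:
    """Ordered SNP sites x sample identifiers x genotype-code matrix."""

    sites: pd.DataFrame
    individuals: list[str]
    genotypes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_site = self.genotypes.shape
        if n_ind != len(self.individuals):
            raise ValueError(
                f"genotype matrix has {n_ind} rows but {len(self.individuals)} individuals"
            )
        if n_site != len(self.sites):
            raise ValueError(
                f"genotype matrix has {n_site} columns but {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")
        self._check_site_order()

    def _check_site_order(self) -> None:
        pos = self.sites["pos"].to_numpy()
        chrom = self.sites["chrom"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        if np.any(same & (pos[1:] <= pos[:-1])):
            raise ValueError("sites must be strictly increasing in pos within chromosome")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in panel order (first-appearance order)."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def chromosome_slice(self, chrom: str) -> slice:
        """Contiguous column slice of one chromosome's sites."""
        mask = (self.sites["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return slice(0, 0)
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"sites of chromosome {chrom!r} are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset_sites(self, keep: np.ndarray) -> "GenotypePanel":
        """New panel restricted to a boolean/index site selection."""
        keep = np.asarray(keep)
        sites = self.sites.iloc[keep].reset_index(drop=True) if keep.dtype != bool else (
            self.sites.loc[keep].reset_index(drop=True)
        )
        return GenotypePanel(
            sites=sites,
            individuals=list(self.individuals),
            genotypes=self.genotypes[:, keep],
        )


def make_sites(records: list[VariantSite] | list[tuple]) -> pd.DataFrame:
    """Build a site table from VariantSite objects or (chrom,pos,ref,alt[,qual]) tuples."""
    rows = []
    for r in records:
        if isinstance(r, VariantSite):
            rows.append((r.chrom, r.pos, r.ref, r.alt, r.qual))
        else:
            chrom, pos, ref, alt, *rest = r
            rows.append((str(chrom), int(pos), ref, alt, rest[0] if rest else None))
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return df
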