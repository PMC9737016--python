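"""ROH islands: per-SNP ROH incidence and significant-region calling.

A SNP's incidence is the fraction of individuals whose ROH cover it.  SNPs
whose incidence strictly exceeds the threshold (default 0.30, i.e. "more
than 30% of samples") are significant; consecutive significant SNPs on one
chromosome closer than the cluster gap are grouped into islands.  The gap
rule is an explicit, reportable convention — the incidence track is always
exportable so regions can be re-clustered under any other rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh import ROHSegment
from .summary import round_half_away

__all__ = [
    "IslandParams",
    "Island",
    "snp_incidence",
    "call_islands",
    "island_length_kb",
    "islands_to_frame",
]


@dataclass(frozen=True)
class IslandParams:
    incidence_threshold: float = 0.30  # strict >
    cluster_max_gap_bp: int = 250_000

    def __post_init__(self) -> None:
        if not 0.0 < self.incidence_threshold < 1.0:
            raise ValueError("incidence_threshold must be in (0, 1)")
        if self.cluster_max_gap_bp <= 0:
            raise ValueError("cluster_max_gap_bp must be positive")


@dataclass(frozen=True)
class Island:
    """A region of consecutive significant SNPs (outermost SNP positions)."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snp: int
    peak_incidence: float

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("island start after end")

    @property
    def length_kb(self) -> int:
        return island_length_kb(self)


def island_length_kb(island: Island) -> int:
    """Region length in kb: round((end - start + 1)/1000), half away from zero."""
    return round_half_away((island.end_pos - island.start_pos + 1) / 1000.0)


def snp_incidence(
    segments: list[ROHSegment], sites: pd.DataFrame, n_individuals: int
) -> pd.DataFrame:
    """Per-site count and fraction of individuals whose ROH cover the site.

    ``sites`` must carry position-sorted ``chrom``/``pos`` columns (a panel's
    site table).  Returns chrom, pos, k (covering individuals), incidence.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    k = np.zeros(len(sites), dtype=np.int64)
    pos_by_chrom = {
        str(chrom): (grp.index.to_numpy(), grp["pos"].to_numpy())
        for chrom, grp in sites.groupby("chrom", sort=False)
    }
    by_ind_chrom: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        by_ind_chrom.setdefault((s.individual, s.chrom), []).append(s)
    for (_, chrom), segs in by_ind_chrom.items():
        if chrom not in pos_by_chrom:
            continue
        idx, pos = pos_by_chrom[chrom]
        covered = np.zeros(pos.size, dtype=bool)
        for s in segs:
            lo = np.searchsorted(pos, s.start_pos, side="left")
            hi = np.searchsorted(pos, s.end_pos, side="right")
            covered[lo:hi] = True
        k[idx[covered]] += 1  # one count per individual even with overlapping segments
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "k": k,
            "incidence": k / n_individuals,
        }
    )


def call_islands(track: pd.DataFrame, params: IslandParams | None = None) -> list[Island]:
    """Cluster significant SNPs (incidence strictly above threshold) into islands.

    Consecutive significant SNPs on the same chromosome at most
    ``cluster_max_gap_bp`` apart join one island; island bounds are the
    outermost significant SNP positions.
    """
    if params is None:
        params = IslandParams()
    sig = track[track["incidence"] > params.incidence_threshold]
    islands: list[Island] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        inc = grp["incidence"].to_numpy()
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > params.cluster_max_gap_bp)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [pos.size - 1]))
        for a, b in zip(starts, ends):
            islands.append(
                Island(
                    chrom=str(chrom),
                    start_pos=int(pos[a]),
                    end_pos=int(pos[b]),
                    n_snp=int(b - a + 1),
                    peak_incidence=float(inc[a : b + 1].max()),
                )
            )
    return islands


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    """Islands as a table mirroring the usual report layout (Chr, Start, End, Kb, N of SNPs)."""
    return pd.DataFrame(
        [
            (i.chrom, i.start_pos, i.end_pos, i.length_kb, i.n_snp, i.peak_incidence)
            for i in islands
        ],
        columns=["chrom", "start_pos", "end_pos", "length_kb", "n_snp", "peak_incidence"],
    )
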