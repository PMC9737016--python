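"""Sliding-window detection of runs of homozygosity (ROH).

The scan follows the window-based method popularized by PLINK ``--homozyg``
and the detectRUNS R package.  Per individual and chromosome:

1. every window of ``window_size`` consecutive SNPs is classified as
   homozygous iff it contains at most ``max_het_in_window`` heterozygous and
   at most ``max_missing_in_window`` missing calls;
2. each SNP is flagged when the proportion of homozygous windows among the
   windows covering it reaches ``window_pass_threshold`` (>=, i.e. a
   "minimum proportion" reading);
3. maximal stretches of consecutively flagged SNPs become candidate runs,
   split wherever adjacent flagged SNPs lie more than ``max_gap_bp`` apart;
4. candidates are kept as ROH when they contain at least ``min_snp_in_run``
   SNPs, span at least ``min_length_bp``, and average no more than
   ``max_kb_per_snp`` kilobases per SNP.

Near chromosome ends the number of covering windows shrinks; the default
``edge_mode="shrink"`` normalizes by the actual covering-window count (the
detectRUNS convention), while ``"skip"`` keeps the full-window denominator,
which makes edge SNPs harder to flag.  A chromosome shorter than one window
is scanned with a single truncated window covering all its SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

__all__ = [
    "ROHParams",
    "ROHSegment",
    "window_is_homozygous",
    "snp_pass_flags",
    "assemble_candidate_runs",
    "filter_runs",
    "detect_roh",
    "segments_to_frame",
    "segments_to_bed",
]

# a hair below any representable proportion step; guards float comparison at
# exact-threshold ratios like 1/20 == 0.05 without admitting smaller ratios
_PROP_EPS = 1e-9


@dataclass(frozen=True)
class ROHParams:
    """Parameterization of the window scan and the run filters.

    Defaults correspond to a dense resequencing panel: 50-SNP windows with
    at most 1 heterozygous and 5 missing calls, a covering-window pass
    proportion of 0.05, and runs of >= 100 SNPs, >= 500 kb, at least one
    SNP per 50 kb, with <= 100 kb between consecutive homozygous SNPs.
    """

    window_size: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 5
    window_pass_threshold: float = 0.05
    min_snp_in_run: int = 100
    min_length_bp: int = 500_000
    max_kb_per_snp: float = 50.0
    max_gap_bp: int = 100_000
    edge_mode: str = "shrink"

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.max_het_in_window < 0 or self.max_missing_in_window < 0:
            raise ValueError("window allowances must be >= 0")
        if not 0.0 <= self.window_pass_threshold <= 1.0:
            raise ValueError("window_pass_threshold must be in [0, 1]")
        if self.min_snp_in_run < 1 or self.min_length_bp < 1:
            raise ValueError("run minimums must be >= 1")
        if self.max_kb_per_snp <= 0 or self.max_gap_bp <= 0:
            raise ValueError("density and gap bounds must be positive")
        if self.edge_mode not in ("shrink", "skip"):
            raise ValueError(f"unknown edge_mode {self.edge_mode!r}")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: first/last SNP positions (1-based, inclusive)."""

    individual: str
    chrom: str
    start_pos: int
    end_pos: int
    n_snp: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError("segment start after end")
        if self.n_snp < 1:
            raise ValueError("segment needs at least one SNP")

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


@dataclass(frozen=True)
class CandidateRun:
    """A maximal stretch of flagged SNPs, before the run filters."""

    start_pos: int
    end_pos: int
    n_snp: int

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos + 1


def window_is_homozygous(codes: np.ndarray, params: ROHParams) -> bool:
    """True iff the window clears the heterozygote and missing allowances."""
    codes = np.asarray(codes)
    return bool(
        (codes == 1).sum() <= params.max_het_in_window
        and (codes == MISSING).sum() <= params.max_missing_in_window
    )


def snp_pass_flags(codes: np.ndarray, params: ROHParams) -> np.ndarray:
    """Flag each SNP of one chromosome by its covering-window homozygosity.

    ``codes`` is one individual's genotype vector over the chromosome's
    position-ordered SNPs.  Returns a boolean vector of equal length.
    """
    codes = np.asarray(codes)
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = params.window_size
    het = (codes == 1).astype(np.int64)
    mis = (codes == MISSING).astype(np.int64)
    if n < w:
        ok = het.sum() <= params.max_het_in_window and mis.sum() <= params.max_missing_in_window
        if params.edge_mode == "shrink":
            return np.full(n, ok)
        # skip mode keeps the full-window denominator even for the truncated window
        return np.full(n, (1.0 if ok else 0.0) / w + _PROP_EPS >= params.window_pass_threshold)

    # window start s covers SNPs [s, s+w-1]; sums via cumulative differences
    het_c = np.concatenate(([0], np.cumsum(het)))
    mis_c = np.concatenate(([0], np.cumsum(mis)))
    het_w = het_c[w:] - het_c[:-w]
    mis_w = mis_c[w:] - mis_c[:-w]
    win_ok = (het_w <= params.max_het_in_window) & (mis_w <= params.max_missing_in_window)

    ok_c = np.concatenate(([0], np.cumsum(win_ok)))
    idx = np.arange(n)
    s_lo = np.maximum(0, idx - w + 1)
    s_hi = np.minimum(idx, n - w)
    n_hom = ok_c[s_hi + 1] - ok_c[s_lo]
    n_cover = (s_hi - s_lo + 1) if params.edge_mode == "shrink" else np.full(n, w)
    return n_hom / n_cover + _PROP_EPS >= params.window_pass_threshold


def assemble_candidate_runs(
    flags: np.ndarray, positions: np.ndarray, params: ROHParams
) -> list[CandidateRun]:
    """Group flagged SNPs into candidate runs, splitting at large gaps.

    Runs are maximal stretches of consecutively flagged SNPs; within a
    stretch, a distance greater than ``max_gap_bp`` between adjacent SNPs
    splits the run.
    """
    flags = np.asarray(flags, dtype=bool)
    positions = np.asarray(positions, dtype=np.int64)
    if flags.size != positions.size:
        raise ValueError("flags and positions must align")
    runs: list[CandidateRun] = []
    i = 0
    n = flags.size
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and flags[j + 1]
            and positions[j + 1] - positions[j] <= params.max_gap_bp
        ):
            j += 1
        runs.append(
            CandidateRun(
                start_pos=int(positions[i]), end_pos=int(positions[j]), n_snp=j - i + 1
            )
        )
        i = j + 1
    return runs


def filter_runs(
    candidates: list[CandidateRun], params: ROHParams, individual: str, chrom: str
) -> list[ROHSegment]:
    """Apply the SNP-count, length and density filters to candidate runs."""
    out = []
    for c in candidates:
        if c.n_snp < params.min_snp_in_run:
            continue
        if c.length_bp < params.min_length_bp:
            continue
        if c.length_bp > c.n_snp * params.max_kb_per_snp * 1000.0:
            continue
        out.append(
            ROHSegment(
                individual=individual,
                chrom=chrom,
                start_pos=c.start_pos,
                end_pos=c.end_pos,
                n_snp=c.n_snp,
            )
        )
    return out


def detect_roh(panel: GenotypePanel, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH for every individual on every chromosome of the panel.

    Deterministic: identical input yields an identical segment list, ordered
    by individual (panel order), chromosome (panel order), then position.
    """
    if params is None:
        params = ROHParams()
    segments: list[ROHSegment] = []
    chrom_slices = [(c, panel.chromosome_slice(c)) for c in panel.chromosomes]
    for i, ind in enumerate(panel.individuals):
        for chrom, sl in chrom_slices:
            codes = panel.genotypes[i, sl]
            positions = panel.sites["pos"].to_numpy()[sl]
            flags = snp_pass_flags(codes, params)
            candidates = assemble_candidate_runs(flags, positions, params)
            segments.extend(filter_runs(candidates, params, ind, chrom))
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment list as a table (individual, chrom, start, end, n_snp, length_bp)."""
    return pd.DataFrame(
        [
            (s.individual, s.chrom, s.start_pos, s.end_pos, s.n_snp, s.length_bp)
            for s in segments
        ],
        columns=["individual", "chrom", "start_pos", "end_pos", "n_snp", "length_bp"],
    )


def segments_to_bed(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segments as 0-based half-open BED intervals, one row per segment."""
    return pd.DataFrame(
        [(s.chrom, s.start_pos - 1, s.end_pos, s.individual) for s in segments],
        columns=["chrom", "start", "end", "name"],
    )
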