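"""ROH summaries: length classes, per-chromosome counts, and F_ROH.

F_ROH — the ROH-based inbreeding coefficient — is an individual's total ROH
length divided by the length of the genome considered.  The default
denominator is the summed autosome lengths of the :class:`GenomeSpec`; a
``denominator="snp_span"`` alternative uses the first-to-last SNP span per
chromosome, which is the harsher choice when SNP coverage leaves chromosome
ends unobserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .roh import ROHSegment

__all__ = [
    "GenomeSpec",
    "LengthClassSummary",
    "FrohRecord",
    "length_class_summary",
    "froh",
    "froh_table",
    "chromosome_counts",
    "snp_span_lengths",
]

DEFAULT_CLASS_EDGES_MB = (0.5, 1.0, 2.0, 5.0)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class GenomeSpec:
    """Autosome label -> length in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def from_fai(cls, path) -> "GenomeSpec":
        """Read chromosome lengths from a samtools .fai index (first two columns)."""
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"]
        )
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


@dataclass
class LengthClassSummary:
    """ROH counts per length class (left-closed bins, last class open-ended)."""

    edges_mb: tuple[float, ...]
    counts: list[int]
    total: int

    @property
    def fractions(self) -> list[float]:
        if self.total == 0:
            return [float("nan")] * len(self.counts)
        return [c / self.total for c in self.counts]

    @property
    def percentages(self) -> list[int]:
        """Display percentages, rounded half away from zero."""
        return [round_half_away(100.0 * f) if self.total else 0 for f in self.fractions]

    @property
    def labels(self) -> list[str]:
        e = self.edges_mb
        out = [f"{e[i]:g}-{e[i + 1]:g} Mb" for i in range(len(e) - 1)]
        out.append(f">{e[-1]:g} Mb")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length_class": self.labels,
                "n_roh": self.counts,
                "fraction": self.fractions,
                "percent": self.percentages,
            }
        )


@dataclass(frozen=True)
class FrohRecord:
    individual: str
    total_roh_bp: int
    f_roh: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_roh <= 1.0:
            raise ValueError(f"f_roh out of [0,1]: {self.f_roh}")


def length_class_summary(
    segments: list[ROHSegment], edges_mb: tuple[float, ...] = DEFAULT_CLASS_EDGES_MB
) -> LengthClassSummary:
    """Bin segments by length into [e0,e1), [e1,e2), ..., [e_last, inf).

    A segment of exactly an edge length falls into the right-hand class
    (left-closed bins).
    """
    edges = tuple(float(e) for e in edges_mb)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("class edges must be strictly increasing")
    bounds_bp = [e * 1e6 for e in edges] + [float("inf")]
    counts = [0] * len(edges)
    for s in segments:
        for k in range(len(edges)):
            if bounds_bp[k] <= s.length_bp < bounds_bp[k + 1]:
                counts[k] += 1
                break
        else:
            raise ValueError(
                f"segment length {s.length_bp} bp below the first class edge"
            )
    return LengthClassSummary(edges_mb=edges, counts=counts, total=len(segments))


def froh(
    segments: list[ROHSegment],
    genome: GenomeSpec,
    individual: str | None = None,
    denominator: str = "genome",
    snp_spans: dict[str, int] | None = None,
) -> FrohRecord:
    """F_ROH of one individual: total ROH bp over the genome length.

    ``segments`` may be pre-filtered to one individual, or pass
    ``individual`` to select.  ``denominator="snp_span"`` divides by the
    summed per-chromosome SNP spans instead (requires ``snp_spans``).
    """
    if individual is not None:
        segments = [s for s in segments if s.individual == individual]
    ids = {s.individual for s in segments}
    if len(ids) > 1:
        raise ValueError(f"segments span several individuals: {sorted(ids)}")
    name = individual if individual is not None else (ids.pop() if ids else "")
    for s in segments:
        if s.chrom not in genome.lengths:
            raise ValueError(f"segment chromosome {s.chrom!r} absent from genome spec")
        if s.end_pos > genome.lengths[s.chrom]:
            raise ValueError(
                f"segment end {s.end_pos} beyond chromosome {s.chrom} "
                f"length {genome.lengths[s.chrom]}"
            )
    total = sum(s.length_bp for s in segments)
    if denominator == "genome":
        denom = genome.total_bp
    elif denominator == "snp_span":
        if snp_spans is None:
            raise ValueError("denominator='snp_span' requires snp_spans")
        denom = sum(snp_spans.values())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return FrohRecord(individual=name, total_roh_bp=total, f_roh=total / denom)


def froh_table(
    segments: list[ROHSegment],
    genome: GenomeSpec,
    individuals: list[str],
    denominator: str = "genome",
    snp_spans: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-individual F_ROH table over an explicit individual list (zeros included)."""
    rows = []
    for ind in individuals:
        rec = froh(segments, genome, individual=ind, denominator=denominator, snp_spans=snp_spans)
        rows.append((ind, rec.total_roh_bp, rec.f_roh))
    return pd.DataFrame(rows, columns=["individual", "total_roh_bp", "f_roh"])


def chromosome_counts(
    segments: list[ROHSegment], genome: GenomeSpec | None = None
) -> pd.DataFrame:
    """ROH counts per chromosome over all individuals (zero-filled from genome spec)."""
    counts: dict[str, int] = {}
    if genome is not None:
        counts = dict.fromkeys(genome.lengths, 0)
    for s in segments:
        counts[s.chrom] = counts.get(s.chrom, 0) + 1
    return pd.DataFrame(
        {"chrom": list(counts.keys()), "n_roh": list(counts.values())}
    )


def snp_span_lengths(sites: pd.DataFrame) -> dict[str, int]:
    """Per-chromosome first-to-last SNP span (inclusive bp) from a site table."""
    spans = {}
    for chrom, grp in sites.groupby("chrom", sort=False):
        spans[str(chrom)] = int(grp["pos"].max() - grp["pos"].min() + 1)
    return spans
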