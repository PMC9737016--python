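"""Positional gene annotation of ROH islands.

Gene intervals come from BED4+ (0-based half-open, converted to 1-based
inclusive) or GFF3 (``gene``-type records, already 1-based inclusive).  An
island is annotated with every gene it overlaps by at least one base pair;
no promoter or flank extension is applied.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from urllib.parse import unquote

import numpy as np
import pandas as pd

from .islands import Island

__all__ = ["GeneInterval", "IslandAnnotation", "load_gene_intervals", "overlap_genes",
           "annotation_to_frame"]


@dataclass(frozen=True)
class GeneInterval:
    """One gene span, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str
    name: str = ""
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class IslandAnnotation:
    island: Island
    genes: tuple[GeneInterval, ...]


def _open_text(path):
    return gzip.open(str(path), "rt") if str(path).endswith(".gz") else open(str(path))


def _parse_gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = unquote(value.strip())
    return out


def load_gene_intervals(path, fmt: str | None = None) -> list[GeneInterval]:
    """Load gene intervals from BED4+ or GFF3 (gzip allowed).

    ``fmt`` is inferred from the suffix when omitted ("bed" or one of
    "gff"/"gff3").  GFF3 parsing keeps only ``gene``-type records; a file
    yielding none produces an empty list with a warning.  Malformed lines
    raise ``ValueError`` naming the line number.
    """
    if fmt is None:
        stem = str(path).removesuffix(".gz")
        fmt = "bed" if stem.endswith(".bed") else "gff"
    fmt = fmt.lower()
    if fmt not in ("bed", "gff", "gff3"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes: list[GeneInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track "):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED4 requires at least 4 columns")
                    chrom, start0, end0, name = fields[:4]
                    biotype = fields[6] if len(fields) > 6 else ""
                    genes.append(
                        GeneInterval(
                            chrom=chrom,
                            start=int(start0) + 1,  # 0-based half-open -> 1-based inclusive
                            end=int(end0),
                            gene_id=name,
                            name=name,
                            biotype=biotype,
                        )
                    )
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 requires 9 columns")
                    chrom, _source, ftype, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
                    if ftype != "gene":
                        continue
                    attrs = _parse_gff_attributes(fields[8])
                    genes.append(
                        GeneInterval(
                            chrom=chrom,
                            start=int(start),
                            end=int(end),
                            gene_id=attrs.get("ID", attrs.get("gene_id", "")),
                            name=attrs.get("Name", attrs.get("gene_name", "")),
                            biotype=attrs.get("biotype", attrs.get("gene_biotype", "")),
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: malformed line {lineno}: {exc}") from exc
    if not genes:
        warnings.warn(f"{path}: no gene records found")
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def overlap_genes(islands: list[Island], genes: list[GeneInterval]) -> list[IslandAnnotation]:
    """Per-island list of genes overlapping it by >= 1 bp (inclusive coordinates)."""
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    starts_ends = {
        chrom: (
            np.array([g.start for g in gs], dtype=np.int64),
            np.array([g.end for g in gs], dtype=np.int64),
        )
        for chrom, gs in by_chrom.items()
    }
    out = []
    for isl in islands:
        gs = by_chrom.get(isl.chrom, [])
        if gs:
            starts, ends = starts_ends[isl.chrom]
            hit = (starts <= isl.end_pos) & (ends >= isl.start_pos)
            overlapping = tuple(g for g, h in zip(gs, hit) if h)
        else:
            overlapping = ()
        out.append(IslandAnnotation(island=isl, genes=overlapping))
    return out


def annotation_to_frame(annotations: list[IslandAnnotation]) -> pd.DataFrame:
    """Annotated islands as a table with comma-separated gene symbols."""
    rows = []
    for a in annotations:
        symbols = ", ".join((g.name or g.gene_id) for g in a.genes) or "None"
        rows.append(
            (
                a.island.chrom,
                a.island.start_pos,
                a.island.end_pos,
                a.island.length_kb,
                a.island.n_snp,
                symbols,
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "length_kb", "n_snp", "genes"]
    )
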