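"""Domain types, interval arithmetic and readers/writers for the formats
every pipeline stage touches.

Coordinates are 0-based half-open internally, matching BED.  Tab-separated
tables that come from 1-based inclusive sources can be converted on read
with ``one_based=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_CNA_STATES = ("gain", "loss", "CNLOH", "neutral")
VALID_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "PolII", "input", "mRNA")


class GenomeIOError(ValueError):
    """Raised for malformed or inconsistent genomic input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise GenomeIOError("chrom must be non-empty")
        if self.start < 0:
            raise GenomeIOError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise GenomeIOError(f"empty interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


def distance_to(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals.

    Overlapping or touching intervals have distance 0; intervals on
    different chromosomes are infinitely far apart so that proximity
    predicates are simply ``distance <= threshold``.
    """
    if a.chrom != b.chrom:
        return math.inf
    if a.start < b.end and b.start < a.end:
        return 0
    return max(b.start - a.end, a.start - b.end, 0)


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene: TSS anchor for profiles, exon length for RPKM.

    ``thick_start``/``thick_end`` delimit the coding region (BED12
    thickStart/thickEnd); exonic sequence outside it is UTR.
    """

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    thick_start: int | None = None
    thick_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.exons:
            raise GenomeIOError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise GenomeIOError(f"exon off-chromosome in {self.gene_id}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise GenomeIOError(f"exon outside gene body in {self.gene_id}")
            if prev_end is not None and ex.start < prev_end:
                raise GenomeIOError(f"overlapping/unsorted exons in {self.gene_id}")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """Transcription start site (last base of the interval on '-')."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def exon_length_bp(self) -> int:
        return sum(len(ex) for ex in self.exons)


@dataclass
class TagSet:
    """Aligned single-end tags (5' positions) for one mark/sample."""

    mark: str
    sample: str
    tags: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise GenomeIOError(f"unknown mark {self.mark!r}")
        for chrom, pos, strand in self.tags:
            if pos < 0:
                raise GenomeIOError(f"negative tag position {pos} on {chrom}")

    @property
    def library_size(self) -> int:
        return len(self.tags)

    def positions(self, chrom: str) -> list[int]:
        return [p for c, p, _ in self.tags if c == chrom]


@dataclass(frozen=True)
class CnaSegment:
    """A copy-number segment call."""

    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in VALID_CNA_STATES:
            raise GenomeIOError(f"unknown CNA state {self.state!r}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a BED12 file.

    Returns one :class:`GeneModel` per record, sorted by (chrom, start).
    TSS is derived from the strand.  Malformed lines raise
    :class:`GenomeIOError` naming the line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GenomeIOError(f"line {lineno}: expected BED12, got {len(fields)} columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start, thick_end = int(fields[6]), int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise GenomeIOError(f"line {lineno}: {exc}") from exc
            if block_count == 0 or len(sizes) != block_count or len(starts) != block_count:
                raise GenomeIOError(f"line {lineno}: inconsistent exon blocks")
            exons = tuple(
                GenomicInterval(chrom, start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    interval=GenomicInterval(chrom, start, end),
                    strand=strand,
                    exons=exons,
                    thick_start=thick_start,
                    thick_end=thick_end,
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 with lexicographic chrom sort."""
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.gene_id)):
        sizes = ",".join(str(len(ex)) for ex in g.exons)
        starts = ",".join(str(ex.start - g.interval.start) for ex in g.exons)
        thick_s = g.thick_start if g.thick_start is not None else g.interval.start
        thick_e = g.thick_end if g.thick_end is not None else g.interval.end
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    g.chrom, g.interval.start, g.interval.end, g.gene_id, 0,
                    g.strand, thick_s, thick_e, "0,0,0", len(g.exons), sizes, starts,
                )
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_tags(path: str | Path, mark: str, sample: str) -> TagSet:
    """Read aligned tags from a BED file as 5' positions.

    The 5' end is the interval start on '+' and ``end - 1`` on '-'.
    A missing strand column defaults to '+'.
    """
    tags: list[tuple[str, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(f"line {lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0:
                raise GenomeIOError(f"line {lineno}: negative coordinate")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            pos = start if strand == "+" else end - 1
            tags.append((chrom, pos, strand))
    return TagSet(mark=mark, sample=sample, tags=tags)


def write_tags(tagset: TagSet, path: str | Path, tag_length: int = 35) -> None:
    """Write tags as BED6 intervals of ``tag_length`` anchored at the 5' end."""
    lines = []
    for chrom, pos, strand in sorted(tagset.tags):
        if strand == "+":
            start, end = pos, pos + tag_length
        else:
            start, end = max(0, pos - tag_length + 1), pos + 1
        lines.append(f"{chrom}\t{start}\t{end}\t.\t0\t{strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_cna_segments(path: str | Path, one_based: bool = False) -> list[CnaSegment]:
    """Read copy-number segments from a TSV with columns chrom/start/end/state."""
    df = pd.read_csv(path, sep="\t")
    offset = 1 if one_based else 0
    segs = [
        CnaSegment(
            GenomicInterval(str(r.chrom), int(r.start) - offset, int(r.end) - offset + (1 if one_based else 0)),
            str(r.state),
        )
        for r in df.itertuples()
    ]
    segs.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return segs


def write_cna_segments(segments: Iterable[CnaSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"chrom": s.interval.chrom, "start": s.interval.start,
             "end": s.interval.end, "state": s.state}
            for s in segments
        ]
    ).sort_values(["chrom", "start"], kind="stable")
    df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-level count table (gene_id + one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise GenomeIOError("count table must have a gene_id column")
    return df.set_index("gene_id")


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Cq table with columns sample, group, assay, replicate, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "assay", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeIOError(f"Cq table missing columns: {sorted(missing)}")
    return df


def chrom_lengths_from_genes(genes: Sequence[GeneModel], pad: int = 10_000) -> dict[str, int]:
    """Infer minimal chromosome lengths covering all genes plus padding."""
    out: dict[str, int] = {}
    for g in genes:
        out[g.chrom] = max(out.get(g.chrom, 0), g.interval.end + pad)
    return out
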