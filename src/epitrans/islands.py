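"""Window/gap ChIP island calling, differential-island comparison, and
genomic annotation of islands.

The caller partitions each chromosome into fixed windows, marks windows
whose tag count clears a Poisson background threshold as eligible, merges
eligible windows across bounded gaps into islands, and scores each island
with an upper-tail Poisson test against the input-scaled expectation.
Broad marks (H3K27me3) use a larger gap so scattered domains consolidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_fdr
from .genome_io import GeneModel, GenomicInterval, TagSet, distance_to

logger = logging.getLogger(__name__)

DEFAULT_GAP_BP = {"H3K4me1": 200, "H3K4me3": 200, "PolII": 200, "H3K27me3": 600}

ANNOTATION_PRECEDENCE = (
    "promoter", "5'UTR", "3'UTR", "coding exon", "intron",
    "downstream", "distal intergenic",
)


@dataclass
class IslandParams:
    """Parameters of the window/gap island caller."""

    window_bp: int = 200
    gap_bp: int = 200  # 600 for broad marks such as H3K27me3
    effective_genome_fraction: float = 0.81
    eligibility_tail: float = 0.20  # Poisson upper-tail mass for window eligibility
    island_fdr: float = 0.001
    diff_fold: float = 3.0
    diff_fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.gap_bp % self.window_bp != 0:
            raise ValueError("gap_bp must be a multiple of window_bp")
        if not (0 < self.effective_genome_fraction <= 1):
            raise ValueError("effective_genome_fraction must be in (0, 1]")

    @classmethod
    def for_mark(cls, mark: str, **kwargs) -> "IslandParams":
        kwargs.setdefault("gap_bp", DEFAULT_GAP_BP.get(mark, 200))
        return cls(**kwargs)


@dataclass
class Island:
    interval: GenomicInterval
    chip_count: int
    input_count: int
    normalized_enrichment: float
    p_value: float
    fdr: float = np.nan


@dataclass
class DifferentialIsland:
    interval: GenomicInterval
    count_a: int
    count_b: int
    readcount_a: float  # tags per million in sample a
    readcount_b: float
    fold_change: float  # normalized a / b
    p_value: float
    fdr: float = np.nan
    direction: str = ""  # increased / decreased (sample a vs b)


@dataclass
class RegionAnnotation:
    category: str
    gene_id: str | None = None


def _window_counts(positions: np.ndarray, n_windows: int, window_bp: int) -> np.ndarray:
    idx = positions // window_bp
    idx = idx[(idx >= 0) & (idx < n_windows)]
    return np.bincount(idx, minlength=n_windows)


def _poisson_upper_threshold(lam: float, tail: float) -> int:
    """Smallest k with P(X >= k) < tail for X ~ Poisson(lam)."""
    k = int(stats.poisson.ppf(1 - tail, lam))
    while stats.poisson.sf(k - 1, lam) >= tail:
        k += 1
    return k


def _eligible_runs(eligible: np.ndarray, max_gap_windows: int) -> list[tuple[int, int]]:
    """Merge eligible windows separated by <= max_gap_windows ineligible ones.

    Returns (first_window, last_window) index pairs, inclusive.
    """
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap_windows:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def call_islands(
    chip: TagSet,
    input_tags: TagSet | None,
    params: IslandParams,
    chrom_lengths: dict[str, int],
) -> list[Island]:
    """Call enriched islands for one ChIP library against matched input.

    Window eligibility uses the genome-wide background rate
    ``chip_library * window_bp / (genome_size * effective_genome_fraction)``;
    eligible windows within ``gap_bp`` merge into islands; each island is
    scored by the Poisson upper tail of its total chip count given the
    input-scaled expectation (floored at background), and BH-filtered at
    ``island_fdr``.  With no input, scoring falls back to background only.
    """
    genome_bp = sum(chrom_lengths.values())
    if chip.library_size == 0:
        return []
    lam_bg = chip.library_size * params.window_bp / (genome_bp * params.effective_genome_fraction)
    k_min = _poisson_upper_threshold(lam_bg, params.eligibility_tail)

    input_lib = input_tags.library_size if input_tags is not None else 0
    if input_lib == 0:
        if input_tags is not None:
            logger.warning("empty input library; scoring islands against background only")
        scale = 0.0
    else:
        scale = chip.library_size / input_lib

    candidates: list[tuple[GenomicInterval, int, int]] = []
    for chrom, length in sorted(chrom_lengths.items()):
        n_win = -(-length // params.window_bp)
        chip_pos = np.asarray(chip.positions(chrom), dtype=np.int64)
        chip_counts = _window_counts(chip_pos, n_win, params.window_bp)
        if input_lib:
            in_pos = np.asarray(input_tags.positions(chrom), dtype=np.int64)
            in_counts = _window_counts(in_pos, n_win, params.window_bp)
        else:
            in_counts = np.zeros(n_win, dtype=np.int64)
        eligible = chip_counts >= k_min
        for w0, w1 in _eligible_runs(eligible, params.gap_bp // params.window_bp):
            iv = GenomicInterval(chrom, w0 * params.window_bp,
                                 min((w1 + 1) * params.window_bp, n_win * params.window_bp))
            c = int(chip_counts[w0:w1 + 1].sum())
            i = int(in_counts[w0:w1 + 1].sum())
            candidates.append((iv, c, i))

    if not candidates:
        return []
    islands = []
    for iv, c, i in candidates:
        n_windows = -(-len(iv) // params.window_bp)
        expectation = max(i * scale, lam_bg * n_windows)
        p = float(stats.poisson.sf(c - 1, expectation))
        enrich = c / expectation if expectation > 0 else np.inf
        islands.append(Island(iv, c, i, enrich, p))
    fdrs = bh_fdr([isl.p_value for isl in islands])
    out = []
    for isl, q in zip(islands, fdrs):
        isl.fdr = float(q)
        if q <= params.island_fdr:
            out.append(isl)
    return out


def differential_islands(
    tags_a: TagSet,
    tags_b: TagSet,
    params: IslandParams,
    chrom_lengths: dict[str, int],
    input_a: TagSet | None = None,
    input_b: TagSet | None = None,
) -> list[DifferentialIsland]:
    """Regions differentially enriched between two samples of one mark.

    Candidate regions are islands called on the pooled signal (so both
    directions share one region set); per region, library-normalized
    densities are compared with a two-sided exact binomial test of
    ``count_a`` against the library-size proportion.  Regions pass if the
    normalized fold change is >= ``diff_fold`` in either direction at
    BH FDR < ``diff_fdr``.
    """
    lib_a, lib_b = tags_a.library_size, tags_b.library_size
    if lib_a == 0 or lib_b == 0:
        raise ValueError("both samples need nonzero libraries")
    pooled = TagSet(mark=tags_a.mark, sample="pooled", tags=tags_a.tags + tags_b.tags)
    if input_a is not None and input_b is not None:
        pooled_input = TagSet(mark="input", sample="pooled",
                              tags=input_a.tags + input_b.tags)
    else:
        pooled_input = None
    regions = call_islands(pooled, pooled_input, params, chrom_lengths)

    pos_a = {c: np.sort(np.asarray(tags_a.positions(c), dtype=np.int64))
             for c in chrom_lengths}
    pos_b = {c: np.sort(np.asarray(tags_b.positions(c), dtype=np.int64))
             for c in chrom_lengths}

    def _count(pos: dict[str, np.ndarray], iv: GenomicInterval) -> int:
        arr = pos.get(iv.chrom)
        if arr is None or arr.size == 0:
            return 0
        return int(np.searchsorted(arr, iv.end, "left") - np.searchsorted(arr, iv.start, "left"))

    prelim: list[DifferentialIsland] = []
    p0 = lib_a / (lib_a + lib_b)
    for region in regions:
        iv = region.interval
        ca = _count(pos_a, iv)
        cb = _count(pos_b, iv)
        if ca == 0 and cb == 0:
            continue
        rc_a = ca / lib_a * 1e6
        rc_b = cb / lib_b * 1e6
        fc = ((ca if ca else 0.5) / lib_a) / ((cb if cb else 0.5) / lib_b)
        p = float(stats.binomtest(ca, ca + cb, p0, alternative="two-sided").pvalue)
        prelim.append(DifferentialIsland(iv, ca, cb, rc_a, rc_b, fc, p))

    if not prelim:
        return []
    fdrs = bh_fdr([d.p_value for d in prelim])
    out = []
    for d, q in zip(prelim, fdrs):
        d.fdr = float(q)
        d.direction = "increased" if d.fold_change > 1 else "decreased"
        if max(d.fold_change, 1 / d.fold_change) >= params.diff_fold and q < params.diff_fdr:
            out.append(d)
    return out


def summarize_differential(
    islands_by_mark: dict[str, list[DifferentialIsland]]
) -> pd.DataFrame:
    """Per-mark counts and percentages of increased vs decreased islands.

    Percentages are reported to one decimal; a mark with no islands gets NA.
    """
    rows = []
    for mark, islands in islands_by_mark.items():
        n_inc = sum(1 for d in islands if d.direction == "increased")
        n_dec = sum(1 for d in islands if d.direction == "decreased")
        total = n_inc + n_dec
        rows.append({
            "mark": mark,
            "n_increased": n_inc,
            "n_decreased": n_dec,
            "pct_increased": round(100.0 * n_inc / total, 1) if total else np.nan,
            "pct_decreased": round(100.0 * n_dec / total, 1) if total else np.nan,
        })
    return pd.DataFrame(rows)


def summarize_counts(n_increased: int, n_decreased: int) -> tuple[float, float]:
    """Percentage split of a differential-island tally, to one decimal."""
    total = n_increased + n_decreased
    if total == 0:
        return (np.nan, np.nan)
    return (round(100.0 * n_increased / total, 1),
            round(100.0 * n_decreased / total, 1))


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _categorize_midpoint(
    chrom: str, pos: int, gene: GeneModel, promoter_bp: int, downstream_bp: int
) -> str | None:
    """Category of a point relative to one gene, or None if unrelated."""
    if gene.chrom != chrom:
        return None
    iv = gene.interval
    if gene.strand == "+":
        prom = (iv.start - promoter_bp, iv.start)
        down = (iv.end, iv.end + downstream_bp)
    else:
        prom = (iv.end, iv.end + promoter_bp)
        down = (iv.start - downstream_bp, iv.start)
    if prom[0] <= pos < prom[1]:
        return "promoter"
    if iv.start <= pos < iv.end:
        in_exon = any(ex.start <= pos < ex.end for ex in gene.exons)
        if not in_exon:
            return "intron"
        ts = gene.thick_start if gene.thick_start is not None else iv.start
        te = gene.thick_end if gene.thick_end is not None else iv.end
        if ts <= pos < te:
            return "coding exon"
        before_cds = pos < ts
        if (before_cds and gene.strand == "+") or (not before_cds and gene.strand == "-"):
            return "5'UTR"
        return "3'UTR"
    if down[0] <= pos < down[1]:
        return "downstream"
    return None


def annotate_islands(
    islands: list[Island] | list[DifferentialIsland],
    genes: list[GeneModel],
    promoter_bp: int = 3000,
    downstream_bp: int = 3000,
) -> list[RegionAnnotation]:
    """Assign one genomic category per island by its midpoint.

    Precedence when several genes apply:
    promoter > 5'UTR > 3'UTR > coding exon > intron > downstream >
    distal intergenic.
    """
    rank = {c: i for i, c in enumerate(ANNOTATION_PRECEDENCE)}
    out = []
    for island in islands:
        iv = island.interval
        mid = iv.midpoint
        best: tuple[int, str | None] = (rank["distal intergenic"], None)
        for gene in genes:
            if gene.chrom != iv.chrom:
                continue
            if distance_to(gene.interval, iv) > max(promoter_bp, downstream_bp) + len(iv):
                continue
            cat = _categorize_midpoint(iv.chrom, mid, gene, promoter_bp, downstream_bp)
            if cat is not None and rank[cat] < best[0]:
                best = (rank[cat], gene.gene_id)
        out.append(RegionAnnotation(ANNOTATION_PRECEDENCE[best[0]], best[1]))
    return out
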