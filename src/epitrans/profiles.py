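"""Expression-quartile TSS metagene profiles of ChIP tag density.

Genes are split into four expression quartiles (high, medium, low,
very low) by RPKM; for each quartile the mean tag density is computed in
25-bp bins over +/- 5 kb around the TSS, with offsets oriented so that
upstream is always negative, and per-gene-per-bin counts capped at a
Poisson upper-tail threshold to remove tower artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel, TagSet

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("high", "medium", "low", "very low")


@dataclass
class MetageneProfile:
    mark: str
    sample: str
    quartile: str
    bin_offsets: np.ndarray  # left edges, TSS-relative, strand-oriented
    density: np.ndarray      # mean trimmed tag count per gene per bin
    n_genes: int = 0

    def peak_offset(self) -> int:
        """Left edge of the highest-density bin."""
        return int(self.bin_offsets[int(np.argmax(self.density))])


def assign_quartiles(rpkm: dict[str, float] | pd.Series) -> dict[str, str]:
    """Quartile label per gene by descending RPKM, groups equal within 1.

    Ties are broken by gene_id order so membership is deterministic.
    """
    series = pd.Series(rpkm)
    if len(series) < 4:
        raise ValueError("need at least 4 genes to form quartiles")
    ordered = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    n = len(ordered)
    out: dict[str, str] = {}
    # distribute n into 4 groups differing by at most 1, largest first
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    pos = 0
    for label, size in zip(QUARTILE_LABELS, sizes):
        for gene_id, _ in ordered[pos:pos + size]:
            out[gene_id] = label
        pos += size
    return out


def poisson_trim(bin_counts: np.ndarray, alpha: float = 1e-5, lam: float | None = None) -> np.ndarray:
    """Cap bin counts at the Poisson upper-tail threshold.

    lam defaults to the mean of the supplied counts; the cap is the
    smallest k with ``P(X >= k) < alpha`` for X ~ Poisson(lam), and any
    count above it is set to the cap.
    """
    counts = np.asarray(bin_counts, dtype=float)
    if lam is None:
        lam = float(counts.mean()) if counts.size else 0.0
    if lam <= 0:
        return counts.copy()
    cap = int(stats.poisson.ppf(1 - alpha, lam))
    while stats.poisson.sf(cap - 1, lam) >= alpha:
        cap += 1
    return np.minimum(counts, cap)


def gene_bin_matrix(
    tags: TagSet,
    genes: list[GeneModel],
    flank_bp: int = 5000,
    bin_bp: int = 25,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[np.ndarray, list[GeneModel]]:
    """Per-gene, per-bin tag counts over [TSS - flank, TSS + flank).

    Offsets are strand-oriented: for '-' genes the genomic axis is
    mirrored so upstream tags land in negative-offset bins.  Genes whose
    flank extends past a known chromosome edge are skipped.  Returns the
    (n_genes, n_bins) count matrix and the genes actually used.
    """
    n_bins = 2 * flank_bp // bin_bp
    pos_by_chrom = {
        c: np.sort(np.asarray(tags.positions(c), dtype=np.int64))
        for c in {g.chrom for g in genes}
    }
    rows, used = [], []
    for gene in genes:
        tss = gene.tss
        if tss - flank_bp < 0:
            logger.debug("gene %s too close to chromosome start; skipped", gene.gene_id)
            continue
        if chrom_lengths is not None and tss + flank_bp > chrom_lengths.get(gene.chrom, np.inf):
            logger.debug("gene %s too close to chromosome end; skipped", gene.gene_id)
            continue
        arr = pos_by_chrom[gene.chrom]
        lo = np.searchsorted(arr, tss - flank_bp, "left")
        hi = np.searchsorted(arr, tss + flank_bp, "left")
        window = arr[lo:hi]
        offsets = window - tss if gene.strand == "+" else tss - window
        offsets = offsets[(offsets >= -flank_bp) & (offsets < flank_bp)]
        idx = (offsets + flank_bp) // bin_bp
        rows.append(np.bincount(idx, minlength=n_bins))
        used.append(gene)
    if not rows:
        return np.zeros((0, n_bins)), []
    return np.vstack(rows), used


def tss_profile(
    tags: TagSet,
    genes: list[GeneModel],
    quartile: str = "",
    flank_bp: int = 5000,
    bin_bp: int = 25,
    trim_alpha: float = 1e-5,
    trim_lambda: float | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> MetageneProfile:
    """Mean trimmed tag density around the TSS for one gene group.

    ``trim_lambda`` should be the global mean per-gene-per-bin count for
    this (mark, sample) so all quartiles share one trimming cap; when
    None it is estimated from this group's matrix.
    """
    matrix, used = gene_bin_matrix(tags, genes, flank_bp, bin_bp, chrom_lengths)
    n_bins = 2 * flank_bp // bin_bp
    offsets = np.arange(-flank_bp, flank_bp, bin_bp)
    if matrix.shape[0] == 0:
        return MetageneProfile(tags.mark, tags.sample, quartile, offsets,
                               np.zeros(n_bins), 0)
    lam = trim_lambda if trim_lambda is not None else float(matrix.mean())
    trimmed = poisson_trim(matrix.ravel(), alpha=trim_alpha, lam=lam).reshape(matrix.shape)
    density = trimmed.mean(axis=0)
    return MetageneProfile(tags.mark, tags.sample, quartile, offsets,
                           density, len(used))


def quartile_profiles(
    tags: TagSet,
    genes: list[GeneModel],
    quartile_of: dict[str, str],
    flank_bp: int = 5000,
    bin_bp: int = 25,
    trim_alpha: float = 1e-5,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, MetageneProfile]:
    """One metagene profile per expression quartile for a (mark, sample).

    The trimming rate is estimated once from all genes so quartiles are
    capped consistently.
    """
    full_matrix, _ = gene_bin_matrix(tags, genes, flank_bp, bin_bp, chrom_lengths)
    lam = float(full_matrix.mean()) if full_matrix.size else 0.0
    out = {}
    for label in QUARTILE_LABELS:
        subset = [g for g in genes if quartile_of.get(g.gene_id) == label]
        out[label] = tss_profile(
            tags, subset, label, flank_bp, bin_bp, trim_alpha,
            trim_lambda=lam if lam > 0 else None, chrom_lengths=chrom_lengths,
        )
    return out


def profiles_to_frame(profiles: dict[str, MetageneProfile]) -> pd.DataFrame:
    """Tabulate quartile profiles: one row per bin, one column per quartile."""
    any_profile = next(iter(profiles.values()))
    df = pd.DataFrame({"offset": any_profile.bin_offsets})
    for label, prof in profiles.items():
        df[label] = prof.density
    return df
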