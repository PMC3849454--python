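"""Copy-number-aware island-density bias testing.

Checks whether ChIP island density differs between copy-number states —
a control for read-mapping bias.  Adjacent same-state copy-number
segments closer than 1 Mb are merged, islands in lost regions are
excluded, per-chromosome islands-per-Mb densities are computed for the
gain / CNLOH / neutral footprints, and the distributions are compared
with a Mann-Whitney U test (exact enumeration at small sample sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genome_io import CnaSegment, GenomicInterval

MERGE_GAP_BP = 1_000_000  # strict: gaps of exactly 1 Mb stay unmerged


@dataclass
class DensityByState:
    state: str
    densities: list[float]  # one islands-per-Mb value per chromosome


def merge_cna(segments: Sequence[CnaSegment]) -> list[CnaSegment]:
    """Merge same-state neighbors separated by < 1 Mb, absorbing the gap.

    Input segments must be sorted and non-overlapping; different states
    never merge.  Idempotent.
    """
    by_chrom: dict[str, list[CnaSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    merged: list[CnaSegment] = []
    for chrom in sorted(by_chrom):
        segs = sorted(by_chrom[chrom], key=lambda s: s.interval.start)
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.interval.start < prev.interval.end:
                raise ValueError(f"overlapping CNA segments on {chrom}")
        current = segs[0]
        for seg in segs[1:]:
            gap = seg.interval.start - current.interval.end
            if seg.state == current.state and gap < MERGE_GAP_BP:
                current = CnaSegment(
                    GenomicInterval(chrom, current.interval.start, seg.interval.end),
                    current.state,
                )
            else:
                merged.append(current)
                current = seg
        merged.append(current)
    return merged


def exclude_lost(islands: list, segments: Sequence[CnaSegment]) -> tuple[list, int, float]:
    """Drop islands whose midpoint lies in a loss segment.

    Returns (retained islands, excluded count, excluded fraction of all
    input islands).
    """
    losses = [s.interval for s in segments if s.state == "loss"]
    retained, excluded = [], 0
    for island in islands:
        mid = island.interval.midpoint
        if any(iv.contains(island.interval.chrom, mid) for iv in losses):
            excluded += 1
        else:
            retained.append(island)
    frac = excluded / len(islands) if islands else 0.0
    return retained, excluded, frac


def state_footprints(
    segments: Sequence[CnaSegment], chrom_lengths: dict[str, int]
) -> dict[str, dict[str, list[GenomicInterval]]]:
    """Per-state, per-chromosome interval footprints.

    The neutral footprint is the complement of every called event (loss
    included, since lost regions are excluded upstream and must not count
    as neutral territory).
    """
    out: dict[str, dict[str, list[GenomicInterval]]] = {
        s: {} for s in ("gain", "loss", "CNLOH", "neutral")
    }
    for seg in segments:
        out[seg.state].setdefault(seg.interval.chrom, []).append(seg.interval)
    for chrom, length in chrom_lengths.items():
        events = sorted(
            (s.interval for s in segments if s.interval.chrom == chrom),
            key=lambda iv: iv.start,
        )
        pos, gaps = 0, []
        for iv in events:
            if iv.start > pos:
                gaps.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            gaps.append(GenomicInterval(chrom, pos, length))
        if gaps:
            out["neutral"][chrom] = gaps
    return out


def density_by_state(
    islands: list,
    segments: Sequence[CnaSegment],
    chrom_lengths: dict[str, int],
    states: Sequence[str] = ("gain", "CNLOH", "neutral"),
) -> dict[str, DensityByState]:
    """Islands-per-Mb per chromosome for each copy-number state.

    Islands are assigned to a state by midpoint.  Chromosomes with zero
    footprint for a state contribute no value for that state.
    """
    footprints = state_footprints(segments, chrom_lengths)
    mids: dict[str, list[int]] = {}
    for island in islands:
        mids.setdefault(island.interval.chrom, []).append(island.interval.midpoint)
    out = {}
    for state in states:
        values = []
        for chrom in sorted(chrom_lengths):
            ivs = footprints[state].get(chrom, [])
            footprint_bp = sum(len(iv) for iv in ivs)
            if footprint_bp == 0:
                continue
            n = sum(
                1
                for mid in mids.get(chrom, [])
                if any(iv.start <= mid < iv.end for iv in ivs)
            )
            values.append(n / (footprint_bp / 1e6))
        out[state] = DensityByState(state, values)
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_ranksum_pvalue(ranks_a: np.ndarray, all_ranks: np.ndarray) -> float:
    """Two-sided permutation p of the rank sum via subset-sum counting.

    Counts, over all C(n+m, n) label assignments, how many give a rank
    sum at or beyond the observed one in either tail.  Midranks are
    doubled so sums stay integral under ties.
    """
    n = ranks_a.size
    scaled = np.rint(all_ranks * 2).astype(int)
    obs = int(round(ranks_a.sum() * 2))
    total = scaled.sum()
    max_sum = total
    # dp[k][s] = number of size-k subsets with rank sum s
    dp = np.zeros((n + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in scaled:
        for k in range(n - 1, -1, -1):
            dp[k + 1, r:] += dp[k, : max_sum + 1 - r]
    dist = dp[n]
    n_total = dist.sum()
    lower = dist[: obs + 1].sum() / n_total
    upper = dist[obs:].sum() / n_total
    return float(min(1.0, 2.0 * min(lower, upper)))


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of sample a, p).

    Uses exact enumeration over all label assignments when
    ``min(n, m) <= 8`` and ``n + m <= 25``, else the normal approximation
    with tie correction.  All-tied input gives p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2)
    if np.ptp(pooled) == 0:
        return u_a, 1.0
    if min(a.size, b.size) <= 8 and a.size + b.size <= 25:
        p = _exact_ranksum_pvalue(ranks[: a.size], ranks)
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
    return u_a, min(1.0, p)


def bias_test(
    islands: list,
    segments: Sequence[CnaSegment],
    chrom_lengths: dict[str, int],
) -> dict[str, float]:
    """Gain-vs-neutral and CNLOH-vs-neutral density comparisons.

    Returns the two-sided Mann-Whitney p for each contrast (NaN when a
    state has no footprint on any chromosome).
    """
    dens = density_by_state(islands, segments, chrom_lengths)
    out = {}
    for state in ("gain", "CNLOH"):
        va, vn = dens[state].densities, dens["neutral"].densities
        if not va or not vn:
            out[f"{state}_vs_neutral_p"] = float("nan")
        else:
            out[f"{state}_vs_neutral_p"] = mann_whitney(va, vn)[1]
    return out
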