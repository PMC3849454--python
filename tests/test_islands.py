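import numpy as np
import pytest

from epitrans.genome_io import GenomicInterval, TagSet
from epitrans.islands import (
    DifferentialIsland,
    IslandParams,
    annotate_islands,
    call_islands,
    differential_islands,
    summarize_counts,
    summarize_differential,
)
from epitrans.synthetic import generate_genome


def uniform_tagset(n, chrom_len, seed, mark="PolII", sample="tumor", chrom="chr1"):
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, chrom_len, size=n)
    return TagSet(mark, sample, tags=[(chrom, int(p), "+") for p in pos])


def spiked_tagset(n_bg, chrom_len, region, n_spike, seed, **kw):
    ts = uniform_tagset(n_bg, chrom_len, seed, **kw)
    rng = np.random.default_rng(seed + 1)
    spike = rng.integers(region[0], region[1], size=n_spike)
    ts.tags.extend(("chr1", int(p), "+") for p in spike)
    return ts


class TestCallIslands:
    def test_merge_rule_across_single_gap(self):
        # two eligible windows [0,200) and [400,600) with gap 200 -> one island
        tags = [("chr1", p, "+") for p in list(range(0, 200, 4)) + list(range(400, 600, 4))]
        chip = TagSet("PolII", "tumor", tags=tags)
        inp = uniform_tagset(100, 100_000, seed=0, mark="input")
        params = IslandParams(gap_bp=200)
        islands = call_islands(chip, inp, params, {"chr1": 100_000})
        assert len(islands) == 1
        assert (islands[0].interval.start, islands[0].interval.end) == (0, 600)

    def test_gap_larger_than_limit_splits_islands(self):
        tags = [("chr1", p, "+") for p in list(range(0, 200, 4)) + list(range(800, 1000, 4))]
        chip = TagSet("PolII", "tumor", tags=tags)
        inp = uniform_tagset(100, 100_000, seed=0, mark="input")
        narrow = call_islands(chip, inp, IslandParams(gap_bp=200), {"chr1": 100_000})
        broad = call_islands(chip, inp, IslandParams(gap_bp=600), {"chr1": 100_000})
        assert len(narrow) == 2
        assert len(broad) == 1

    def test_planted_region_recovered(self):
        region = (500_000, 502_000)
        chip = spiked_tagset(20_000, 1_000_000, region, 360, seed=5)
        inp = uniform_tagset(20_000, 1_000_000, seed=99, mark="input")
        islands = call_islands(chip, inp, IslandParams(), {"chr1": 1_000_000})
        assert len(islands) == 1
        isl = islands[0]
        overlap = min(isl.interval.end, region[1]) - max(isl.interval.start, region[0])
        assert overlap / (region[1] - region[0]) >= 0.8

    def test_islands_tile_windows_and_never_overlap(self):
        chip = spiked_tagset(20_000, 1_000_000, (100_000, 102_000), 400, seed=2)
        chip.tags.extend(("chr1", int(p), "+") for p in range(700_000, 702_000, 5))
        inp = uniform_tagset(20_000, 1_000_000, seed=3, mark="input")
        islands = call_islands(chip, inp, IslandParams(), {"chr1": 1_000_000})
        assert len(islands) >= 2
        ordered = sorted(islands, key=lambda i: i.interval.start)
        for isl in ordered:
            assert isl.interval.start % 200 == 0
            assert len(isl.interval) % 200 == 0
        for a, b in zip(ordered, ordered[1:]):
            assert a.interval.end <= b.interval.start

    def test_empty_chip_library(self):
        chip = TagSet("PolII", "tumor", tags=[])
        assert call_islands(chip, None, IslandParams(), {"chr1": 100_000}) == []

    def test_gap_must_be_window_multiple(self):
        with pytest.raises(ValueError):
            IslandParams(window_bp=200, gap_bp=300)


class TestDifferentialIslands:
    def _planted_pair(self, seed):
        region = (300_000, 302_000)
        a = spiked_tagset(20_000, 1_000_000, region, 500, seed=seed, sample="tumor")
        b = spiked_tagset(20_000, 1_000_000, region, 100, seed=seed + 50, sample="normal")
        return a, b, region

    def test_planted_asymmetric_region_recovered(self):
        a, b, region = self._planted_pair(seed=4)
        out = differential_islands(a, b, IslandParams(), {"chr1": 1_000_000})
        hits = [
            d for d in out
            if d.interval.overlaps(GenomicInterval("chr1", *region))
        ]
        assert len(hits) == 1
        d = hits[0]
        assert d.direction == "increased"
        assert 3.5 <= d.fold_change <= 7.0

    def test_antisymmetry_under_sample_swap(self):
        a, b, _ = self._planted_pair(seed=8)
        fwd = differential_islands(a, b, IslandParams(), {"chr1": 1_000_000})
        rev = differential_islands(b, a, IslandParams(), {"chr1": 1_000_000})
        assert len(fwd) == len(rev) >= 1
        for df, dr in zip(fwd, rev):
            assert df.interval == dr.interval
            assert df.fold_change == pytest.approx(1.0 / dr.fold_change)
            assert {df.direction, dr.direction} == {"increased", "decreased"}
            assert df.p_value == pytest.approx(dr.p_value, rel=1e-9)

    def test_symmetric_signal_not_emitted(self):
        region = (300_000, 302_000)
        a = spiked_tagset(20_000, 1_000_000, region, 400, seed=21, sample="tumor")
        b = spiked_tagset(20_000, 1_000_000, region, 400, seed=22, sample="normal")
        out = differential_islands(a, b, IslandParams(), {"chr1": 1_000_000})
        assert not any(
            d.interval.overlaps(GenomicInterval("chr1", *region)) for d in out
        )


class TestSummaries:
    def test_single_direction(self):
        assert summarize_counts(1, 0) == (100.0, 0.0)

    def test_zero_islands_reported_na(self):
        df = summarize_differential({"PolII": []})
        assert np.isnan(df["pct_increased"].iloc[0])

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            inc, dec = int(rng.integers(1, 10_000)), int(rng.integers(1, 10_000))
            pi, pd_ = summarize_counts(inc, dec)
            assert pi + pd_ == pytest.approx(100.0, abs=0.1)


@pytest.fixture(scope="module")
def genes():
    return generate_genome(1, 3_000_000, 60, seed=13)


class TestAnnotation:
    @staticmethod
    def _island(chrom, start, end):
        return DifferentialIsland(
            GenomicInterval(chrom, start, end), 1, 1, 1.0, 1.0, 1.0, 1.0
        )

    def test_upstream_of_plus_tss_is_promoter(self, genes):
        gene = next(g for g in genes if g.strand == "+")
        isl = self._island(gene.chrom, gene.tss - 1100, gene.tss - 900)
        (anno,) = annotate_islands([isl], genes)
        assert anno.category == "promoter"
        assert anno.gene_id == gene.gene_id

    def test_intronic_island_far_from_tss(self, genes):
        for gene in genes:
            if gene.strand != "+" or len(gene.exons) < 2:
                continue
            ex0, ex1 = gene.exons[0], gene.exons[1]
            if ex1.start - ex0.end >= 400 and ex0.end - gene.tss > 3_500:
                mid = (ex0.end + ex1.start) // 2
                isl = self._island(gene.chrom, mid - 100, mid + 100)
                (anno,) = annotate_islands([isl], genes)
                assert anno.category == "intron"
                return
        pytest.skip("no suitable wide intron at this seed")

    def test_matches_brute_force_scan(self, genes):
        rng = np.random.default_rng(31)
        islands = [
            self._island("chr1", int(s), int(s) + 400)
            for s in rng.integers(0, 2_900_000, size=200)
        ]
        annos = annotate_islands(islands, genes, promoter_bp=3000, downstream_bp=3000)

        def brute(midpoint):
            cats = set()
            for g in genes:
                iv = g.interval
                prom = (iv.start - 3000, iv.start) if g.strand == "+" else (iv.end, iv.end + 3000)
                down = (iv.end, iv.end + 3000) if g.strand == "+" else (iv.start - 3000, iv.start)
                if prom[0] <= midpoint < prom[1]:
                    cats.add("promoter")
                elif iv.start <= midpoint < iv.end:
                    in_ex = any(e.start <= midpoint < e.end for e in g.exons)
                    if not in_ex:
                        cats.add("intron")
                    elif g.thick_start <= midpoint < g.thick_end:
                        cats.add("coding exon")
                    elif (midpoint < g.thick_start) == (g.strand == "+"):
                        cats.add("5'UTR")
                    else:
                        cats.add("3'UTR")
                elif down[0] <= midpoint < down[1]:
                    cats.add("downstream")
            order = ["promoter", "5'UTR", "3'UTR", "coding exon", "intron",
                     "downstream", "distal intergenic"]
            for c in order:
                if c in cats:
                    return c
            return "distal intergenic"

        for isl, anno in zip(islands, annos):
            assert anno.category == brute(isl.interval.midpoint)
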