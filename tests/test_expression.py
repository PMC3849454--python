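import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from epitrans.expression import (
    ExpressionRecord,
    bh_fdr,
    call_de,
    chi_square_2x2,
    compute_rpkm,
    filter_expressed,
    fisher_de,
    fold_change,
    length_bias_enrichment,
    mirna_de,
    tmm_factor,
    wallenius_enrichment_p,
)


def fisher_oracle(ca, ra, cb, rb):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = ca + ra + cb + rb
    row1 = ca + ra
    col1 = ca + cb
    probs = []
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        probs.append((x, stats.hypergeom.pmf(x, n, col1, row1)))
    p_obs = dict(probs)[ca]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-9))


class TestRpkm:
    def test_unit_case(self):
        assert compute_rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_zero_count(self):
        assert compute_rpkm(0, 500, 10_000) == 0.0

    def test_random_table_matches_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = int(rng.integers(0, 5000))
            length = int(rng.integers(100, 50_000))
            lib = int(rng.integers(10_000, 10_000_000))
            assert compute_rpkm(c, length, lib) == pytest.approx(c * 1e9 / (length * lib))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compute_rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            compute_rpkm(1, 100, 0)


class TestFilter:
    def test_at_least_one_sample_above_threshold_retained(self):
        r = ExpressionRecord("g", 1, 1, rpkm_a=0.5, rpkm_b=2.0)
        assert filter_expressed([r]) == [r]

    def test_both_below_threshold_dropped(self):
        r = ExpressionRecord("g", 1, 1, rpkm_a=0.9, rpkm_b=0.9)
        assert filter_expressed([r]) == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(1)
        records = [
            ExpressionRecord(f"g{i}", 0, 0, rpkm_a=float(a), rpkm_b=float(b))
            for i, (a, b) in enumerate(rng.uniform(0, 3, size=(200, 2)))
        ]
        kept = filter_expressed(records)
        expected = sum(1 for r in records if r.rpkm_a > 1 or r.rpkm_b > 1)
        assert len(kept) == expected


class TestTmm:
    def test_identical_libraries_factor_one(self):
        counts = np.arange(1, 101)
        assert tmm_factor(counts, counts) == pytest.approx(1.0)

    def test_exact_doubling_factor_two(self):
        counts = np.arange(1, 101)
        assert tmm_factor(counts, 2 * counts) == pytest.approx(2.0)

    def test_matches_sort_and_average_oracle(self):
        rng = np.random.default_rng(7)
        ref = rng.integers(5, 2000, size=300).astype(float)
        test = (ref * rng.lognormal(0.3, 0.4, size=300)).round()
        # oracle: explicit sort, trim, weighted average
        keep = (ref > 0) & (test > 0)
        r, t = ref[keep], test[keep]
        m = np.log2(t / r)
        a = 0.5 * (np.log2(t) + np.log2(r))
        w = 1.0 / (1.0 / t - 1.0 / t.sum() + 1.0 / r - 1.0 / r.sum())
        km = int(np.floor(0.30 * m.size))
        ka = int(np.floor(0.05 * a.size))
        keep_m = np.isin(np.arange(m.size), np.argsort(m, kind="stable")[km:m.size - km])
        keep_a = np.isin(np.arange(a.size), np.argsort(a, kind="stable")[ka:a.size - ka])
        sel = keep_m & keep_a
        expected = 2.0 ** np.average(m[sel], weights=w[sel])
        assert tmm_factor(ref, test) == pytest.approx(expected)

    def test_fallback_warning_with_few_genes(self):
        with pytest.warns(UserWarning, match="fewer than 10"):
            tmm_factor(np.array([10.0, 20.0, 30.0]), np.array([10.0, 20.0, 30.0]))


class TestFisher:
    def test_balanced_table_p_one(self):
        assert fisher_de(5, 5, 100, 100) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        assert fisher_de(10, 5, 110, 105) == pytest.approx(
            fisher_oracle(10, 100, 5, 100), rel=1e-9
        )

    @pytest.mark.parametrize("ca, cb", [(30, 10), (20, 5), (50, 25), (10, 2)])
    def test_library_scaling_converges_to_binomial_limit(self, ca, cb):
        # with counts fixed and libraries growing, the 2x2 exact test
        # approaches the conditional binomial comparison of the two counts;
        # the gap to that limit shrinks monotonically across doublings
        limit = float(stats.binomtest(ca, ca + cb, 0.5).pvalue)
        gaps = [
            abs(fisher_de(ca, cb, 1000 * s, 1000 * s) - limit)
            for s in (1, 2, 4, 8)
        ]
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))
        assert gaps[-1] < 5e-4

    def test_count_exceeding_library_rejected(self):
        with pytest.raises(ValueError):
            fisher_de(200, 5, 100, 100)


class TestCallDe:
    def test_fold_gate_blocks_small_fold(self):
        r = ExpressionRecord("g", 10, 29, fold_change=2.9, p_value=0.001)
        (out,) = call_de([r])
        assert out.de_call == "none"

    def test_fdr_gate_blocks_large_p(self):
        r = ExpressionRecord("g", 10, 40, fold_change=4.0, p_value=0.06)
        (out,) = call_de([r])
        assert out.de_call == "none"

    def test_direction_follows_fold(self):
        recs = [
            ExpressionRecord("up", 10, 100, fold_change=10.0, p_value=1e-8),
            ExpressionRecord("dn", 100, 10, fold_change=0.1, p_value=1e-8),
        ]
        out = call_de(recs)
        assert [r.de_call for r in out] == ["up", "down"]

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_bh_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        adj = bh_fdr(p)
        # brute-force step-up on sorted p-values
        m = p.size
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        assert np.allclose(adj, expected)


class TestMirnaDe:
    def test_identical_proportions_no_call(self):
        r = ExpressionRecord("m", 50, 50, fold_change=1.0)
        (out,) = mirna_de([r], lib_a=10_000, lib_b=10_000)
        assert out.p_value == pytest.approx(1.0)
        assert out.de_call == "none"

    def test_chi_square_matches_hand_formula(self):
        ca, cb, la, lb = 40, 10, 1000, 1000
        table = np.array([[ca, la - ca], [cb, lb - cb]], dtype=float)
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected_cells = np.outer(row, col) / table.sum()
        chi2 = ((table - expected_cells) ** 2 / expected_cells).sum()
        assert chi_square_2x2(ca, cb, la, lb) == pytest.approx(
            float(stats.chi2.sf(chi2, df=1))
        )

    def test_bonferroni_is_m_times_p(self):
        recs = [
            ExpressionRecord(f"m{i}", 30 + 10 * i, 10, fold_change=3.5)
            for i in range(4)
        ]
        out = mirna_de(recs, lib_a=5000, lib_b=5000)
        for r in out:
            assert r.fdr == pytest.approx(min(1.0, 4 * r.p_value))


class TestFoldChange:
    def test_zero_count_uses_pseudocount(self):
        fc = fold_change(0, 1000, 10, 1000)
        assert fc == pytest.approx(10 / 0.5)


class TestEnrichment:
    def test_equal_weights_reduce_to_hypergeometric(self):
        p = wallenius_enrichment_p(5, 20, 6, 3, odds=1.0)
        assert p == pytest.approx(float(stats.hypergeom.sf(2, 20, 5, 6)))

    def test_category_of_every_gene_p_one(self):
        lengths = {f"g{i}": 1000 for i in range(10)}
        de = {f"g{i}": i < 3 for i in range(10)}
        cats = {"all": list(lengths)}
        result = length_bias_enrichment(de, lengths, cats)
        assert result["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_category_excluded(self):
        lengths = {f"g{i}": 1000 for i in range(10)}
        de = {f"g{i}": i < 3 for i in range(10)}
        cats = {"none": ["absent_gene"], "some": ["g0", "g1"]}
        result = length_bias_enrichment(de, lengths, cats)
        assert list(result["category"]) == ["some"]

    def test_long_gene_bias_dampens_enrichment(self):
        # DE concentrated in long genes: a long-gene category should be
        # less surprising under the length-aware test than the central one
        rng = np.random.default_rng(3)
        lengths = {f"g{i}": int(l) for i, l in enumerate(rng.integers(200, 20_000, 200))}
        ordered = sorted(lengths, key=lengths.get)
        de = {g: g in ordered[-40:] for g in lengths}  # all DE genes are long
        cats = {"long": ordered[-30:]}
        res = length_bias_enrichment(de, lengths, cats)
        n_de_in = int(res["n_de"].iloc[0])
        central = float(stats.hypergeom.sf(n_de_in - 1, 200, 30, 40))
        assert res["p_value"].iloc[0] > central
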