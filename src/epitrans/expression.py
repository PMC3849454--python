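"""Gene and miRNA expression quantification and differential testing.

The workflow mirrors a two-library digital expression comparison: RPKM
quantification, a >= 1 RPKM detection filter, TMM between-library scaling,
a per-gene Fisher exact test on TMM-scaled libraries, Benjamini-Hochberg
FDR with a fold-change gate, and length-bias-aware category enrichment via
the Wallenius noncentral hypergeometric distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FC_PSEUDOCOUNT = 0.5  # used in the reported ratio only, never in testing


@dataclass
class ExpressionRecord:
    gene_id: str
    count_a: int
    count_b: int
    rpkm_a: float = np.nan
    rpkm_b: float = np.nan
    fold_change: float = np.nan  # normalized b / a
    p_value: float = np.nan
    fdr: float = np.nan
    de_call: str = "none"  # {up, down, none}; direction of sample b vs a


@dataclass
class NormalizationFactors:
    """Per-sample effective-library scaling, anchored at a reference.

    ``effective_library(sample) = library_size * factor[sample]`` with
    ``factor[reference] = 1``.
    """

    reference_sample: str
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors.setdefault(self.reference_sample, 1.0)
        if abs(self.factors[self.reference_sample] - 1.0) > 1e-12:
            raise ValueError("reference sample must have factor 1")


def compute_rpkm(count: float, exon_length_bp: int, library_size: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_length_bp <= 0:
        raise ValueError("exon_length_bp must be positive")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 1e9 / (exon_length_bp * library_size)


def filter_expressed(records: list[ExpressionRecord], threshold_rpkm: float = 1.0) -> list[ExpressionRecord]:
    """Keep genes detected above the RPKM threshold in at least one sample."""
    return [r for r in records if r.rpkm_a > threshold_rpkm or r.rpkm_b > threshold_rpkm]


def tmm_factor(
    counts_ref: np.ndarray,
    counts_test: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """Weighted trimmed mean of log-ratios between two count vectors.

    M = log2(test/ref) and A = mean log2 abundance are computed on genes
    with nonzero counts in both vectors; the top and bottom ``trim_m`` of
    genes by M and ``trim_a`` by A are discarded, and the remaining M
    values are averaged with inverse-approximate-variance weights.
    Returns ``2**mean`` so an exact 2x library gives factor 2.
    """
    ref = np.asarray(counts_ref, dtype=float)
    test = np.asarray(counts_test, dtype=float)
    if ref.shape != test.shape:
        raise ValueError("count vectors must have equal length")
    n_ref, n_test = ref.sum(), test.sum()
    keep = (ref > 0) & (test > 0)
    ref, test = ref[keep], test[keep]
    if ref.size == 0:
        warnings.warn("no genes with nonzero counts in both samples; factor 1.0")
        return 1.0

    m = np.log2(test / ref)
    a = 0.5 * (np.log2(test) + np.log2(ref))
    # binomial-style approximate variance of M
    w = 1.0 / np.maximum(1.0 / test - 1.0 / n_test + 1.0 / ref - 1.0 / n_ref, 1e-12)

    def _trim_mask(values: np.ndarray, frac: float) -> np.ndarray:
        k = int(np.floor(frac * values.size))
        if k == 0:
            return np.ones(values.size, dtype=bool)
        order = np.argsort(values, kind="stable")
        mask = np.ones(values.size, dtype=bool)
        mask[order[:k]] = False
        mask[order[values.size - k:]] = False
        return mask

    kept = _trim_mask(m, trim_m) & _trim_mask(a, trim_a)
    if kept.sum() < 10:
        warnings.warn("fewer than 10 genes survive TMM trimming; using untrimmed mean")
        kept = np.ones(m.size, dtype=bool)
    mean_m = float(np.average(m[kept], weights=w[kept]))
    return float(2.0 ** mean_m)


def normalization_factors(
    counts: pd.DataFrame, reference_sample: str
) -> NormalizationFactors:
    """TMM effective-library factors for every sample against a reference.

    The raw trimmed-mean ratio tracks both depth and composition; dividing
    by the library-size ratio leaves the compositional part so that
    ``library_size * factor`` equalizes the proportions of typical
    (non-differential) genes across samples.
    """
    ref_counts = counts[reference_sample].to_numpy()
    lib_ref = ref_counts.sum()
    factors: dict[str, float] = {reference_sample: 1.0}
    for sample in counts.columns:
        if sample == reference_sample:
            continue
        raw = tmm_factor(ref_counts, counts[sample].to_numpy())
        lib = counts[sample].to_numpy().sum()
        factors[sample] = raw * lib_ref / lib
    return NormalizationFactors(reference_sample=reference_sample, factors=factors)


def fisher_de(count_a: int, count_b: int, effective_lib_a: float, effective_lib_b: float) -> float:
    """Two-sided Fisher exact p for one gene against the rest of each library."""
    lib_a, lib_b = int(round(effective_lib_a)), int(round(effective_lib_b))
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be nonnegative")
    if count_a > lib_a or count_b > lib_b:
        raise ValueError("count exceeds library size")
    table = [[count_a, lib_a - count_a], [count_b, lib_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def fold_change(count_a: float, lib_a: float, count_b: float, lib_b: float) -> float:
    """Normalized ratio b/a with a 0.5 pseudo-count for zero counts."""
    ca = count_a if count_a > 0 else FC_PSEUDOCOUNT
    cb = count_b if count_b > 0 else FC_PSEUDOCOUNT
    return (cb / lib_b) / (ca / lib_a)


def call_de(
    records: list[ExpressionRecord],
    fdr_alpha: float = 0.05,
    fc_threshold: float = 3.0,
) -> list[ExpressionRecord]:
    """BH-correct p-values and set de_call by the FDR-and-fold conjunction.

    A gene is called iff its BH FDR is below ``fdr_alpha`` AND
    ``max(fc, 1/fc) >= fc_threshold``; direction follows the fold change.
    """
    if not records:
        return records
    fdrs = bh_fdr([r.p_value for r in records])
    for r, q in zip(records, fdrs):
        r.fdr = float(q)
        fc = r.fold_change
        if q < fdr_alpha and max(fc, 1.0 / fc) >= fc_threshold:
            r.de_call = "up" if fc > 1 else "down"
        else:
            r.de_call = "none"
    return records


def chi_square_2x2(count_a: int, count_b: int, lib_a: int, lib_b: int) -> float:
    """Pearson chi-square p (no continuity correction) on a 2x2 count table."""
    table = np.array([[count_a, lib_a - count_a], [count_b, lib_b - count_b]], dtype=float)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def mirna_de(
    records: list[ExpressionRecord],
    alpha: float = 0.05,
    fc_threshold: float = 3.0,
    lib_a: int | None = None,
    lib_b: int | None = None,
) -> list[ExpressionRecord]:
    """Small-RNA differential calls: per-gene chi-square with Bonferroni.

    Records should already be detection-filtered (>= 1 RPKM in at least
    one sample).  Genes whose 2x2 table has an expected cell below 1 fall
    back to the Fisher exact test.  The Bonferroni family is the set of
    tested genes.
    """
    if not records:
        return records
    la = lib_a if lib_a is not None else sum(r.count_a for r in records)
    lb = lib_b if lib_b is not None else sum(r.count_b for r in records)
    m = len(records)
    for r in records:
        table = np.array(
            [[r.count_a, la - r.count_a], [r.count_b, lb - r.count_b]], dtype=float
        )
        if table.sum() == 0:
            p = 1.0
        else:
            expected = stats.contingency.expected_freq(table)
            if (expected < 1).any():
                p = fisher_de(r.count_a, r.count_b, la, lb)
            else:
                p = chi_square_2x2(r.count_a, r.count_b, la, lb)
        r.p_value = float(p)
        r.fdr = min(1.0, m * p)  # Bonferroni-adjusted
        fc = r.fold_change
        if r.fdr < alpha and max(fc, 1.0 / fc) >= fc_threshold:
            r.de_call = "up" if fc > 1 else "down"
        else:
            r.de_call = "none"
    return records


# ---------------------------------------------------------------------------
# Length-bias-aware category enrichment
# ---------------------------------------------------------------------------

def probability_weights(
    de_flags: np.ndarray, gene_lengths: np.ndarray, n_bins: int = 40
) -> np.ndarray:
    """Per-gene selection weights from a monotone fit of P(DE) vs length.

    Genes are grouped into equal-occupancy length bins; the per-bin DE
    fraction is fit by isotonic regression on median bin length, and each
    gene receives the fitted probability for its bin (floored at a small
    positive value so odds stay finite).
    """
    de = np.asarray(de_flags, dtype=float)
    lengths = np.asarray(gene_lengths, dtype=float)
    n = de.size
    n_bins = min(n_bins, max(1, n // 5))
    order = np.argsort(lengths, kind="stable")
    bin_ids = np.empty(n, dtype=int)
    bin_ids[order] = np.minimum((np.arange(n) * n_bins) // n, n_bins - 1)
    bin_len = np.array([np.median(lengths[bin_ids == b]) for b in range(n_bins)])
    bin_rate = np.array([de[bin_ids == b].mean() for b in range(n_bins)])
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(bin_len, bin_rate)
    weights = fitted[bin_ids]
    return np.maximum(weights, 1e-6)


def wallenius_enrichment_p(
    n_in_cat: int, n_total: int, n_de: int, n_de_in_cat: int, odds: float
) -> float:
    """Upper-tail Wallenius noncentral hypergeometric p for one category.

    At odds 1 this is exactly the central hypergeometric tail.
    """
    if n_in_cat == 0 or n_de == 0:
        return 1.0
    if abs(odds - 1.0) < 1e-9:
        return float(stats.hypergeom.sf(n_de_in_cat - 1, n_total, n_in_cat, n_de))
    dist = stats.nchypergeom_wallenius(n_total, n_in_cat, n_de, odds)
    return float(dist.sf(n_de_in_cat - 1))


def length_bias_enrichment(
    de_flags: dict[str, bool],
    gene_lengths: dict[str, int],
    category_map: dict[str, list[str]],
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Category over-representation of DE genes, correcting for length bias.

    Each gene's probability of being called differentially expressed is
    modelled as a monotone function of its length; a category's odds
    parameter is the mean weight inside over the mean weight outside, and
    the enrichment p-value is the Wallenius biased-urn upper tail.  BH
    correction runs across categories.
    """
    genes = sorted(gene_lengths)
    idx = {g: i for i, g in enumerate(genes)}
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)
    de = np.array([bool(de_flags.get(g, False)) for g in genes])
    weights = probability_weights(de, lengths)
    n_total, n_de = len(genes), int(de.sum())

    rows = []
    for cat, members in sorted(category_map.items()):
        member_idx = np.array([idx[g] for g in members if g in idx], dtype=int)
        if member_idx.size == 0:
            logger.info("category %s has no scored genes; excluded", cat)
            continue
        inside = np.zeros(n_total, dtype=bool)
        inside[member_idx] = True
        n_in = int(inside.sum())
        n_de_in = int((inside & de).sum())
        if n_in == n_total:
            odds, p = 1.0, 1.0
        else:
            odds = float(weights[inside].mean() / weights[~inside].mean())
            p = wallenius_enrichment_p(n_in, n_total, n_de, n_de_in, odds)
        rows.append({"category": cat, "n_genes": n_in, "n_de": n_de_in,
                     "odds": odds, "p_value": p})
    result = pd.DataFrame(rows)
    if not result.empty:
        result["fdr"] = bh_fdr(result["p_value"].to_numpy())
        result["significant"] = result["fdr"] < fdr_alpha
    return result


# ---------------------------------------------------------------------------
# Table-level driver
# ---------------------------------------------------------------------------

def differential_expression(
    counts: pd.DataFrame,
    exon_lengths: dict[str, int],
    sample_a: str,
    sample_b: str,
    rpkm_threshold: float = 1.0,
    fdr_alpha: float = 0.05,
    fc_threshold: float = 3.0,
) -> pd.DataFrame:
    """Full mRNA differential-expression table between two samples.

    ``sample_a`` is the normalization reference.  Returns one row per gene
    passing the detection filter, with RPKM, fold change (b over a),
    Fisher p, BH FDR and the DE call.
    """
    lib_a = int(counts[sample_a].sum())
    lib_b = int(counts[sample_b].sum())
    norm = normalization_factors(counts[[sample_a, sample_b]], sample_a)
    eff_a = lib_a * norm.factors[sample_a]
    eff_b = lib_b * norm.factors[sample_b]

    records = []
    for gene_id, row in counts.iterrows():
        if gene_id not in exon_lengths:
            continue
        ca, cb = int(row[sample_a]), int(row[sample_b])
        rec = ExpressionRecord(
            gene_id=str(gene_id), count_a=ca, count_b=cb,
            rpkm_a=compute_rpkm(ca, exon_lengths[gene_id], lib_a),
            rpkm_b=compute_rpkm(cb, exon_lengths[gene_id], lib_b),
        )
        rec.fold_change = fold_change(ca, eff_a, cb, eff_b)
        records.append(rec)

    records = filter_expressed(records, rpkm_threshold)
    for rec in records:
        rec.p_value = fisher_de(rec.count_a, rec.count_b, eff_a, eff_b)
    records = call_de(records, fdr_alpha=fdr_alpha, fc_threshold=fc_threshold)

    return pd.DataFrame(
        [
            {"gene_id": r.gene_id, "count_a": r.count_a, "count_b": r.count_b,
             "rpkm_a": r.rpkm_a, "rpkm_b": r.rpkm_b, "fold_change": r.fold_change,
             "p_value": r.p_value, "fdr": r.fdr, "de_call": r.de_call}
            for r in records
        ]
    ).set_index("gene_id")
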