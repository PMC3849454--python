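"""Candidate-gene selection and qPCR-style validation statistics.

A gene is a candidate when it (i) lies within 5 kb of a region with
>= 3-fold increased RNA Pol II binding in the cancer-like sample,
(ii) lies within 5 kb of a region with >= 3-fold increased H3K27me3
binding in the normal-like sample, and (iii) shows >= 3-fold increased
expression in the cancer-like sample.  The relative-quantification step
implements the delta-delta-Ct method normalized to the geometric mean of
two housekeeping genes, with a Mann-Whitney group comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cna_bias import mann_whitney
from .genome_io import GeneModel, GenomicInterval, distance_to
from .islands import DifferentialIsland

logger = logging.getLogger(__name__)


@dataclass
class CandidateGene:
    gene_id: str
    expression_fc: float
    nearest_polII_island: tuple[GenomicInterval, float, float] | None
    nearest_k27_island: tuple[GenomicInterval, float, float] | None
    criteria_met: tuple[bool, bool, bool]

    @property
    def is_candidate(self) -> bool:
        return all(self.criteria_met)


@dataclass
class QpcrResult:
    gene_id: str
    relative_expression: pd.Series  # per-sample arbitrary units
    groups: pd.Series
    group_fold_change: float
    mann_whitney_p: float


def _nearest_qualifying(
    gene: GeneModel,
    islands: list[DifferentialIsland],
    direction: str,
    fc: float,
) -> tuple[GenomicInterval, float, float] | None:
    """Closest island with the required direction and fold, or None."""
    best = None
    for isl in islands:
        if isl.direction != direction:
            continue
        oriented_fc = isl.fold_change if direction == "increased" else 1 / isl.fold_change
        if oriented_fc < fc:
            continue
        d = distance_to(gene.interval, isl.interval)
        if best is None or d < best[2]:
            best = (isl.interval, oriented_fc, d)
    return best


def select_candidates(
    de_table: pd.DataFrame,
    diff_polII: list[DifferentialIsland],
    diff_k27: list[DifferentialIsland],
    genes: list[GeneModel],
    window_bp: int = 5000,
    fc: float = 3.0,
    require_de_fdr: bool = True,
) -> list[CandidateGene]:
    """Apply the 3-criterion conjunction and return candidates by fold change.

    Differential islands are oriented sample-a-vs-sample-b with sample a
    the cancer-like line: Pol II must be "increased" (up in cancer) and
    H3K27me3 "decreased" (i.e. higher in the normal-like line).  Distances
    are measured from the gene body.  Criterion (iii) uses the DE table's
    fold change (cancer over normal) and, by default, its FDR-gated call.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    out = []
    for gene_id, row in de_table.iterrows():
        gene = gene_by_id.get(str(gene_id))
        if gene is None:
            continue
        pol = _nearest_qualifying(gene, diff_polII, "increased", fc)
        k27 = _nearest_qualifying(gene, diff_k27, "decreased", fc)
        crit1 = pol is not None and pol[2] <= window_bp
        crit2 = k27 is not None and k27[2] <= window_bp
        if require_de_fdr:
            crit3 = row["de_call"] == "up"
        else:
            crit3 = row["fold_change"] >= fc
        cand = CandidateGene(str(gene_id), float(row["fold_change"]), pol, k27,
                             (crit1, crit2, crit3))
        if cand.is_candidate:
            out.append(cand)
    out.sort(key=lambda c: -c.expression_fc)
    return out


def ddct(
    cq_table: pd.DataFrame,
    target: str,
    housekeeping_pair: tuple[str, str],
    reference_group: str,
) -> tuple[pd.Series, pd.Series]:
    """Relative expression per sample by the delta-delta-Ct method.

    Technical replicates are averaged per (sample, assay).  The target Cq
    is normalized to the arithmetic mean Cq of the two housekeeping
    assays — equivalent to the geometric mean of their linear quantities —
    then to the mean delta-Cq of the reference group; relative expression
    is ``2 ** -ddCt``.  Samples missing any assay are dropped with a log
    message.  Returns (relative expression, group label) per sample.
    """
    hk1, hk2 = housekeeping_pair
    mean_cq = cq_table.groupby(["sample", "assay"])["cq"].mean().unstack()
    groups = cq_table.groupby("sample")["group"].first()
    needed = [target, hk1, hk2]
    missing = [a for a in needed if a not in mean_cq.columns]
    if missing:
        raise ValueError(f"assays absent from Cq table: {missing}")
    complete = mean_cq[needed].dropna()
    dropped = set(mean_cq.index) - set(complete.index)
    for s in sorted(dropped):
        logger.warning("sample %s dropped: missing Cq", s)
    dcq = complete[target] - (complete[hk1] + complete[hk2]) / 2.0
    groups = groups.loc[complete.index]
    ref_mean = dcq[groups == reference_group].mean()
    if math.isnan(ref_mean):
        raise ValueError(f"no samples in reference group {reference_group!r}")
    rel = 2.0 ** -(dcq - ref_mean)
    rel.name = target
    return rel, groups


def compare_groups(
    relative_expressions: pd.Series, group_labels: pd.Series, reference_group: str
) -> tuple[float, float]:
    """Fold change of group means (test over reference) and Mann-Whitney p."""
    ref = relative_expressions[group_labels == reference_group]
    test = relative_expressions[group_labels != reference_group]
    if len(ref) < 3 or len(test) < 3:
        raise ValueError("each group needs at least 3 samples")
    fold = float(test.mean() / ref.mean())
    _, p = mann_whitney(test.to_numpy(), ref.to_numpy())
    return fold, p


def qpcr_validation(
    cq_table: pd.DataFrame,
    targets: list[str],
    housekeeping_pair: tuple[str, str],
    reference_group: str,
) -> list[QpcrResult]:
    """Run ddCt + group comparison for each assayed target gene."""
    out = []
    for target in targets:
        rel, groups = ddct(cq_table, target, housekeeping_pair, reference_group)
        fold, p = compare_groups(rel, groups, reference_group)
        out.append(QpcrResult(target, rel, groups, fold, p))
    return out


def candidates_to_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append({
            "gene_id": c.gene_id,
            "expression_fc": c.expression_fc,
            "polII_island_distance": c.nearest_polII_island[2] if c.nearest_polII_island else np.nan,
            "polII_island_fold": c.nearest_polII_island[1] if c.nearest_polII_island else np.nan,
            "k27_island_distance": c.nearest_k27_island[2] if c.nearest_k27_island else np.nan,
            "k27_island_fold": c.nearest_k27_island[1] if c.nearest_k27_island else np.nan,
        })
    return pd.DataFrame(rows)
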