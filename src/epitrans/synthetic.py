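"""Synthetic two-cell-line study generator with planted truth.

Builds, from a seed, a complete toy study: a small genome with stranded
multi-exon genes, negative-binomial expression counts for a tumor-like
and a normal-like line with planted >= 3-fold differential genes, ChIP
tags for four marks with realistic TSS geometry (bimodal H3K4me1/me3,
TSS-peaked Pol II, broad H3K27me3 over weakly expressed genes with a TSS
dip in the tumor-like line), copy-number segments, and a qPCR Cq plate
with two housekeeping assays.  Every generator is a pure function of its
parameters and seed, and a :class:`TruthTable` records what was planted.

Mark geometry defaults: H3K4me3 peaks ~350 bp either side of the TSS,
H3K4me1 ~700 bp upstream / ~1300 bp downstream, Pol II centred on the
TSS, H3K27me3 spread over the gene body plus 1 kb flanks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    CnaSegment,
    GeneModel,
    GenomicInterval,
    TagSet,
    write_cna_segments,
    write_count_table,
    write_gene_models,
    write_tags,
)
from .profiles import assign_quartiles

TUMOR, NORMAL = "tumor", "normal"


@dataclass
class TruthTable:
    """Everything planted into one synthetic dataset."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true log2 FC (tumor/normal)
    candidate_genes: list[str] = field(default_factory=list)
    island_truth: dict[str, list[tuple[GenomicInterval, float, str]]] = field(default_factory=dict)
    cna_truth: list[CnaSegment] = field(default_factory=list)
    qpcr_truth: dict[str, float] = field(default_factory=dict)  # gene -> true tumor/normal ratio

    def validate(self, genes: list[GeneModel], fc_threshold: float = 3.0) -> None:
        gene_ids = {g.gene_id for g in genes}
        for cand in self.candidate_genes:
            lfc = self.de_genes.get(cand)
            if lfc is None or 2.0 ** lfc < fc_threshold:
                raise ValueError(f"candidate {cand} not planted DE at >= {fc_threshold}-fold up")
            if cand not in gene_ids:
                raise ValueError(f"candidate {cand} not in gene set")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_genes": self.de_genes,
            "candidate_genes": self.candidate_genes,
            "island_truth": {
                mark: [
                    {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "enrichment": enr, "sample": sample}
                    for iv, enr, sample in entries
                ]
                for mark, entries in self.island_truth.items()
            },
            "cna_truth": [
                {"chrom": s.interval.chrom, "start": s.interval.start,
                 "end": s.interval.end, "state": s.state}
                for s in self.cna_truth
            ],
            "qpcr_truth": self.qpcr_truth,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_genes=payload["de_genes"],
            candidate_genes=payload["candidate_genes"],
            island_truth={
                mark: [
                    (GenomicInterval(e["chrom"], e["start"], e["end"]),
                     e["enrichment"], e["sample"])
                    for e in entries
                ]
                for mark, entries in payload["island_truth"].items()
            },
            cna_truth=[
                CnaSegment(GenomicInterval(e["chrom"], e["start"], e["end"]), e["state"])
                for e in payload["cna_truth"]
            ],
            qpcr_truth=payload["qpcr_truth"],
        )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(
    n_chrom: int = 2,
    chrom_length_bp: int = 2_500_000,
    n_genes: int = 150,
    seed: int = 0,
    min_gap_bp: int = 12_000,
    edge_bp: int = 8_000,
) -> list[GeneModel]:
    """Non-overlapping stranded genes with 1-10 exons, deterministic per seed.

    Genes are at least ``min_gap_bp`` apart so that promoter-proximal
    ChIP signal planted at one gene stays more than 5 kb from its
    neighbors, keeping planted candidate truth unambiguous.
    """
    if n_genes < 8:
        raise ValueError("need at least 8 genes")
    if chrom_length_bp < 100_000:
        raise ValueError("chromosomes must be at least 100 kb")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        pos = edge_bp
        for _ in range(per_chrom[ci]):
            pos += int(rng.integers(min_gap_bp, min_gap_bp * 2))
            length = int(rng.integers(3_000, 12_000))
            if pos + length > chrom_length_bp - edge_bp:
                raise ValueError(
                    f"genes do not fit on {chrom}: need more space for {per_chrom[ci]} genes"
                )
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 11))
            # split the body into 2*n_exons-1 alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(1, length), size=max(0, 2 * n_exons - 2), replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = tuple(
                GenomicInterval(chrom, pos + int(bounds[2 * k]), pos + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
            interval = GenomicInterval(chrom, pos, pos + length)
            cds_lo = pos + int(0.1 * length)
            cds_hi = pos + int(0.9 * length)
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    interval=interval,
                    strand=strand,
                    exons=exons,
                    thick_start=cds_lo,
                    thick_end=cds_hi,
                )
            )
            pos += length
    return genes


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(
    genes: list[GeneModel],
    n_de: int = 30,
    fc_range: tuple[float, float] = (3.0, 8.0),
    dispersion: float = 0.01,
    library_sizes: tuple[int, int] = (400_000, 400_000),
    seed: int = 0,
    candidate_ids: list[str] | None = None,
    shared_dispersion: float = 0.1,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Negative-binomial count tables for the two lines with planted DE.

    Non-differential genes share their expected proportion across lines
    (up to library scaling); ``n_de`` genes are shifted by a fold drawn
    from ``fc_range``, half up and half down in the tumor-like line.
    Overdispersion has two parts: a gene-level gamma multiplier shared
    by both lines (``shared_dispersion``; shapes the cross-gene count
    distribution but cancels in the between-line ratio) and an
    independent per-line multiplier (``dispersion``) that the
    differential test must withstand.  Differential status is planted on
    genes of above-median abundance so the planted truth survives the
    detection filter.  Genes named in ``candidate_ids`` are always
    planted up at the top of the fold range with generous abundance.
    Returns the count table (columns tumor, normal) and the truth map
    gene -> signed log2 fold (tumor/normal).
    """
    if n_de > len(genes):
        raise ValueError("n_de exceeds the number of genes")
    if fc_range[0] < 3.0:
        raise ValueError("planted folds below 3 would not satisfy the DE rule")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    abundance = rng.lognormal(mean=np.log(60.0), sigma=1.0, size=n)
    abundance /= abundance.sum()

    candidate_ids = list(candidate_ids or [])
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    for cid in candidate_ids:
        # keep candidates above the detection filter without making them
        # highly expressed in the normal-like line (they are planted as
        # repressed-in-normal, activated-in-tumor)
        abundance[idx_of[cid]] = max(abundance[idx_of[cid]], np.median(abundance))
    abundance /= abundance.sum()

    eligible = [
        i for i in np.argsort(-abundance)[: n // 2]
        if gene_ids[i] not in candidate_ids
    ]
    n_other = max(0, n_de - len(candidate_ids))
    chosen = list(rng.choice(eligible, size=min(n_other, len(eligible)), replace=False))

    truth: dict[str, float] = {}
    fc_tumor = np.ones(n)
    for cid in candidate_ids:
        fc = float(rng.uniform(max(6.0, fc_range[0]), max(8.0, fc_range[1])))
        fc_tumor[idx_of[cid]] = fc
        truth[cid] = float(np.log2(fc))
    for k, i in enumerate(chosen):
        fc = float(rng.uniform(*fc_range))
        if k % 2 == 0:
            fc_tumor[i] = fc
            truth[gene_ids[i]] = float(np.log2(fc))
        else:
            fc_tumor[i] = 1.0 / fc
            truth[gene_ids[i]] = float(-np.log2(fc))

    def _nb(mean: np.ndarray) -> np.ndarray:
        if dispersion <= 1e-9:
            return rng.poisson(mean)
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean * dispersion)
        return rng.poisson(lam)

    if shared_dispersion > 1e-9:
        shape = 1.0 / shared_dispersion
        shared = rng.gamma(shape, shared_dispersion, size=n)
    else:
        shared = np.ones(n)
    mean_tumor = abundance * shared * library_sizes[0] * fc_tumor
    mean_normal = abundance * shared * library_sizes[1]
    counts = pd.DataFrame(
        {TUMOR: _nb(mean_tumor), NORMAL: _nb(mean_normal)}, index=pd.Index(gene_ids, name="gene_id")
    )
    return counts, truth


# ---------------------------------------------------------------------------
# ChIP tags
# ---------------------------------------------------------------------------

@dataclass
class MarkModel:
    """Offset geometry and quartile weighting for one ChIP mark."""

    kind: str  # "bimodal", "tss" or "body"
    offsets: tuple[float, ...] = ()
    sd: float = 50.0
    body_flank_bp: int = 1000
    # expected signal tags per gene by expression quartile
    quartile_tags: dict[str, float] = field(default_factory=dict)
    symmetric: bool = True  # same expected signal in both samples


# Per-gene signal rates are kept small enough that per-gene per-bin counts
# at the planted peaks stay near the Poisson trimming cap used by the
# profile stage, as they do at realistic sequencing depth; towers far above
# the cap would be flattened into plateaus and erase the planted geometry.
DEFAULT_MARK_MODELS: dict[str, MarkModel] = {
    "H3K4me3": MarkModel(
        kind="bimodal", offsets=(-350.0, 350.0), sd=40.0,
        quartile_tags={"high": 30, "medium": 16, "low": 6, "very low": 2},
        symmetric=False,  # follows each sample's own expression
    ),
    "H3K4me1": MarkModel(
        kind="bimodal", offsets=(-700.0, 1300.0), sd=100.0,
        quartile_tags={"high": 30, "medium": 18, "low": 8, "very low": 3},
        symmetric=False,
    ),
    "PolII": MarkModel(
        kind="tss", offsets=(0.0,), sd=80.0,
        quartile_tags={"high": 40, "medium": 20, "low": 8, "very low": 3},
        symmetric=True,  # tied to mean expression so only planted sites differ
    ),
    "H3K27me3": MarkModel(
        kind="body", body_flank_bp=1000,
        quartile_tags={"high": 60, "medium": 120, "low": 250, "very low": 420},
        symmetric=True,
    ),
}

CANDIDATE_POLII_BOOST = 10.0   # tumor-only extra Pol II signal, x high-quartile rate
CANDIDATE_K27_TAGS = 1600.0    # normal-only extra H3K27me3 tags over the gene body
DIP_HALF_WIDTH_BP = 300        # tumor-line H3K27me3 depletion zone around active TSS
DIP_RETENTION = 0.1


def _signal_positions(
    rng: np.random.Generator, gene: GeneModel, model: MarkModel, n_tags: int
) -> np.ndarray:
    if n_tags == 0:
        return np.empty(0, dtype=np.int64)
    if model.kind == "body":
        lo = max(0, gene.interval.start - model.body_flank_bp)
        hi = gene.interval.end + model.body_flank_bp
        return rng.integers(lo, hi, size=n_tags)
    comps = rng.integers(0, len(model.offsets), size=n_tags)
    offs = np.array(model.offsets)[comps] + rng.normal(0.0, model.sd, size=n_tags)
    if gene.strand == "+":
        pos = gene.tss + offs
    else:
        pos = gene.tss - offs
    return np.maximum(np.rint(pos).astype(np.int64), 0)


def generate_chip_tags(
    genes: list[GeneModel],
    expression_quartiles: dict[str, dict[str, str]],
    mark_models: dict[str, MarkModel] | None = None,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    candidate_ids: list[str] | None = None,
    background_tags: int = 20_000,
    input_tags: int = 40_000,
) -> tuple[dict[tuple[str, str], TagSet], dict[str, list[tuple[GenomicInterval, float, str]]]]:
    """ChIP tag sets per (mark, sample) plus matched inputs, with truth.

    ``expression_quartiles`` maps sample -> gene -> quartile label; a
    synthetic "mean" sample keys the symmetric marks.  Candidate genes
    get tumor-only Pol II enrichment at the TSS and normal-only broad
    H3K27me3 over the body; tumor-line H3K27me3 is depleted around the
    TSS of highly expressed genes (the dip).  Input tags are uniform.
    Returns ({(mark, sample): TagSet, ("input", sample): TagSet},
    island truth per mark).
    """
    mark_models = mark_models or DEFAULT_MARK_MODELS
    candidate_ids = set(candidate_ids or [])
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.interval.end + 10_000)
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    chrom_p = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()

    def _uniform_tags(n: int) -> list[tuple[str, int, str]]:
        picks = rng.choice(len(chroms), size=n, p=chrom_p)
        out = []
        for ci in range(len(chroms)):
            m = int((picks == ci).sum())
            if m == 0:
                continue
            pos = rng.integers(0, chrom_lengths[chroms[ci]], size=m)
            strands = np.where(rng.random(m) < 0.5, "+", "-")
            out.extend(zip([chroms[ci]] * m, pos.tolist(), strands.tolist()))
        return out

    tagsets: dict[tuple[str, str], TagSet] = {}
    island_truth: dict[str, list[tuple[GenomicInterval, float, str]]] = {m: [] for m in mark_models}

    for mark, model in mark_models.items():
        for sample in (TUMOR, NORMAL):
            quart = expression_quartiles[sample if not model.symmetric else "mean"]
            tags: list[tuple[str, int, str]] = _uniform_tags(background_tags)
            for gene in genes:
                expected = model.quartile_tags.get(quart.get(gene.gene_id, "very low"), 0.0)
                if mark == "PolII" and gene.gene_id in candidate_ids:
                    if sample == TUMOR:
                        expected += CANDIDATE_POLII_BOOST * model.quartile_tags["high"]
                    else:
                        expected = model.quartile_tags["low"]
                if mark == "H3K27me3" and gene.gene_id in candidate_ids:
                    if sample == NORMAL:
                        expected += CANDIDATE_K27_TAGS
                n_sig = int(rng.poisson(expected))
                pos = _signal_positions(rng, gene, model, n_sig)
                if (
                    mark == "H3K27me3"
                    and sample == TUMOR
                    and expression_quartiles[TUMOR].get(gene.gene_id) == "high"
                ):
                    near_tss = np.abs(pos - gene.tss) <= DIP_HALF_WIDTH_BP
                    keep = ~near_tss | (rng.random(pos.size) < DIP_RETENTION)
                    pos = pos[keep]
                strands = np.where(rng.random(pos.size) < 0.5, "+", "-")
                tags.extend(zip([gene.chrom] * pos.size, pos.tolist(), strands.tolist()))
            tagsets[(mark, sample)] = TagSet(mark=mark, sample=sample, tags=tags)

    for sample in (TUMOR, NORMAL):
        tagsets[("input", sample)] = TagSet(mark="input", sample=sample,
                                            tags=_uniform_tags(input_tags))

    gene_by_id = {g.gene_id: g for g in genes}
    for cid in sorted(candidate_ids):
        g = gene_by_id[cid]
        island_truth["PolII"].append(
            (GenomicInterval(g.chrom, max(0, g.tss - 400), g.tss + 400),
             CANDIDATE_POLII_BOOST, TUMOR)
        )
        island_truth["H3K27me3"].append(
            (GenomicInterval(g.chrom, max(0, g.interval.start - 1000), g.interval.end + 1000),
             CANDIDATE_K27_TAGS / max(DEFAULT_MARK_MODELS["H3K27me3"].quartile_tags["high"], 1.0),
             NORMAL)
        )
    return tagsets, island_truth


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

def generate_cna(
    chrom_lengths: dict[str, int],
    seed: int = 0,
) -> list[CnaSegment]:
    """Copy-number segments tiling part of the genome.

    Includes a pair of same-state (gain) segments 0.5 Mb apart to
    exercise merging, a loss region, and CNLOH; segments never overlap.
    Proportions are scaled to each chromosome's length.
    """
    rng = np.random.default_rng(seed)
    segments: list[CnaSegment] = []
    chroms = sorted(chrom_lengths)
    for i, chrom in enumerate(chroms):
        L = chrom_lengths[chrom]
        jitter = int(rng.integers(0, min(20_000, max(1, L // 100))))
        if i % 2 == 0:
            # two gains < 1 Mb apart, then CNLOH, then a loss
            layout = [
                ("gain", 0.06, 0.16), ("gain", 0.36, 0.46),
                ("CNLOH", 0.52, 0.62), ("loss", 0.72, 0.84),
            ]
        else:
            layout = [("gain", 0.10, 0.22), ("CNLOH", 0.40, 0.52), ("loss", 0.80, 0.88)]
        for state, f0, f1 in layout:
            start = min(int(f0 * L) + jitter, L - 2)
            end = min(int(f1 * L) + jitter, L - 1)
            segments.append(CnaSegment(GenomicInterval(chrom, start, end), state))
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return segments


def loss_free_genes(genes: list[GeneModel], segments: list[CnaSegment], pad: int = 6_000) -> list[GeneModel]:
    """Genes whose padded body avoids every loss segment."""
    losses = [s.interval for s in segments if s.state == "loss"]
    out = []
    for g in genes:
        padded = GenomicInterval(g.chrom, max(0, g.interval.start - pad), g.interval.end + pad)
        if not any(padded.overlaps(iv) for iv in losses):
            out.append(g)
    return out


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def generate_qpcr(
    genes_assayed: dict[str, float],
    n_per_group: int = 10,
    housekeeping: tuple[str, str] = ("HK1", "HK2"),
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Cq plate for target assays with two housekeeping genes.

    ``genes_assayed`` maps target -> true tumor/normal expression ratio.
    Cq = baseline - log2(expression) + Gaussian noise per technical
    replicate; housekeeping expression is constant across groups, and an
    additional per-sample plate shift affects all of a sample's assays
    equally (removed by ddCt normalization).
    """
    if len(housekeeping) != 2:
        raise ValueError("exactly two housekeeping assays are required")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"N{i + 1}", NORMAL) for i in range(n_per_group)] + [
        (f"T{i + 1}", TUMOR) for i in range(n_per_group)
    ]
    baselines = {assay: float(rng.uniform(18, 26)) for assay in
                 list(genes_assayed) + list(housekeeping)}
    for sample, group in samples:
        plate_shift = float(rng.normal(0.0, 0.5)) if noise_sd > 0 else 0.0
        for assay in list(genes_assayed) + list(housekeeping):
            if assay in housekeeping:
                expr = 1.0
            else:
                expr = genes_assayed[assay] if group == TUMOR else 1.0
            base_cq = baselines[assay] - np.log2(expr) + plate_shift
            for rep in range(1, n_replicates + 1):
                cq = base_cq + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append({"sample": sample, "group": group, "assay": assay,
                             "replicate": rep, "cq": cq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    genes: list[GeneModel]
    chrom_lengths: dict[str, int]
    counts: pd.DataFrame
    tagsets: dict[tuple[str, str], TagSet]
    cna_segments: list[CnaSegment]
    cq_table: pd.DataFrame
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_models(self.genes, outdir / "genes.bed")
        write_count_table(self.counts, outdir / "counts.tsv")
        for (mark, sample), ts in self.tagsets.items():
            write_tags(ts, outdir / f"tags_{mark}_{sample}.bed")
        write_cna_segments(self.cna_segments, outdir / "cna_segments.tsv")
        self.cq_table.to_csv(outdir / "cq_table.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")
        pd.DataFrame(
            [{"chrom": c, "length": l} for c, l in sorted(self.chrom_lengths.items())]
        ).to_csv(outdir / "chrom_lengths.tsv", sep="\t", index=False)


def generate_dataset(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_length_bp: int = 2_500_000,
    n_genes: int = 150,
    n_de: int = 30,
    n_candidates: int = 6,
    dispersion: float = 0.01,
    library_sizes: tuple[int, int] = (400_000, 400_000),
    qpcr_effect: float = 2.0,
    qpcr_noise_sd: float = 0.25,
) -> SyntheticDataset:
    """Generate the full toy study with planted, validated truth."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=5)
    genes = generate_genome(n_chrom, chrom_length_bp, n_genes, seed=int(sub[0]))
    chrom_lengths = {f"chr{i + 1}": chrom_length_bp for i in range(n_chrom)}

    cna = generate_cna(chrom_lengths, seed=int(sub[1]))
    # pick candidates outside lost regions and away from chromosome edges
    safe = [
        g for g in loss_free_genes(genes, cna)
        if g.interval.start > 8_000 and g.interval.end < chrom_length_bp - 8_000
    ]
    cand_rng = np.random.default_rng(int(sub[2]))
    candidates = sorted(
        g.gene_id for g in cand_rng.choice(np.array(safe, dtype=object),
                                           size=n_candidates, replace=False)
    )

    counts, de_truth = generate_expression(
        genes, n_de=n_de, dispersion=dispersion, library_sizes=library_sizes,
        seed=int(sub[3]), candidate_ids=candidates,
    )

    exon_lengths = {g.gene_id: g.exon_length_bp for g in genes}
    rpkm = {
        s: {
            g: counts.loc[g, s] * 1e9 / (exon_lengths[g] * counts[s].sum())
            for g in counts.index
        }
        for s in (TUMOR, NORMAL)
    }
    mean_rpkm = {g: (rpkm[TUMOR][g] + rpkm[NORMAL][g]) / 2 for g in counts.index}
    quartiles = {
        TUMOR: assign_quartiles(rpkm[TUMOR]),
        NORMAL: assign_quartiles(rpkm[NORMAL]),
        "mean": assign_quartiles(mean_rpkm),
    }

    tagsets, island_truth = generate_chip_tags(
        genes, quartiles, seed=int(sub[4]), chrom_lengths=chrom_lengths,
        candidate_ids=candidates,
    )

    qpcr_targets = {candidates[0]: qpcr_effect}
    cq = generate_qpcr(qpcr_targets, noise_sd=qpcr_noise_sd, seed=int(sub[4]))

    truth = TruthTable(
        de_genes=de_truth,
        candidate_genes=candidates,
        island_truth=island_truth,
        cna_truth=cna,
        qpcr_truth=qpcr_targets,
    )
    truth.validate(genes)
    return SyntheticDataset(genes, chrom_lengths, counts, tagsets, cna, cq, truth)
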