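"""End-to-end orchestration: expression -> islands -> profiles ->
copy-number bias -> candidate prioritization, driven by one config.

Every stage writes deterministic TSV outputs into the run directory and
a manifest records parameters, seeds and per-stage row counts so a rerun
with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cna_bias as cb
from . import expression as ex
from . import islands as isl
from . import prioritize as pri
from . import profiles as prof
from .genome_io import (
    read_cna_segments,
    read_count_table,
    read_cq_table,
    read_gene_models,
    read_tags,
)
from .synthetic import NORMAL, TUMOR, TruthTable, generate_dataset

logger = logging.getLogger(__name__)

MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "PolII")


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run."""

    data_dir: str
    output_dir: str
    seed: int = 0
    reference_sample: str = NORMAL
    rpkm_threshold: float = 1.0
    de_fdr: float = 0.05
    de_fold: float = 3.0
    window_bp: int = 200
    gap_bp: dict = field(default_factory=lambda: dict(isl.DEFAULT_GAP_BP))
    effective_genome_fraction: float = 0.81
    island_fdr: float = 0.001
    diff_fold: float = 3.0
    diff_fdr: float = 0.05
    profile_flank_bp: int = 5000
    profile_bin_bp: int = 25
    trim_alpha: float = 1e-5
    candidate_window_bp: int = 5000
    qpcr_housekeeping: tuple = ("HK1", "HK2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def make_demo(outdir: str | Path, seed: int = 0, **dataset_kwargs) -> RunConfig:
    """Write a synthetic dataset and a ready-to-run config under outdir."""
    outdir = Path(outdir)
    data_dir = outdir / "data"
    dataset = generate_dataset(seed=seed, **dataset_kwargs)
    dataset.write(data_dir)
    config = RunConfig(data_dir=str(data_dir), output_dir=str(outdir / "results"), seed=seed)
    config.to_yaml(outdir / "config.yaml")
    return config


def _load_inputs(config: RunConfig) -> dict:
    data = Path(config.data_dir)
    genes = read_gene_models(data / "genes.bed")
    counts = read_count_table(data / "counts.tsv")
    lengths = pd.read_csv(data / "chrom_lengths.tsv", sep="\t")
    chrom_lengths = dict(zip(lengths["chrom"], lengths["length"]))
    tagsets = {}
    for mark in MARKS + ("input",):
        for sample in (TUMOR, NORMAL):
            path = data / f"tags_{mark}_{sample}.bed"
            if path.exists():
                tagsets[(mark, sample)] = read_tags(path, mark, sample)
    cna_path = data / "cna_segments.tsv"
    cna = read_cna_segments(cna_path) if cna_path.exists() else None
    cq_path = data / "cq_table.tsv"
    cq = read_cq_table(cq_path) if cq_path.exists() else None
    truth_path = data / "truth.json"
    truth = TruthTable.from_json(truth_path) if truth_path.exists() else None
    return dict(genes=genes, counts=counts, chrom_lengths=chrom_lengths,
                tagsets=tagsets, cna=cna, cq=cq, truth=truth)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)
    genes = inputs["genes"]
    chrom_lengths = inputs["chrom_lengths"]
    tagsets = inputs["tagsets"]
    manifest: dict = {
        "config": asdict(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    # ---- expression ------------------------------------------------------
    exon_lengths = {g.gene_id: g.exon_length_bp for g in genes}
    de_table = ex.differential_expression(
        inputs["counts"], exon_lengths,
        sample_a=config.reference_sample, sample_b=TUMOR,
        rpkm_threshold=config.rpkm_threshold,
        fdr_alpha=config.de_fdr, fc_threshold=config.de_fold,
    )
    de_table.to_csv(outdir / "expression_de.tsv", sep="\t")
    manifest["stages"]["expression"] = {
        "n_tested": int(len(de_table)),
        "n_up": int((de_table["de_call"] == "up").sum()),
        "n_down": int((de_table["de_call"] == "down").sum()),
    }

    # ---- islands ---------------------------------------------------------
    sample_islands: dict[tuple[str, str], list] = {}
    differential: dict[str, list] = {}
    for mark in MARKS:
        params = isl.IslandParams(
            window_bp=config.window_bp,
            gap_bp=config.gap_bp.get(mark, 200),
            effective_genome_fraction=config.effective_genome_fraction,
            island_fdr=config.island_fdr,
            diff_fold=config.diff_fold,
            diff_fdr=config.diff_fdr,
        )
        for sample in (TUMOR, NORMAL):
            key = (mark, sample)
            if key not in tagsets:
                continue
            sample_islands[key] = isl.call_islands(
                tagsets[key], tagsets.get(("input", sample)), params, chrom_lengths
            )
        if (mark, TUMOR) in tagsets and (mark, NORMAL) in tagsets:
            differential[mark] = isl.differential_islands(
                tagsets[(mark, TUMOR)], tagsets[(mark, NORMAL)], params, chrom_lengths,
                input_a=tagsets.get(("input", TUMOR)), input_b=tagsets.get(("input", NORMAL)),
            )

    island_rows = []
    for (mark, sample), islands in sample_islands.items():
        annos = isl.annotate_islands(islands, genes)
        for island, anno in zip(islands, annos):
            island_rows.append({
                "mark": mark, "sample": sample, "chrom": island.interval.chrom,
                "start": island.interval.start, "end": island.interval.end,
                "chip_count": island.chip_count, "input_count": island.input_count,
                "enrichment": island.normalized_enrichment,
                "p_value": island.p_value, "fdr": island.fdr,
                "category": anno.category, "gene_id": anno.gene_id or "",
            })
    pd.DataFrame(island_rows).to_csv(outdir / "islands.tsv", sep="\t", index=False)

    diff_rows = []
    for mark, islands in differential.items():
        for d in islands:
            diff_rows.append({
                "mark": mark, "chrom": d.interval.chrom,
                "start": d.interval.start, "end": d.interval.end,
                "count_tumor": d.count_a, "count_normal": d.count_b,
                "readcount_tumor": d.readcount_a, "readcount_normal": d.readcount_b,
                "fold_change": d.fold_change, "p_value": d.p_value,
                "fdr": d.fdr, "direction": d.direction,
            })
    pd.DataFrame(diff_rows).to_csv(outdir / "differential_islands.tsv", sep="\t", index=False)
    summary = isl.summarize_differential(differential)
    summary.to_csv(outdir / "differential_summary.tsv", sep="\t", index=False)
    manifest["stages"]["islands"] = {
        "n_islands": int(len(island_rows)),
        "n_differential": int(len(diff_rows)),
        "summary": summary.to_dict(orient="records"),
    }

    # ---- profiles --------------------------------------------------------
    de = de_table
    rpkm_cols = {"tumor": "rpkm_b", "normal": "rpkm_a"}
    profile_counts = {}
    for mark in MARKS:
        for sample in (TUMOR, NORMAL):
            key = (mark, sample)
            if key not in tagsets:
                continue
            rpkm = de[rpkm_cols[sample]].to_dict()
            covered = [g for g in genes if g.gene_id in rpkm]
            quart = prof.assign_quartiles({g.gene_id: rpkm[g.gene_id] for g in covered})
            profs = prof.quartile_profiles(
                tagsets[key], covered, quart,
                flank_bp=config.profile_flank_bp, bin_bp=config.profile_bin_bp,
                trim_alpha=config.trim_alpha, chrom_lengths=chrom_lengths,
            )
            frame = prof.profiles_to_frame(profs)
            frame.to_csv(outdir / f"profile_{mark}_{sample}.tsv", sep="\t", index=False)
            profile_counts[f"{mark}_{sample}"] = int(len(frame))
    manifest["stages"]["profiles"] = profile_counts

    # ---- cna_bias --------------------------------------------------------
    if inputs["cna"] is not None:
        merged = cb.merge_cna(inputs["cna"])
        bias_report = {}
        for mark in ("PolII", "H3K27me3"):
            tumor_islands = sample_islands.get((mark, TUMOR), [])
            retained, n_excl, frac_excl = cb.exclude_lost(tumor_islands, merged)
            stats = cb.bias_test(retained, merged, chrom_lengths)
            bias_report[mark] = {
                "n_islands": len(tumor_islands),
                "n_excluded_in_loss": n_excl,
                "fraction_excluded": frac_excl,
                **stats,
            }
        with open(outdir / "cna_bias.json", "w") as fh:
            json.dump(bias_report, fh, indent=2)
        manifest["stages"]["cna_bias"] = bias_report
    else:
        logger.warning("no CNA segment file; cna_bias stage skipped")
        manifest["stages"]["cna_bias"] = "skipped"

    # ---- prioritize ------------------------------------------------------
    candidates = pri.select_candidates(
        de_table, differential.get("PolII", []), differential.get("H3K27me3", []),
        genes, window_bp=config.candidate_window_bp, fc=config.de_fold,
    )
    cand_frame = pri.candidates_to_frame(candidates)
    cand_frame.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    manifest["stages"]["prioritize"] = {"n_candidates": int(len(candidates))}

    if inputs["cq"] is not None:
        cq = inputs["cq"]
        hk = tuple(config.qpcr_housekeeping)
        targets = sorted(set(cq["assay"]) - set(hk))
        results = pri.qpcr_validation(cq, targets, hk, reference_group=NORMAL)
        qpcr_rows = [
            {"gene_id": r.gene_id, "group_fold_change": r.group_fold_change,
             "mann_whitney_p": r.mann_whitney_p}
            for r in results
        ]
        pd.DataFrame(qpcr_rows).to_csv(outdir / "qpcr_validation.tsv", sep="\t", index=False)
        manifest["stages"]["qpcr"] = qpcr_rows

    # ---- truth comparison ------------------------------------------------
    truth = inputs["truth"]
    if truth is not None:
        called_up = set(de[de["de_call"] == "up"].index) | set(de[de["de_call"] == "down"].index)
        planted = set(truth.de_genes)
        recovered = planted & called_up
        found_candidates = {c.gene_id for c in candidates}
        manifest["truth_recovery"] = {
            "de_sensitivity": len(recovered) / len(planted) if planted else float("nan"),
            "candidates_expected": sorted(truth.candidate_genes),
            "candidates_found": sorted(found_candidates),
            "candidate_recall": (
                len(found_candidates & set(truth.candidate_genes)) / len(truth.candidate_genes)
                if truth.candidate_genes else float("nan")
            ),
            "candidate_false_positives": sorted(found_candidates - set(truth.candidate_genes)),
            "pass": set(truth.candidate_genes) == found_candidates,
        }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
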