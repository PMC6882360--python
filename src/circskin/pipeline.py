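"""End-to-end orchestration: simulate -> detect -> quantify -> diff ->
iae -> nanostring -> integrate, with one configuration object, logging of
every threshold, and a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    bsj_detect,
    circ_quant,
    differential,
    iae_analysis,
    io_formats,
    mirna_integration,
    nanostring_norm,
    synthetic_data,
)

logger = logging.getLogger("circskin")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """All thresholds and switches, with the study's printed defaults."""

    seed: int = 0
    out_dir: str = "circskin_out"
    min_reads_single_sample: int = 2
    high_abundance_mean: float = 5.0
    fold_down_threshold: float = 0.5
    iae_window_any: int = 2300
    iae_window_same_subfamily: int = 10_000
    anchor_length: int = 20
    diagonal_band_log2: float = 1.0
    use_reads: bool = False  # detect from simulated reads vs count tables
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate",
            "detect",
            "quantify",
            "diff",
            "iae",
            "nanostring",
            "integrate",
        ]
    )
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "min_reads_single_sample",
            "high_abundance_mean",
            "iae_window_any",
            "iae_window_same_subfamily",
            "anchor_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the report bundle.

    Writes all stage outputs plus a manifest (seed, thresholds, output
    checksums) under ``config.out_dir``.  A stage whose inputs were not
    produced fails fast naming the missing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: %s", {
        "min_reads_single_sample": config.min_reads_single_sample,
        "high_abundance_mean": config.high_abundance_mean,
        "fold_down_threshold": config.fold_down_threshold,
        "iae_window_any": config.iae_window_any,
        "iae_window_same_subfamily": config.iae_window_same_subfamily,
        "anchor_length": config.anchor_length,
        "diagonal_band_log2": config.diagonal_band_log2,
    })
    bundle: dict = {"config": asdict(config)}
    state: dict = {}

    def require(key: str, producer: str):
        if key not in state:
            raise RuntimeError(
                f"stage requires output of {producer!r}, which did not run"
            )
        return state[key]

    if "simulate" in config.stages:
        sim_cfg = synthetic_data.SimulationConfig(
            seed=config.seed, **config.simulation
        )
        genome, annotation, repeats, truth = (
            synthetic_data.simulate_genome_annotation(sim_cfg)
        )
        counts = synthetic_data.simulate_counts(sim_cfg, truth)
        ns_circ, ns_mirna = synthetic_data.simulate_nanostring(sim_cfg, truth)
        state.update(
            genome=genome, annotation=annotation, repeats=repeats, truth=truth,
            counts=counts, ns_circ=ns_circ, ns_mirna=ns_mirna, sim_cfg=sim_cfg,
        )
        io_formats.write_fasta(out / "genome.fa", genome)
        io_formats.write_annotation(out / "annotation.gtf", annotation)
        io_formats.write_repeats_bed(out / "repeats.bed", repeats)
        io_formats.write_fasta(
            out / "mirnas.fa",
            {m: s.replace("U", "T") for m, s in truth.mirna_sequences.items()},
        )
        truth.to_json(out / "truth.json")
        for name, frame in (
            ("bsj_counts", counts.bsj),
            ("donor_linear_counts", counts.donor_linear),
            ("acceptor_linear_counts", counts.acceptor_linear),
            ("gene_counts", counts.genes),
            ("mirna_counts", counts.mirna),
        ):
            frame.to_csv(out / f"{name}.tsv", sep="\t")
        if config.use_reads:
            reads = synthetic_data.simulate_reads(
                sim_cfg, truth, counts, genome, annotation
            )
            state["reads"] = reads
            for sample, rs in reads.items():
                io_formats.write_fastq(out / f"reads_{sample}.fastq", rs)
        logger.info("simulate: %d circles, %d genes", len(truth.circs),
                    len(truth.gene_nl_means))

    if "detect" in config.stages and config.use_reads:
        reads = require("reads", "simulate")
        genome = require("genome", "simulate")
        annotation = require("annotation", "simulate")
        candidates = bsj_detect.detect_bsj(
            reads, genome, anchor_length=config.anchor_length
        )
        linear = bsj_detect.count_linear_junctions(
            reads, genome, annotation, candidates,
            anchor_length=config.anchor_length,
        )
        samples = list(require("counts", "simulate").bsj.columns)
        detected_bsj = pd.DataFrame(
            {c.id: c.supporting_reads for c in candidates}
        ).T.reindex(columns=samples).fillna(0)
        state["detected_bsj"] = detected_bsj
        state["detected_linear"] = linear
        detected_bsj.to_csv(out / "detected_bsj.tsv", sep="\t")
        logger.info("detect: %d candidates", len(candidates))

    if "quantify" in config.stages:
        counts = require("counts", "simulate")
        annotation = require("annotation", "simulate")
        records = circ_quant.build_records(
            counts.bsj.astype(float),
            counts.donor_linear.astype(float),
            counts.acceptor_linear.astype(float),
            counts.total_reads,
            counts.condition,
            annotation=annotation,
            high_abundance_mean=config.high_abundance_mean,
            min_reads_single_sample=config.min_reads_single_sample,
        )
        state["records"] = records
        frame = circ_quant.records_frame(records)
        frame.to_csv(out / "circ_quant.tsv", sep="\t")
        bundle["n_high_abundance"] = {
            cond: int(frame[f"high_abundance_{cond}"].sum())
            for cond in sorted(set(counts.condition))
        }
        logger.info("quantify: %s", bundle["n_high_abundance"])

    if "diff" in config.stages:
        counts = require("counts", "simulate")
        records = require("records", "quantify")
        high = [
            r.id for r in records
            if any(r.high_abundance.get(c, False) for c in set(counts.condition))
        ]
        # differential testing runs on size-factor-normalized BSJ counts:
        # factors come from the gene matrix (median of ratios), which is
        # robust to the global circRNA downregulation that would bias
        # total-count RPM toward the smaller lesional libraries
        factors, _ = differential.median_of_ratios_sizefactors(counts.genes)
        factors.to_csv(out / "gene_size_factors.tsv", sep="\t")
        normalized = counts.bsj.astype(float) / factors
        results = differential.per_feature_welch(
            normalized.loc[high], counts.condition
        )
        volcano = differential.diff_results_frame(results)
        volcano.to_csv(out / "volcano_circ.tsv", sep="\t")
        state["volcano"] = volcano
        means = volcano[["mean_lesional", "mean_non_lesional"]]
        global_test = differential.global_paired_wilcoxon(
            means["mean_lesional"], means["mean_non_lesional"]
        )
        sets = {
            cond: {r.id for r in records if r.high_abundance.get(cond, False)}
            for cond in sorted(set(counts.condition))
        }
        overlap = differential.overlap_stats(*sets.values())
        bundle["global_wilcoxon_p"] = global_test.p_value
        bundle["high_abundance_overlap"] = overlap
        bundle["n_significantly_down"] = int(
            ((volcano["p_value"] < 0.05) & (volcano["fold_change"] < 1)).sum()
        )
        logger.info("diff: %d significantly down, overlap %s",
                    bundle["n_significantly_down"], overlap["overlap_percent"])

    if "iae" in config.stages:
        repeats = require("repeats", "simulate")
        records = require("records", "quantify")
        volcano = require("volcano", "diff")
        high = [r for r in records if r.id in volcano.index]
        iae_report = {}
        for mode in (iae_analysis.MODE_ANY_2300,
                     iae_analysis.MODE_SAME_SUBFAMILY_10000):
            hits = {}
            flagged = {}
            for r in high:
                hit = iae_analysis.find_flanking_iae(
                    r.interval, repeats, mode=mode, circ_id=r.id
                )
                flagged[r.id] = hit is not None
                if hit is not None:
                    hits[r.id] = hit
            down = {
                r.id: bool(
                    volcano.loc[r.id, "fold_change"] < config.fold_down_threshold
                )
                for r in high
            }
            table, chi2 = iae_analysis.iae_association_test(flagged, down)
            dist, medians = iae_analysis.iae_distance_test(hits, down)
            iae_report[mode] = {
                "n_flagged": sum(flagged.values()),
                "table": table.to_dict(),
                "chi2": chi2.statistic,
                "chi2_p": chi2.p_value,
                "distance_p": dist.p_value,
                **medians,
            }
        bundle["iae"] = iae_report
        logger.info("iae: %s", {m: v["n_flagged"] for m, v in iae_report.items()})

    if "nanostring" in config.stages:
        ns_circ = require("ns_circ", "simulate")
        ns_mirna = require("ns_mirna", "simulate")
        truth = require("truth", "simulate")
        circ_norm, _ = nanostring_norm.normalize_chain(ns_circ)
        circ_norm.counts.to_csv(out / "nanostring_circ_normalized.tsv", sep="\t")
        stage1 = nanostring_norm.background_subtract(ns_mirna, floor=1.0)
        stage2, _ = nanostring_norm.positive_control_normalize(stage1)
        candidates = [
            p for p in stage2.probes_of("endogenous")
            if (stage2.counts.loc[p] > 1).all()
        ]
        stability = nanostring_norm.normfinder(stage2, candidates=candidates)
        mirna_norm = nanostring_norm.reference_normalize(
            stage2, reference_ids=list(stability.best_pair)
        )
        mirna_norm.counts.to_csv(out / "nanostring_mirna_normalized.tsv", sep="\t")
        state["mirna_norm"] = mirna_norm
        bundle["normfinder_best_pair"] = list(stability.best_pair)
        bundle["normfinder_pair_is_designated"] = (
            stability.best_pair == tuple(sorted(truth.designated_stable_pair))
        )
        logger.info("nanostring: best pair %s", stability.best_pair)

    if "integrate" in config.stages:
        truth = require("truth", "simulate")
        genome = require("genome", "simulate")
        annotation = require("annotation", "simulate")
        records = require("records", "quantify")
        mirna_norm = require("mirna_norm", "nanostring")
        conds = sorted(set(require("counts", "simulate").condition))
        high = [
            r for r in records
            if any(r.high_abundance.get(c, False) for c in conds)
            and r.annotated_splice_consistent
        ]
        sequences = {
            r.id: mirna_integration.assemble_circ_sequence(
                r.interval, annotation, genome, circ_id=r.id
            )
            for r in high
        }
        mirna_ids = [
            m for m in truth.mirna_sequences if m in mirna_norm.counts.index
        ]
        site_table = mirna_integration.site_count_table(
            {m: truth.mirna_sequences[m] for m in mirna_ids}, sequences
        )
        delta = pd.Series(
            {
                r.id: r.mean_rpm[synthetic_data.LESIONAL]
                - r.mean_rpm[synthetic_data.NON_LESIONAL]
                for r in high
            }
        )
        scores = mirna_integration.sponge_scores(site_table, delta)
        norm_counts = mirna_norm.counts.loc[mirna_ids]
        les_cols = [
            s for s in norm_counts.columns
            if mirna_norm.condition[s] == synthetic_data.LESIONAL
        ]
        nl_cols = [c for c in norm_counts.columns if c not in les_cols]
        fc = norm_counts[les_cols].mean(axis=1) / norm_counts[nl_cols].mean(axis=1)
        diff = norm_counts[les_cols].mean(axis=1) - norm_counts[nl_cols].mean(axis=1)
        regressions = mirna_integration.score_vs_expression_regression(
            scores, fc, diff
        )
        score_frame = pd.DataFrame(
            [(s.mirna, s.total_sites, s.score) for s in scores],
            columns=["mirna", "total_sites", "sponge_score"],
        ).set_index("mirna")
        score_frame.to_csv(out / "sponge_scores.tsv", sep="\t")
        bundle["sponge_regression"] = {
            model: {
                "slope": res.slope,
                "slope_se": res.slope_se,
                "slope_ci95": list(res.slope_ci95()),
                "r_squared": res.r_squared,
                "f_p_value": res.p_value,
                "n": res.n,
            }
            for model, res in regressions.items()
        }
        logger.info("integrate: %s", bundle["sponge_regression"])

    manifest = {
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if k not in ("stages", "simulation", "out_dir")
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "report.json")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    bundle["manifest"] = manifest
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    return bundle
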