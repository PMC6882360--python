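"""Quantitative circRNA descriptors: RPM, circular-to-linear ratio,
detection and high-abundance classes, and annotation-derived features.

RPM is backsplice-spanning reads per million total reads in the sample.
The circular-to-linear (CTL) ratio divides the backsplice count by the
average of the linear reads spanning the donor and acceptor splice sites
of the same junction, plus one pseudo count so the ratio is always finite.
A circRNA is "high abundance" in a condition when its mean backsplice
count over that condition's samples is at least ``high_abundance_mean``
reads (default 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AnnotationSet, GenomicInterval, Transcript, circ_id

__all__ = [
    "CircRecord",
    "compute_rpm",
    "compute_ctl",
    "classify_abundance",
    "choose_host_transcript",
    "annotate_circ",
    "build_records",
    "records_frame",
    "host_gene_histogram",
    "top_abundant",
    "HIGH_ABUNDANCE_MEAN",
]

HIGH_ABUNDANCE_MEAN = 5.0


def compute_rpm(bsj_count: float, total_reads: float) -> float:
    """Backsplice reads per million total reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return bsj_count / total_reads * 1e6


def compute_ctl(bsj_count: float, donor_linear: float, acceptor_linear: float) -> float:
    """Circular-to-linear ratio with a single pseudo count.

    ctl = bsj / ((donor + acceptor)/2 + 1); the pseudo count keeps the
    ratio finite for circle-only loci.
    """
    if bsj_count < 0 or donor_linear < 0 or acceptor_linear < 0:
        raise ValueError("counts must be non-negative")
    return bsj_count / ((donor_linear + acceptor_linear) / 2.0 + 1.0)


@dataclass
class CircRecord:
    """All per-circRNA quantities the downstream analyses consume."""

    interval: GenomicInterval
    bsj_count: dict[str, float]
    donor_linear: dict[str, float]
    acceptor_linear: dict[str, float]
    total_reads: dict[str, float]
    rpm: dict[str, float] = field(default_factory=dict)
    ctl: dict[str, float] = field(default_factory=dict)
    mean_rpm: dict[str, float] = field(default_factory=dict)  # per condition
    mean_ctl: dict[str, float] = field(default_factory=dict)
    mean_bsj: dict[str, float] = field(default_factory=dict)
    high_abundance: dict[str, bool] = field(default_factory=dict)
    detected: dict[str, bool] = field(default_factory=dict)
    ctl_above_one: dict[str, bool] = field(default_factory=dict)
    host_gene: str = ""
    host_transcript: str = ""
    n_exons_annotated: int = 0
    annotated_splice_consistent: bool = False

    @property
    def id(self) -> str:
        return circ_id(self.interval)


def classify_abundance(
    record: CircRecord,
    condition: dict[str, str] | pd.Series,
    high_abundance_mean: float = HIGH_ABUNDANCE_MEAN,
    min_reads_single_sample: int = 2,
) -> CircRecord:
    """Fill detection and high-abundance flags per condition (in place)."""
    samples_by_condition: dict[str, list[str]] = {}
    for sample in record.bsj_count:
        samples_by_condition.setdefault(condition[sample], []).append(sample)
    for cond, samples in samples_by_condition.items():
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        counts = [record.bsj_count[s] for s in samples]
        record.mean_bsj[cond] = sum(counts) / len(counts)
        record.high_abundance[cond] = record.mean_bsj[cond] >= high_abundance_mean
        record.detected[cond] = any(c >= min_reads_single_sample for c in counts)
        record.mean_rpm[cond] = sum(record.rpm[s] for s in samples) / len(samples)
        record.mean_ctl[cond] = sum(record.ctl[s] for s in samples) / len(samples)
        record.ctl_above_one[cond] = record.mean_ctl[cond] > 1.0
    return record


def choose_host_transcript(
    interval: GenomicInterval, annotation: AnnotationSet
) -> Transcript | None:
    """Host transcript: most exons fully inside the BSJ span; ties by
    longest spliced length.  Falls back to any transcript overlapping the
    span when none has a contained exon."""
    best: Transcript | None = None
    best_key = (-1, -1)
    for tx in annotation:
        if tx.chrom != interval.chrom:
            continue
        contained = [
            e for e in tx.exons if e.start >= interval.start and e.end <= interval.end
        ]
        span_overlap = tx.exons[0].start < interval.end and tx.exons[-1].end > interval.start
        if not contained and not span_overlap:
            continue
        key = (len(contained), tx.spliced_length)
        if key > best_key:
            best_key = key
            best = tx
    return best


def annotate_circ(record: CircRecord, annotation: AnnotationSet) -> CircRecord:
    """Host gene, contained-exon count and splice-consistency flag.

    A circRNA is splice-consistent when both backsplice ends coincide with
    annotated exon boundaries of a single transcript: an exon starting at
    the acceptor and an exon ending at the donor.
    """
    interval = record.interval
    consistent_tx: list[Transcript] = []
    for tx in annotation:
        if tx.chrom != interval.chrom or tx.strand != interval.strand:
            continue
        has_start = any(e.start == interval.start for e in tx.exons)
        has_end = any(e.end == interval.end for e in tx.exons)
        if has_start and has_end:
            consistent_tx.append(tx)
    host = choose_host_transcript(interval, annotation)
    if consistent_tx:
        # among consistent transcripts apply the same preference rule
        host = max(
            consistent_tx,
            key=lambda tx: (
                sum(
                    1
                    for e in tx.exons
                    if e.start >= interval.start and e.end <= interval.end
                ),
                tx.spliced_length,
            ),
        )
        record.annotated_splice_consistent = True
    else:
        record.annotated_splice_consistent = False
    if host is not None:
        record.host_gene = host.gene_id
        record.host_transcript = host.transcript_id
        record.n_exons_annotated = sum(
            1 for e in host.exons if e.start >= interval.start and e.end <= interval.end
        )
    else:
        record.host_gene = ""
        record.host_transcript = ""
        record.n_exons_annotated = 0
    return record


def build_records(
    bsj: pd.DataFrame,
    donor_linear: pd.DataFrame,
    acceptor_linear: pd.DataFrame,
    total_reads: pd.Series,
    condition: pd.Series,
    annotation: AnnotationSet | None = None,
    high_abundance_mean: float = HIGH_ABUNDANCE_MEAN,
    min_reads_single_sample: int = 2,
) -> list[CircRecord]:
    """Assemble CircRecords from circ x sample count tables.

    Tables are indexed by circRNA identifier ("chrom:start|end:strand");
    ``total_reads`` gives each sample's library size.
    """
    from .io_formats import parse_circ_id

    records = []
    for cid in bsj.index:
        interval = parse_circ_id(str(cid))
        record = CircRecord(
            interval=interval,
            bsj_count={s: float(bsj.loc[cid, s]) for s in bsj.columns},
            donor_linear={s: float(donor_linear.loc[cid, s]) for s in bsj.columns},
            acceptor_linear={
                s: float(acceptor_linear.loc[cid, s]) for s in bsj.columns
            },
            total_reads={s: float(total_reads[s]) for s in bsj.columns},
        )
        for s in bsj.columns:
            record.rpm[s] = compute_rpm(record.bsj_count[s], record.total_reads[s])
            record.ctl[s] = compute_ctl(
                record.bsj_count[s], record.donor_linear[s], record.acceptor_linear[s]
            )
        classify_abundance(
            record, condition, high_abundance_mean, min_reads_single_sample
        )
        if annotation is not None:
            annotate_circ(record, annotation)
        records.append(record)
    return records


def records_frame(records: list[CircRecord]) -> pd.DataFrame:
    """Flat per-circRNA table (one row per circ, per-condition summaries)."""
    rows = []
    for r in records:
        row: dict = {
            "circ_id": r.id,
            "host_gene": r.host_gene,
            "host_transcript": r.host_transcript,
            "n_exons_annotated": r.n_exons_annotated,
            "annotated_splice_consistent": r.annotated_splice_consistent,
        }
        for cond in sorted(r.mean_rpm):
            row[f"mean_rpm_{cond}"] = r.mean_rpm[cond]
            row[f"mean_ctl_{cond}"] = r.mean_ctl[cond]
            row[f"mean_bsj_{cond}"] = r.mean_bsj[cond]
            row[f"high_abundance_{cond}"] = r.high_abundance[cond]
            row[f"detected_{cond}"] = r.detected[cond]
            row[f"ctl_above_one_{cond}"] = r.ctl_above_one[cond]
        rows.append(row)
    return pd.DataFrame(rows).set_index("circ_id")


def host_gene_histogram(records: list[CircRecord], condition: str) -> pd.Series:
    """Circles-per-host-gene counts among high-abundance circRNAs.

    A gene hosting two circles contributes one histogram entry with value
    2.  Returns gene -> number of unique circRNAs.
    """
    counts: dict[str, int] = {}
    for r in records:
        if r.high_abundance.get(condition) and r.host_gene:
            counts[r.host_gene] = counts.get(r.host_gene, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def top_abundant(records: list[CircRecord], n: int = 50) -> list[CircRecord]:
    """Top-n circRNAs ranked by mean RPM over all samples."""

    def overall_rpm(r: CircRecord) -> float:
        return sum(r.rpm.values()) / len(r.rpm)

    return sorted(records, key=overall_rpm, reverse=True)[:n]
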