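"""circRNA-miRNA sponge integration.

Mature circRNA sequences are assembled from the host transcript's exons
inside the backsplice span (the circle inherits the host's splicing
pattern).  Canonical 8mer target sites — an exact match to the reverse
complement of miRNA positions 2-8 followed by an 'A' — are counted with
circular topology, so sites spanning the backsplice junction are found.
Each miRNA's sponge score sums, over the high-abundance circRNAs carrying
its sites, site count x ΔRPM (mean RPM lesional minus non-lesional); the
scores are regressed against miRNA fold changes and absolute expression
differences with an F test for a non-zero slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .circ_quant import choose_host_transcript
from .differential import RegressionResult, ols_regression
from .io_formats import AnnotationSet, GenomicInterval

__all__ = [
    "MatureCircSequence",
    "SpongeScore",
    "assemble_circ_sequence",
    "eightmer_motif",
    "count_sites_circular",
    "site_count_table",
    "sponge_scores",
    "score_vs_expression_regression",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MatureCircSequence:
    """Spliced exonic circle sequence, 5'->3' on the annotated strand."""

    circ_id: str
    sequence: str
    n_exons: int

    def __len__(self) -> int:
        return len(self.sequence)


def assemble_circ_sequence(
    interval: GenomicInterval,
    annotation: AnnotationSet,
    genome: dict[str, str],
    circ_id: str = "",
) -> MatureCircSequence:
    """Concatenate the host transcript's exons inside the backsplice span.

    The host is chosen by the standard rule (most contained exons, ties by
    spliced length) among transcripts whose exon boundaries match both
    backsplice ends; minus-strand circles are reverse complemented so the
    output is the transcript-sense sequence.  Raises for circles without
    an annotated model.
    """
    candidates = [
        tx
        for tx in annotation
        if tx.chrom == interval.chrom
        and tx.strand == interval.strand
        and any(e.start == interval.start for e in tx.exons)
        and any(e.end == interval.end for e in tx.exons)
    ]
    if not candidates:
        raise ValueError(
            f"no annotated model for circle {interval.chrom}:"
            f"{interval.start}|{interval.end}"
        )
    host = choose_host_transcript(interval, annotation)
    if host not in candidates:
        host = max(
            candidates,
            key=lambda tx: (
                sum(
                    1
                    for e in tx.exons
                    if e.start >= interval.start and e.end <= interval.end
                ),
                tx.spliced_length,
            ),
        )
    exons = [
        e for e in host.exons if e.start >= interval.start and e.end <= interval.end
    ]
    chrom_seq = genome[interval.chrom]
    forward = "".join(chrom_seq[e.start : e.end] for e in exons)
    sequence = forward if interval.strand == "+" else _revcomp(forward)
    return MatureCircSequence(circ_id=circ_id, sequence=sequence, n_exons=len(exons))


def eightmer_motif(mirna_sequence: str) -> str:
    """8mer target motif: revcomp of miRNA positions 2-8, then 'A'.

    The miRNA may be given in RNA (U) or DNA (T) alphabet; the motif is in
    the DNA target alphabet.
    """
    seq = mirna_sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    return _revcomp(seq[1:8]) + "A"


def count_sites_circular(motif: str, sequence: str) -> int:
    """Occurrences of the motif in the circular sequence.

    The sequence is treated as a circle: the scan wraps across the
    backsplice junction by appending the first len(motif)-1 characters.
    Overlapping occurrences each count; every circular start position
    counts once.
    """
    if not sequence:
        raise ValueError("empty sequence")
    extended = sequence + sequence[: len(motif) - 1]
    count = 0
    for i in range(len(sequence)):
        if extended[i : i + len(motif)] == motif:
            count += 1
    return count


def count_sites_linear(motif: str, sequence: str) -> int:
    """Linear-only variant of the scan (no junction wrap)."""
    count = 0
    start = 0
    while True:
        idx = sequence.find(motif, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def site_count_table(
    mirnas: dict[str, str],
    circ_sequences: dict[str, MatureCircSequence],
    circular: bool = True,
) -> pd.DataFrame:
    """miRNA x circRNA table of 8mer site counts."""
    scan = count_sites_circular if circular else count_sites_linear
    data = {
        cid: {
            mid: scan(eightmer_motif(mseq), circ.sequence)
            for mid, mseq in mirnas.items()
        }
        for cid, circ in circ_sequences.items()
    }
    return pd.DataFrame(data).sort_index()


@dataclass
class SpongeScore:
    mirna: str
    total_sites: int
    score: float  # sum over circles of sites x ΔRPM


def sponge_scores(
    site_counts: pd.DataFrame, delta_rpm: pd.Series
) -> list[SpongeScore]:
    """Per-miRNA sponge scores over the supplied (high-abundance) circRNAs.

    ``site_counts`` is miRNA x circRNA; ``delta_rpm`` maps circ id to mean
    RPM (lesional) - mean RPM (non-lesional).  miRNAs with zero sites
    everywhere are reported with score 0 and excluded from regressions by
    the caller.
    """
    common = [c for c in site_counts.columns if c in delta_rpm.index]
    scores = []
    for mirna in site_counts.index:
        sites = site_counts.loc[mirna, common]
        total = int(sites.sum())
        score = float((sites * delta_rpm[common]).sum())
        scores.append(SpongeScore(str(mirna), total, score))
    return scores


def score_vs_expression_regression(
    scores: list[SpongeScore],
    mirna_fold_change: pd.Series,
    mirna_abs_difference: pd.Series,
) -> dict[str, RegressionResult]:
    """Regress miRNA expression changes on sponge scores (two models).

    miRNAs without any site are excluded.  Returns the fold-change model
    and the absolute-difference model, each with slope, R² and the F-test
    p for a non-zero slope.
    """
    with_sites = [s for s in scores if s.total_sites > 0]
    usable = [s for s in with_sites if s.mirna in mirna_fold_change.index]
    if len(usable) < 3:
        raise ValueError("need at least 3 miRNAs with sites for regression")
    x = [s.score for s in usable]
    fc = [float(mirna_fold_change[s.mirna]) for s in usable]
    diff = [float(mirna_abs_difference[s.mirna]) for s in usable]
    return {
        "fold_change": ols_regression(x, fc),
        "abs_difference": ols_regression(x, diff),
    }
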