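"""Anchor-based backsplice-junction detection and linear junction counting.

The detector follows the published anchor scheme in a form suited to a
small, fully specified genome: the two terminal anchors of each read are
placed by exact match with a k-mer dictionary; anchors that land on one
chromosome in reversed genomic order delimit a backsplice candidate, and
the anchors are extended toward each other to enumerate every breakpoint
that explains the full read.  A candidate is kept only when a canonical
GT/AG splice signal frames the junction (strand-aware), the breakpoint is
placed at most ``max_ambiguity`` equivalent ways, and both anchors are
unique.  Colinear anchor placements with a gap are resolved the same way
and matched against annotated splice junctions to count linear
donor/acceptor support for each backsplice.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AnnotationSet, GenomicInterval, circ_id

__all__ = [
    "BsjCandidate",
    "LinearJunctionCounts",
    "KmerIndex",
    "detect_bsj",
    "count_linear_junctions",
    "filter_detected",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MIN_ANCHOR = 12
DEFAULT_ANCHOR = 20
DEFAULT_MAX_SPAN = 100_000
DEFAULT_MAX_AMBIGUITY = 2


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BsjCandidate:
    """One backsplice junction with per-sample read support."""

    interval: GenomicInterval
    supporting_reads: dict[str, int] = field(default_factory=dict)
    splice_signal_ok: bool = True
    breakpoint_ambiguity: int = 1
    anchors_unique: bool = True

    @property
    def id(self) -> str:
        return circ_id(self.interval)

    def total_reads(self) -> int:
        return sum(self.supporting_reads.values())


@dataclass
class LinearJunctionCounts:
    """Per-BSJ linear donor-side and acceptor-side junction reads."""

    donor: dict[str, dict[str, int]] = field(default_factory=dict)  # circ -> sample -> n
    acceptor: dict[str, dict[str, int]] = field(default_factory=dict)


class KmerIndex:
    """Exact-match k-mer positions over the forward strand of a genome."""

    def __init__(self, genome: dict[str, str], k: int):
        if k < MIN_ANCHOR:
            raise ValueError(
                f"anchor length {k} below reliable-uniqueness minimum {MIN_ANCHOR}"
            )
        self.k = k
        self.genome = genome
        # cap stored hits: > 2 placements already disqualifies an anchor
        positions: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                hits = positions[seq[i : i + k]]
                if len(hits) < 3:
                    hits.append((chrom, i))
        self.positions = dict(positions)

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.positions.get(kmer, [])


def _enumerate_breakpoints(seq, genome_seq, head_pos, tail_pos, anchor):
    """All split positions b where seq[:b] ends at head_pos+b and seq[b:]
    ends at tail_pos+anchor, each matching the genome exactly."""
    length = len(seq)
    valid = []
    for b in range(anchor, length - anchor + 1):
        e1 = head_pos + b  # first segment occupies [head_pos, e1)
        s2 = tail_pos + anchor - (length - b)  # second segment [s2, tail_pos+anchor)
        if s2 < 0 or e1 > len(genome_seq) or tail_pos + anchor > len(genome_seq):
            continue
        if genome_seq[head_pos:e1] == seq[:b] and genome_seq[s2 : tail_pos + anchor] == seq[b:]:
            valid.append((e1, s2))
    return valid


def _splice_signal_strand(genome_seq: str, acceptor: int, donor: int) -> str | None:
    """Strand of a backsplice framed by canonical signals, or None.

    Forward circles show AG just left of the acceptor and GT just right of
    the donor; reverse circles show AC and CT at the same genomic
    positions (the reverse complement read on the other strand).
    """
    left = genome_seq[max(0, acceptor - 2) : acceptor]
    right = genome_seq[donor : donor + 2]
    if left == "AG" and right == "GT":
        return "+"
    if left == "AC" and right == "CT":
        return "-"
    return None


@dataclass
class _ReadPlacement:
    kind: str  # "backsplice" | "colinear"
    interval: GenomicInterval | None = None
    ambiguity: int = 0
    signal_ok: bool = False
    anchors_unique: bool = True
    junctions: list[tuple[str, int, int]] = field(default_factory=list)


def _place_read(read: str, index: KmerIndex, anchor: int,
                max_span: int) -> _ReadPlacement | None:
    """Classify one read as backsplice, colinear-spliced, or unplaced."""
    for seq in (read, revcomp(read)):
        if len(seq) < 2 * anchor:
            return None
        head_hits = index.lookup(seq[:anchor])
        tail_hits = index.lookup(seq[-anchor:])
        if not head_hits or not tail_hits:
            continue
        unique = len(head_hits) == 1 and len(tail_hits) == 1
        if not unique:
            # stringent mode: multi-mapping anchors are never extended
            return _ReadPlacement("backsplice", anchors_unique=False)
        (hc, hp), (tc, tp) = head_hits[0], tail_hits[0]
        if hc != tc:
            continue
        genome_seq = index.genome[hc]
        length = len(seq)
        if tp >= hp + length - anchor:
            # colinear order with a (possibly zero) gap
            breakpoints = _enumerate_breakpoints(seq, genome_seq, hp, tp, anchor)
            junctions = [
                (hc, e1, s2) for e1, s2 in breakpoints if s2 > e1
            ]
            return _ReadPlacement("colinear", junctions=junctions)
        if tp < hp:
            # reversed order: backsplice geometry
            breakpoints = _enumerate_breakpoints(seq, genome_seq, hp, tp, anchor)
            if not breakpoints:
                continue
            chosen = None
            for e1, s2 in breakpoints:  # e1 = donor end, s2 = acceptor start
                if s2 >= e1 or e1 - s2 > max_span:
                    continue
                strand = _splice_signal_strand(genome_seq, s2, e1)
                if strand is not None and chosen is None:
                    chosen = GenomicInterval(hc, s2, e1, strand)
            return _ReadPlacement(
                "backsplice",
                interval=chosen,
                ambiguity=len(breakpoints),
                signal_ok=chosen is not None,
            )
    return None


def detect_bsj(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: dict[str, str],
    anchor_length: int = DEFAULT_ANCHOR,
    max_span: int = DEFAULT_MAX_SPAN,
    max_ambiguity: int = DEFAULT_MAX_AMBIGUITY,
    index: KmerIndex | None = None,
) -> list[BsjCandidate]:
    """Detect backsplice junctions from per-sample reads.

    Returns one candidate per junction with per-sample supporting read
    counts, sorted by genomic position.  Only reads passing every
    stringency gate (unique anchors, canonical splice signal, breakpoint
    ambiguity <= ``max_ambiguity``) contribute.
    """
    if index is None:
        index = KmerIndex(genome, anchor_length)
    candidates: dict[GenomicInterval, BsjCandidate] = {}
    for sample in sorted(reads_by_sample):
        for _name, read in reads_by_sample[sample]:
            placement = _place_read(read, index, anchor_length, max_span)
            if placement is None or placement.kind != "backsplice":
                continue
            if (
                placement.interval is None
                or not placement.signal_ok
                or not placement.anchors_unique
                or placement.ambiguity > max_ambiguity
            ):
                continue
            cand = candidates.get(placement.interval)
            if cand is None:
                cand = BsjCandidate(
                    placement.interval,
                    supporting_reads={s: 0 for s in reads_by_sample},
                    breakpoint_ambiguity=placement.ambiguity,
                )
                candidates[placement.interval] = cand
            cand.supporting_reads[sample] += 1
            cand.breakpoint_ambiguity = max(
                cand.breakpoint_ambiguity, placement.ambiguity
            )
    return sorted(candidates.values(), key=lambda c: c.interval)


def _bsj_side_junctions(interval: GenomicInterval, annotation: AnnotationSet):
    """Annotated junctions sharing the BSJ's donor or acceptor coordinate.

    On '+' the donor is interval.end and the acceptor interval.start; on
    '-' the two swap.  Returns (donor_side, acceptor_side) sets of
    (chrom, donor_end, acceptor_start) genomic junctions.
    """
    donor_side: set[tuple[str, int, int]] = set()
    acceptor_side: set[tuple[str, int, int]] = set()
    for tx in annotation:
        if tx.chrom != interval.chrom or tx.strand != interval.strand:
            continue
        for e1, s2 in tx.splice_junctions():
            key = (tx.chrom, e1, s2)
            if interval.strand == "+":
                if e1 == interval.end:
                    donor_side.add(key)
                if s2 == interval.start:
                    acceptor_side.add(key)
            else:
                if s2 == interval.start:
                    donor_side.add(key)
                if e1 == interval.end:
                    acceptor_side.add(key)
    return donor_side, acceptor_side


def count_linear_junctions(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    genome: dict[str, str],
    annotation: AnnotationSet,
    bsj_list: list[BsjCandidate],
    anchor_length: int = DEFAULT_ANCHOR,
    index: KmerIndex | None = None,
) -> LinearJunctionCounts:
    """Count colinear reads spanning the splice donor / acceptor of each BSJ.

    A read counts for the donor side of a BSJ iff one of its breakpoint
    placements coincides with an annotated splice junction whose donor
    equals the BSJ donor (symmetric for the acceptor); each read counts at
    most once per side.
    """
    if index is None:
        index = KmerIndex(genome, anchor_length)
    side_map = {c.id: _bsj_side_junctions(c.interval, annotation) for c in bsj_list}
    counts = LinearJunctionCounts(
        donor={c.id: {s: 0 for s in reads_by_sample} for c in bsj_list},
        acceptor={c.id: {s: 0 for s in reads_by_sample} for c in bsj_list},
    )
    # aggregate junction-spanning reads once, then attribute to BSJs
    junction_hits: dict[str, dict[tuple[str, int, int], int]] = {
        s: defaultdict(int) for s in reads_by_sample
    }
    for sample, reads in reads_by_sample.items():
        for _name, read in reads:
            placement = _place_read(read, index, anchor_length, max_span=10**9)
            if placement is None or placement.kind != "colinear":
                continue
            for junction in set(placement.junctions):
                junction_hits[sample][junction] += 1
    for cand in bsj_list:
        donor_side, acceptor_side = side_map[cand.id]
        for sample in reads_by_sample:
            hits = junction_hits[sample]
            counts.donor[cand.id][sample] = sum(
                hits.get(j, 0) for j in donor_side
            )
            counts.acceptor[cand.id][sample] = sum(
                hits.get(j, 0) for j in acceptor_side
            )
    return counts


def filter_detected(
    candidates: list[BsjCandidate] | pd.DataFrame,
    condition: dict[str, str] | pd.Series,
    min_reads_single_sample: int = 2,
) -> dict[str, set[str]]:
    """Detection call per condition: some single sample has >= the minimum.

    Accepts either detector output or a circ x sample count table.
    Returns {condition: set of circ ids detected in that condition}.
    """
    if isinstance(candidates, pd.DataFrame):
        table = candidates
    else:
        table = pd.DataFrame(
            {c.id: c.supporting_reads for c in candidates}
        ).T.fillna(0)
    detected: dict[str, set[str]] = {}
    for sample in table.columns:
        cond = condition[sample]
        detected.setdefault(cond, set())
    for cid, row in table.iterrows():
        for sample, count in row.items():
            if count >= min_reads_single_sample:
                detected[condition[sample]].add(str(cid))
    return detected
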