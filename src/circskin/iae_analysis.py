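"""Inverted Alu element (IAE) analysis around backsplice junctions.

Oppositely oriented Alu repeats in the introns flanking a backsplice
junction can base-pair and promote backsplicing.  Two search modes are
supported: any inverted Alu pair with a total flanking distance of at most
2300 nt, and pairs from the same Alu subfamily within a total distance of
10,000 nt.  "Total distance" is the sum of the two flank gaps:
(circ.start - upstream.end) + (downstream.start - circ.end).  Association
with >2-fold downregulation is tested with Pearson chi-squared (no
continuity correction) and flank distances are compared with a two-sided
Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .differential import TestResult, chi2_independence, mann_whitney_u
from .io_formats import GenomicInterval, RepeatFeature

__all__ = [
    "IaeHit",
    "MODE_ANY_2300",
    "MODE_SAME_SUBFAMILY_10000",
    "find_flanking_iae",
    "iae_association_test",
    "iae_distance_test",
]

MODE_ANY_2300 = "any_2300"
MODE_SAME_SUBFAMILY_10000 = "same_subfamily_10000"
_WINDOWS = {MODE_ANY_2300: 2300, MODE_SAME_SUBFAMILY_10000: 10_000}


@dataclass
class IaeHit:
    """Nearest qualifying inverted Alu pair flanking one backsplice."""

    circ_id: str
    upstream: RepeatFeature
    downstream: RepeatFeature
    total_distance: int
    same_subfamily: bool
    mode: str


def find_flanking_iae(
    circ: GenomicInterval,
    repeats: list[RepeatFeature],
    mode: str = MODE_ANY_2300,
    circ_id: str = "",
) -> IaeHit | None:
    """Nearest inverted Alu pair flanking a backsplice junction.

    Only Alu elements fully outside the circle count (an element inside
    cannot base-pair across the flanks).  A qualifying pair has one
    element upstream, one downstream, on opposite strands, equal
    subfamily in same-subfamily mode, and minimal total distance within
    the mode's window.  Ties break toward the smaller upstream gap.
    """
    if mode not in _WINDOWS:
        raise ValueError(f"unknown mode {mode!r}; expected {sorted(_WINDOWS)}")
    window = _WINDOWS[mode]
    upstream = [
        r
        for r in repeats
        if r.is_alu and r.interval.chrom == circ.chrom and r.interval.end <= circ.start
    ]
    downstream = [
        r
        for r in repeats
        if r.is_alu and r.interval.chrom == circ.chrom and r.interval.start >= circ.end
    ]
    best: tuple[int, int, RepeatFeature, RepeatFeature] | None = None
    for up in upstream:
        gap_up = circ.start - up.interval.end
        if gap_up > window:
            continue
        for down in downstream:
            if down.interval.strand == up.interval.strand:
                continue  # not inverted
            if mode == MODE_SAME_SUBFAMILY_10000 and down.subfamily != up.subfamily:
                continue
            gap_down = down.interval.start - circ.end
            total = gap_up + gap_down
            if total > window:
                continue
            key = (total, gap_up, up, down)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is None:
        return None
    total, _gap_up, up, down = best
    return IaeHit(
        circ_id=circ_id,
        upstream=up,
        downstream=down,
        total_distance=total,
        same_subfamily=up.subfamily == down.subfamily,
        mode=mode,
    )


def iae_association_test(
    flagged: dict[str, bool], downregulated: dict[str, bool]
) -> tuple[pd.DataFrame, TestResult]:
    """2x2 association between IAE flanking and >2-fold downregulation.

    Rows: downregulated yes/no; columns: IAE-flanked yes/no.  Pearson
    chi-squared without continuity correction; a zero marginal yields a
    degenerate result rather than a p value.
    """
    ids = sorted(flagged)
    missing = [i for i in ids if i not in downregulated]
    if missing:
        raise ValueError(f"circRNAs without downregulation class: {missing[:3]}")
    table = pd.DataFrame(
        0,
        index=["down_gt2fold", "not_down"],
        columns=["iae", "no_iae"],
    )
    for cid in ids:
        row = "down_gt2fold" if downregulated[cid] else "not_down"
        col = "iae" if flagged[cid] else "no_iae"
        table.loc[row, col] += 1
    return table, chi2_independence(table.to_numpy())


def iae_distance_test(
    hits: dict[str, IaeHit], downregulated: dict[str, bool]
) -> tuple[TestResult, dict[str, float]]:
    """Mann-Whitney comparison of nearest-IAE distances between groups.

    Among circRNAs with a hit, distances of the >2-fold-downregulated
    group are compared to the rest (two-sided); group medians reported.
    """
    down = [h.total_distance for cid, h in hits.items() if downregulated[cid]]
    rest = [h.total_distance for cid, h in hits.items() if not downregulated[cid]]
    if not down or not rest:
        return (
            TestResult(float("nan"), float("nan"), "mann_whitney", degenerate=True),
            {"median_down": float("nan"), "median_rest": float("nan")},
        )
    result = mann_whitney_u(down, rest)
    medians = {
        "median_down": float(pd.Series(down).median()),
        "median_rest": float(pd.Series(rest).median()),
    }
    return result, medians
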