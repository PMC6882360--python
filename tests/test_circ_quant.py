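import pandas as pd
import pytest

from circskin import circ_quant as cq
from circskin import io_formats as io


# ------------------------------------------------------------ RPM and CTL

def test_rpm_hand_arithmetic():
    assert cq.compute_rpm(5, 1_000_000) == pytest.approx(5.0, abs=1e-12)
    assert cq.compute_rpm(10, 2_000_000) == pytest.approx(5.0, abs=1e-12)
    assert cq.compute_rpm(0, 12345) == 0.0
    with pytest.raises(ValueError):
        cq.compute_rpm(5, 0)


def test_ctl_hand_arithmetic():
    # bsj / ((donor + acceptor)/2 + 1)
    assert cq.compute_ctl(10, 4, 2) == pytest.approx(2.5, abs=1e-12)
    assert cq.compute_ctl(0, 7, 3) == 0.0
    assert cq.compute_ctl(7, 0, 0) == pytest.approx(7.0, abs=1e-12)
    with pytest.raises(ValueError):
        cq.compute_ctl(-1, 0, 0)


# ----------------------------------------------------- abundance classes

def _record(counts: dict, totals: float = 1e6):
    iv = io.GenomicInterval("chr1", 100, 200, "+")
    rec = cq.CircRecord(
        interval=iv,
        bsj_count=dict(counts),
        donor_linear={s: 0.0 for s in counts},
        acceptor_linear={s: 0.0 for s in counts},
        total_reads={s: totals for s in counts},
    )
    for s in counts:
        rec.rpm[s] = cq.compute_rpm(rec.bsj_count[s], totals)
        rec.ctl[s] = cq.compute_ctl(rec.bsj_count[s], 0.0, 0.0)
    return rec


COND = {f"s{i}": "lesional" for i in range(6)}


def test_high_abundance_boundary_inclusive():
    rec = _record({f"s{i}": 5 for i in range(6)})
    cq.classify_abundance(rec, COND)
    assert rec.high_abundance["lesional"]


def test_high_abundance_is_a_mean_rule():
    rec = _record(dict(zip(COND, [0, 0, 0, 0, 0, 30])))
    cq.classify_abundance(rec, COND)
    assert rec.mean_bsj["lesional"] == pytest.approx(5.0)
    assert rec.high_abundance["lesional"]
    rec = _record({f"s{i}": 4 for i in range(6)})
    cq.classify_abundance(rec, COND)
    assert not rec.high_abundance["lesional"]


def test_detected_needs_min_reads_in_one_sample():
    rec = _record({f"s{i}": 1 for i in range(6)})
    cq.classify_abundance(rec, COND, min_reads_single_sample=2)
    assert not rec.detected["lesional"]
    rec = _record(dict(zip(COND, [2, 0, 0, 0, 0, 0])))
    cq.classify_abundance(rec, COND, min_reads_single_sample=2)
    assert rec.detected["lesional"]


# ------------------------------------------------------------- annotation

def _five_exon_annotation():
    exons = [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    ann = io.AnnotationSet()
    ann.add(io.Transcript(
        "t1", "g1",
        [io.GenomicInterval("chr1", s, e, "+") for s, e in exons],
    ))
    return ann


def test_splice_consistent_circle_exons_2_to_3():
    ann = _five_exon_annotation()
    rec = _record({"s0": 10, "s1": 10})
    rec.interval = io.GenomicInterval("chr1", 300, 600, "+")
    cq.annotate_circ(rec, ann)
    assert rec.host_gene == "g1"
    assert rec.n_exons_annotated == 2
    assert rec.annotated_splice_consistent


def test_one_nt_offset_is_not_splice_consistent():
    ann = _five_exon_annotation()
    rec = _record({"s0": 10, "s1": 10})
    rec.interval = io.GenomicInterval("chr1", 301, 600, "+")
    cq.annotate_circ(rec, ann)
    assert not rec.annotated_splice_consistent


def test_host_gene_histogram_counts_gene_once():
    ann = _five_exon_annotation()
    recs = []
    for span in ((300, 600), (300, 800)):
        rec = _record({"s0": 10})
        rec.interval = io.GenomicInterval("chr1", *span, "+")
        cq.classify_abundance(rec, {"s0": "lesional"})
        cq.annotate_circ(rec, ann)
        recs.append(rec)
    hist = cq.host_gene_histogram(recs, "lesional")
    assert hist.to_dict() == {"g1": 2}


# -------------------------------------------------- table-level assembly

def test_build_records_from_generated_tables(default_sim):
    sim = default_sim
    records = cq.build_records(
        sim.counts.bsj,
        sim.counts.donor_linear,
        sim.counts.acceptor_linear,
        sim.counts.total_reads,
        sim.counts.condition,
        annotation=sim.annotation,
    )
    assert len(records) == len(sim.counts.bsj)
    by_id = {r.id: r for r in records}
    sample = sim.counts.bsj.columns[0]
    for pc in sim.truth.circs[:10]:
        rec = by_id[pc.circ_id]
        # RPM recomputes exactly from the table entries
        expected = (sim.counts.bsj.loc[pc.circ_id, sample]
                    / sim.counts.total_reads[sample] * 1e6)
        assert rec.rpm[sample] == pytest.approx(expected, abs=1e-12)
        assert rec.annotated_splice_consistent


def test_records_frame_columns(default_sim):
    sim = default_sim
    records = cq.build_records(
        sim.counts.bsj,
        sim.counts.donor_linear,
        sim.counts.acceptor_linear,
        sim.counts.total_reads,
        sim.counts.condition,
    )
    frame = cq.records_frame(records)
    assert len(frame) == len(records)
    assert "circ_id" in frame.columns or frame.index.name == "circ_id"
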