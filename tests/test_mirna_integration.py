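import numpy as np
import pandas as pd
import pytest

from circskin import mirna_integration as mi
from circskin.io_formats import AnnotationSet, GenomicInterval, Transcript


# ------------------------------------------------------------- 8mer motif

def test_eightmer_motif_mir7():
    assert mi.eightmer_motif("UGGAAGACUAGUGAUUUUGUUGU") == "GTCTTCCA"


def test_eightmer_motif_poly_a_seed():
    assert mi.eightmer_motif("UAAAAAAAGG") == "TTTTTTTA"


def test_eightmer_motif_rejects_short():
    with pytest.raises(ValueError):
        mi.eightmer_motif("UGGAAGA")


# ------------------------------------------------------------ site counts

def test_count_sites_direct_scan():
    assert mi.count_sites_circular("GTCTTCCA", "AAGTCTTCCAAA") == 1
    assert mi.count_sites_circular("GTCTTCCA", "A" * 40) == 0


def test_count_sites_junction_spanning():
    # site formed only across the backsplice junction: ...GTCTT | CCA...
    seq = "CCA" + "G" * 30 + "GTCTT"
    assert mi.count_sites_linear("GTCTTCCA", seq) == 0
    assert mi.count_sites_circular("GTCTTCCA", seq) == 1


def _rotation_oracle(motif: str, sequence: str) -> int:
    # a circular site exists at position r iff the rotation starting at r
    # begins with the motif; counting rotations counts every site once
    return sum(
        1 for r in range(len(sequence))
        if (sequence[r:] + sequence[:r]).startswith(motif)
    )


def test_circular_scan_equals_rotation_oracle_small():
    rng = np.random.default_rng(12)
    for _ in range(100):
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 80)))
        motif = "".join(rng.choice(list("ACGT"), size=4)) + "A"
        assert mi.count_sites_circular(motif, seq) == \
            _rotation_oracle(motif, seq)


# ------------------------------------------------------ sequence assembly

def _genome_and_annotation():
    rng = np.random.default_rng(7)
    chrom = "".join(rng.choice(list("ACGT"), size=600))
    exons = [(100, 200), (300, 400)]
    plus = Transcript("t+", "g+", [GenomicInterval("chr1", s, e, "+")
                                   for s, e in exons])
    minus = Transcript("t-", "g-", [GenomicInterval("chr1", s, e, "-")
                                    for s, e in exons])
    ann = AnnotationSet()
    ann.add(plus)
    ann.add(minus)
    return {"chr1": chrom}, ann


def test_assemble_plus_strand_concatenates_exons():
    genome, ann = _genome_and_annotation()
    seq = mi.assemble_circ_sequence(
        GenomicInterval("chr1", 100, 400, "+"), ann, genome)
    assert seq.sequence == genome["chr1"][100:200] + genome["chr1"][300:400]
    assert len(seq) == 200


def test_assemble_minus_strand_is_reverse_complement():
    genome, ann = _genome_and_annotation()
    plus = mi.assemble_circ_sequence(
        GenomicInterval("chr1", 100, 400, "+"), ann, genome)
    minus = mi.assemble_circ_sequence(
        GenomicInterval("chr1", 100, 400, "-"), ann, genome)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    assert minus.sequence == "".join(comp[b] for b in reversed(plus.sequence))


def test_assemble_unannotated_circle_raises():
    genome, ann = _genome_and_annotation()
    with pytest.raises(ValueError):
        mi.assemble_circ_sequence(
            GenomicInterval("chr1", 101, 400, "+"), ann, genome)


# ----------------------------------------------------------- sponge score

def test_sponge_score_hand_arithmetic():
    sites = pd.DataFrame({"c1": {"m1": 2}, "c2": {"m1": 1}})
    delta = pd.Series({"c1": -10.0, "c2": 1.0})
    (score,) = mi.sponge_scores(sites, delta)
    assert score.total_sites == 3
    assert score.score == pytest.approx(-19.0, abs=1e-12)


def test_sponge_score_linearity_in_delta():
    sites = pd.DataFrame({"c1": {"m1": 2, "m2": 0}, "c2": {"m1": 1, "m2": 3}})
    delta = pd.Series({"c1": -10.0, "c2": 1.0})
    once = {s.mirna: s.score for s in mi.sponge_scores(sites, delta)}
    twice = {s.mirna: s.score for s in mi.sponge_scores(sites, 2 * delta)}
    for mirna in once:
        assert twice[mirna] == pytest.approx(2 * once[mirna], abs=1e-12)


def test_regression_excludes_siteless_and_fits_exact_line():
    scores = [
        mi.SpongeScore("m1", 2, -10.0),
        mi.SpongeScore("m2", 1, 5.0),
        mi.SpongeScore("m3", 4, 20.0),
        mi.SpongeScore("m0", 0, 0.0),  # no sites: excluded
    ]
    fc = pd.Series({"m1": -20.0, "m2": 10.0, "m3": 40.0, "m0": 999.0})
    diff = pd.Series({"m1": 1.0, "m2": 2.0, "m3": 3.0, "m0": 999.0})
    out = mi.score_vs_expression_regression(scores, fc, diff)
    assert out["fold_change"].n == 3
    assert out["fold_change"].slope == pytest.approx(2.0, abs=1e-12)
    assert out["fold_change"].r_squared == pytest.approx(1.0)
    with pytest.raises(ValueError):
        mi.score_vs_expression_regression(scores[:2], fc, diff)
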