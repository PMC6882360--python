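import numpy as np
import pandas as pd
import pytest

from circskin import synthetic_data as sd


def test_generator_is_deterministic(default_sim):
    config = sd.SimulationConfig(seed=0)
    genome, annotation, repeats, truth = sd.simulate_genome_annotation(config)
    counts = sd.simulate_counts(config, truth)
    assert genome == default_sim.genome
    assert counts.bsj.equals(default_sim.counts.bsj)
    assert counts.genes.equals(default_sim.counts.genes)
    assert truth.library_factors == default_sim.truth.library_factors


def test_config_validation():
    with pytest.raises(ValueError):
        sd.SimulationConfig(seed=0, depth=0.0)
    with pytest.raises(ValueError):
        sd.SimulationConfig(seed=0, nb_dispersion=-1.0)
    with pytest.raises(ValueError):
        sd.SimulationConfig(seed=0, down_factor_spread_log2=-0.1)


def test_planted_introns_are_canonical(default_sim):
    sim = default_sim
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    checked = 0
    for tx in sim.annotation:
        seq = sim.genome[tx.chrom]
        for start, end in tx.splice_junctions():
            intron = seq[start:end]
            if tx.strand == "-":
                intron = "".join(comp[b] for b in reversed(intron))
            assert intron[:2] == "GT" and intron[-2:] == "AG"
            checked += 1
    assert checked > 100


def test_circle_fold_changes_median_and_spread(default_sim):
    truth = default_sim.truth
    config = default_sim.config
    factors = np.array([pc.les_mean / pc.nl_mean for pc in truth.circs])
    # quantile-grid construction: median equals circ_down_factor up to the
    # even-n convexity of the arithmetic mean of adjacent grid points
    assert np.median(factors) == pytest.approx(config.circ_down_factor,
                                               rel=1e-3)
    assert factors.min() < config.circ_down_factor < factors.max()
    # a nontrivial share of circles is less than 2-fold down
    assert 10 <= int((factors > 0.5).sum()) <= 40


def test_mirna_panel_net_regulation_is_exactly_zero(default_sim):
    truth = default_sim.truth
    logs = [np.log(truth.mirna_les_means[m] / truth.mirna_nl_means[m])
            for m in truth.mirna_nl_means]
    assert abs(sum(logs)) < 1e-9
    # mirrored tails: effects come in exact reciprocal pairs
    effects = sorted(truth.mirna_les_means[m] / truth.mirna_nl_means[m]
                     for m in truth.mirna_nl_means)
    n_reg = int(round(0.15 * default_sim.config.n_mirnas))
    for i in range(n_reg):
        assert effects[i] * effects[-1 - i] == pytest.approx(1.0, rel=1e-9)


def test_gene_truth_mirrors_host_dependence(default_sim):
    truth = default_sim.truth
    factors = {g: truth.gene_les_means[g] / truth.gene_nl_means[g]
               for g in truth.gene_nl_means}
    down = sorted(f for f in factors.values() if f < 1.0)
    up = sorted((f for f in factors.values() if f > 1.0), reverse=True)
    assert len(down) == len(up)
    for d, u in zip(down, up):
        assert d * u == pytest.approx(1.0, rel=1e-9)
    # host-dependent circles share their circle's factor
    for pc in truth.circs:
        if pc.host_dependent:
            assert factors[pc.gene_id] == pytest.approx(
                pc.les_mean / pc.nl_mean, rel=1e-9)


def test_library_factors_recorded_for_every_sample(default_sim):
    sim = default_sim
    assert set(sim.truth.library_factors) == set(sim.counts.bsj.columns)
    assert all(f > 0 for f in sim.truth.library_factors.values())


def test_planted_iae_distances_respect_windows(default_sim):
    truth = default_sim.truth
    config = default_sim.config
    assert len(truth.iae_pairs) == round(config.frac_iae_flanked
                                         * config.n_circ)
    n_same = 0
    for pair in truth.iae_pairs.values():
        total = pair.gap_upstream + pair.gap_downstream
        assert total <= 2300
        n_same += pair.same_subfamily
    assert n_same == round(config.iae_same_subfamily_frac
                           * len(truth.iae_pairs))


def test_count_tables_shapes_and_samples(default_sim):
    counts = default_sim.counts
    config = default_sim.config
    samples = [f"NL{i}" for i in range(1, config.n_pairs + 1)] + \
        [f"LS{i}" for i in range(1, config.n_pairs + 1)]
    for table in (counts.bsj, counts.donor_linear, counts.acceptor_linear):
        assert list(table.columns) == samples
        assert len(table) == config.n_circ
    assert len(counts.genes) == config.n_genes
    assert set(counts.total_reads.index) == set(samples)
    assert (counts.total_reads > 0).all()
    assert sorted(counts.condition.unique()) == [sd.LESIONAL, sd.NON_LESIONAL]


def test_nanostring_tables_structure(nanostring_tables, default_sim):
    codeset, panel = nanostring_tables
    for table in (codeset, panel):
        assert (table.probe_class == "positive").sum() == 6
        assert (table.probe_class == "negative").sum() == 6
        neg = table.counts.loc[table.probes_of("negative")]
        # negatives sit at the background level
        assert neg.to_numpy().mean() == pytest.approx(
            default_sim.config.nanostring_background, rel=0.5)
    pair = default_sim.truth.designated_stable_pair
    assert set(pair) <= set(panel.counts.index)
    assert len(default_sim.truth.reference_probes) == 7
    assert set(default_sim.truth.reference_probes) <= set(codeset.counts.index)


def test_reads_match_bsj_counts_exactly(small_sim):
    sim = small_sim
    # every planted BSJ read is the tail+head sequence around the junction,
    # emitted exactly count times; verified indirectly: per-sample read
    # numbers equal the per-sample column sums of all count tables
    for sample, reads in sim.reads.items():
        expected = int(
            sim.counts.bsj[sample].sum()
            + sim.counts.donor_linear[sample].sum()
            + sim.counts.acceptor_linear[sample].sum()
            + sim.counts.genes[sample].sum()
        )
        assert len(reads) == expected
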