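import numpy as np
import pandas as pd
import pytest

from circskin import nanostring_norm as nn


def _table(counts: dict, classes: dict, conditions: dict) -> nn.NanoStringTable:
    frame = pd.DataFrame(counts).T  # probes x samples
    return nn.NanoStringTable(
        counts=frame,
        probe_class=pd.Series(classes),
        condition=pd.Series(conditions),
    )


def _base_table(endog):
    counts = {
        "NEG_A": {"s1": 30.0, "s2": 20.0},
        "NEG_B": {"s1": 10.0, "s2": 25.0},
        "POS_A": {"s1": 1000.0, "s2": 1000.0},
        "POS_B": {"s1": 100.0, "s2": 100.0},
        **endog,
    }
    classes = {p: "negative" if p.startswith("NEG")
               else "positive" if p.startswith("POS") else "endogenous"
               for p in counts}
    return _table(counts, classes, {"s1": "lesional", "s2": "non-lesional"})


def test_background_subtract_uses_max_negative_per_lane():
    table = _base_table({"g1": {"s1": 100.0, "s2": 100.0},
                         "g2": {"s1": 25.0, "s2": 25.0}})
    out = nn.background_subtract(table)
    assert out.counts.loc["g1", "s1"] == 70.0   # 100 - max(30, 10)
    assert out.counts.loc["g1", "s2"] == 75.0   # 100 - max(20, 25)
    assert out.counts.loc["g2", "s1"] == 0.0    # floored
    floored = nn.background_subtract(table, floor=1.0)
    assert floored.counts.loc["g2", "s1"] == 1.0


def test_positive_control_normalization_halves_doubled_lane():
    table = _base_table({"g1": {"s1": 50.0, "s2": 100.0}})
    doubled = table.copy_with(table.counts.assign(s1=table.counts["s1"] * 2))
    out, factors = nn.positive_control_normalize(doubled)
    assert factors["s1"] / factors["s2"] == pytest.approx(0.5, abs=1e-12)
    # after normalization the two lanes' positives agree again
    pos = out.counts.loc[["POS_A", "POS_B"]]
    assert np.allclose(pos["s1"], pos["s2"])


def test_positive_control_excludes_zeroed_lowest_rung():
    table = _base_table({"g1": {"s1": 50.0, "s2": 100.0}})
    counts = table.counts.copy()
    counts.loc["POS_B", "s1"] = 0.0  # background-subtracted away
    out, _ = nn.positive_control_normalize(table.copy_with(counts))
    assert np.isfinite(out.counts.to_numpy()).all()


def test_reference_normalize_divides_by_reference_shift():
    counts = {
        "NEG_A": {"s1": 1.0, "s2": 1.0},
        "POS_A": {"s1": 100.0, "s2": 100.0},
        "REF_1": {"s1": 30.0, "s2": 90.0},
        "REF_2": {"s1": 10.0, "s2": 30.0},
        "g1": {"s1": 60.0, "s2": 180.0},
    }
    classes = {"NEG_A": "negative", "POS_A": "positive",
               "REF_1": "reference", "REF_2": "reference",
               "g1": "endogenous"}
    table = _table(counts, classes, {"s1": "lesional", "s2": "non-lesional"})
    out = nn.reference_normalize(table, reference_ids=["REF_1", "REF_2"])
    # s2's references are uniformly 3x s1's, so s2 is divided by 3 relative
    # to s1 and the endogenous probe becomes flat
    assert out.counts.loc["g1", "s1"] == pytest.approx(
        out.counts.loc["g1", "s2"], abs=1e-9)
    # grand mean preserved
    assert out.counts.to_numpy().mean() == pytest.approx(
        table.counts.to_numpy().mean(), abs=1e-9)
    with pytest.raises(ValueError):
        nn.reference_normalize(table, reference_ids=[])


def _normfinder_frame(rng, k=8, n=6, bias=None, noise=0.05):
    probes = {}
    for i in range(k):
        base = rng.uniform(500, 2000)
        b = 0.0 if bias is None else bias[i]
        les = base * 2.0**b * np.exp(rng.normal(0, noise, n))
        nl = base * np.exp(rng.normal(0, noise, n))
        probes[f"p{i}"] = np.concatenate([les, nl])
    cols = [f"LS{j}" for j in range(6)] + [f"NL{j}" for j in range(6)]
    frame = pd.DataFrame(probes).T
    frame.columns = cols
    groups = pd.Series({c: ("lesional" if c.startswith("LS")
                            else "non-lesional") for c in cols})
    return frame, groups


def test_normfinder_constant_candidate_ranks_best():
    rng = np.random.default_rng(0)
    frame, groups = _normfinder_frame(rng, noise=0.2)
    frame.loc["flat"] = 1000.0
    res = nn.normfinder(frame, groups)
    assert res.best_single == "flat"


def test_normfinder_invariant_to_sample_offsets():
    rng = np.random.default_rng(1)
    frame, groups = _normfinder_frame(rng)
    res1 = nn.normfinder(frame, groups)
    shifted = frame.copy()
    shifted["LS0"] = shifted["LS0"] * 3.0  # constant log-scale offset
    res2 = nn.normfinder(shifted, groups)
    assert res1.ranking == res2.ranking
    assert np.allclose(res1.stability, res2.stability)


def test_normfinder_pair_cancels_opposite_biases():
    rng = np.random.default_rng(2)
    # biases sum to zero (normfinder centers per sample) and only p0/p1
    # cancel each other exactly
    bias = [0.6, -0.6, 0.5, 0.3, -0.2, -0.45, 0.25, -0.4]
    frame, groups = _normfinder_frame(rng, bias=bias, noise=0.02)
    res = nn.normfinder(frame, groups)
    assert set(res.best_pair) == {"p0", "p1"}


def test_normfinder_excludes_nonpositive_candidates():
    rng = np.random.default_rng(3)
    frame, groups = _normfinder_frame(rng)
    frame.loc["p0", "LS0"] = 0.0
    with pytest.warns(UserWarning):
        res = nn.normfinder(frame, groups)
    assert "p0" in res.excluded
    assert "p0" not in res.ranking


def test_normalize_chain_on_generated_panel(nanostring_tables, default_sim):
    _, panel = nanostring_tables
    stage = nn.background_subtract(panel, floor=1.0)
    stage, _ = nn.positive_control_normalize(stage)
    candidates = [p for p in stage.counts.index
                  if stage.probe_class[p] == "endogenous"
                  and (stage.counts.loc[p] > 1).all()]
    res = nn.normfinder(stage.counts.loc[candidates], stage.condition)
    # the designated zero-effect low-variance probes must rank among the
    # most stable candidates on any seed; exact best-pair recovery across
    # seeds is asserted in the acceptance suite
    designated = set(default_sim.truth.designated_stable_pair)
    top5 = set(res.ranking[:5])
    assert designated <= top5
    out = nn.reference_normalize(stage, reference_ids=list(res.best_pair))
    assert np.isfinite(out.counts.to_numpy()).all()
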