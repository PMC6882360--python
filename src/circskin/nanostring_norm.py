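"""NanoString nCounter processing and NormFinder reference-gene selection.

The processing chain mirrors the nSolver conventions used for custom
CodeSets and the human miRNA panel: per-lane background subtraction using
the maximum of the negative-control probes, positive-control normalization
with the geometric mean of the positive controls, and a second
normalization against stable reference probes.  Stability is assessed with
a model-based variance decomposition (NormFinder): each candidate's
stability value combines its intra-group variance with its inter-group
bias, and pairs are evaluated on the average signal of the two candidates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NanoStringTable",
    "StabilityResult",
    "background_subtract",
    "positive_control_normalize",
    "reference_normalize",
    "normfinder",
    "normalize_chain",
]

PROBE_CLASSES = ("endogenous", "positive", "negative", "reference")


@dataclass
class NanoStringTable:
    """Probe x sample counts with probe-class and sample annotations."""

    counts: pd.DataFrame  # probes x samples
    probe_class: pd.Series  # probe -> class
    condition: pd.Series  # sample -> condition label
    pairing: pd.Series | None = None  # sample -> patient id

    def __post_init__(self) -> None:
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        for cls in ("positive", "negative"):
            if not (self.probe_class == cls).any():
                raise ValueError(f"table has no {cls} control probes")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def probes_of(self, cls: str) -> pd.Index:
        return self.probe_class.index[self.probe_class == cls]

    def copy_with(self, counts: pd.DataFrame) -> "NanoStringTable":
        return NanoStringTable(counts, self.probe_class, self.condition,
                               self.pairing)

    def endogenous(self) -> pd.DataFrame:
        return self.counts.loc[self.probes_of("endogenous")]


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def background_subtract(table: NanoStringTable, floor: float = 0.0) -> NanoStringTable:
    """Subtract, per sample, the maximum of the negative controls.

    Counts are floored at ``floor`` (0 by default; use 1 for pipelines that
    log-transform afterwards).
    """
    neg = table.counts.loc[table.probes_of("negative")]
    background = neg.max(axis=0)
    adjusted = (table.counts - background).clip(lower=floor)
    return table.copy_with(adjusted)


def positive_control_normalize(
    table: NanoStringTable,
) -> tuple[NanoStringTable, pd.Series]:
    """Scale each lane by its positive-control geometric mean.

    The per-lane factor is (cohort arithmetic mean of per-lane positive
    geomeans) / (this lane's positive geomean); the anchor only fixes the
    global scale.  Positive probes that are not strictly positive in every
    lane (the lowest ladder rung sits at the background level and can be
    zeroed by background subtraction) are excluded from the geomean.
    """
    pos = table.counts.loc[table.probes_of("positive")]
    usable = pos.index[(pos > 0).all(axis=1)]
    if len(usable) == 0:
        raise ValueError("no positive-control probe is positive in every lane")
    pos = pos.loc[usable]
    lane_geomeans = pos.apply(lambda col: _geomean(col.to_numpy()), axis=0)
    factors = lane_geomeans.mean() / lane_geomeans
    factors.name = "scale_factor"
    return table.copy_with(table.counts * factors), factors


def reference_normalize(
    table: NanoStringTable,
    reference_ids: list[str] | None = None,
    n_refs: int = 3,
) -> NanoStringTable:
    """Second normalization against stable reference probes.

    With ``reference_ids`` unset, the ``n_refs`` most stable
    reference-class probes by NormFinder ranking are used.  Each sample is
    divided by the geometric mean of the references, then rescaled so the
    grand mean of the table is preserved.
    """
    if reference_ids is None:
        candidates = list(table.probes_of("reference"))
        if len(candidates) < n_refs:
            raise ValueError("not enough reference probes")
        stability = normfinder(table, candidates=candidates)
        reference_ids = stability.ranking[:n_refs]
    if not reference_ids:
        raise ValueError("empty reference list")
    refs = table.counts.loc[reference_ids]
    for sample in refs.columns:
        if (refs[sample] <= 0).any():
            raise ValueError(
                f"reference probe with count <= 0 in sample {sample!r}"
            )
    ref_geomeans = refs.apply(lambda col: _geomean(col.to_numpy()), axis=0)
    scaled = table.counts / ref_geomeans
    grand_before = table.counts.to_numpy().mean()
    grand_after = scaled.to_numpy().mean()
    return table.copy_with(scaled * (grand_before / grand_after))


def normalize_chain(
    table: NanoStringTable,
    reference_ids: list[str] | None = None,
    floor: float = 0.0,
) -> tuple[NanoStringTable, pd.Series]:
    """background subtraction -> positive-control -> reference normalization."""
    stage1 = background_subtract(table, floor=floor)
    stage2, factors = positive_control_normalize(stage1)
    stage3 = reference_normalize(stage2, reference_ids=reference_ids)
    return stage3, factors


# --------------------------------------------------------------------------
# NormFinder
# --------------------------------------------------------------------------

@dataclass
class StabilityResult:
    """NormFinder output: lower stability value = more stable."""

    stability: pd.Series  # candidate -> stability value
    ranking: list[str] = field(default_factory=list)
    best_single: str = ""
    best_pair: tuple[str, str] = ("", "")
    pair_stability: float = math.nan
    excluded: list[str] = field(default_factory=list)


def _group_summaries(x: np.ndarray, group_index: list[np.ndarray]):
    """Per-candidate, per-group means and sampling variances of the mean."""
    means = np.stack([x[:, idx].mean(axis=1) for idx in group_index], axis=1)
    var_of_mean = np.stack(
        [x[:, idx].var(axis=1, ddof=1) / len(idx) for idx in group_index],
        axis=1,
    )
    return means, var_of_mean


def normfinder(
    table: NanoStringTable | pd.DataFrame,
    groups: pd.Series | None = None,
    candidates: list[str] | None = None,
) -> StabilityResult:
    """Rank candidate reference probes by model-based stability.

    The log2 signal is modelled as probe effect + sample effect + group
    bias + noise.  Sample effects are removed by centering each sample on
    its candidate average; the group bias d_ig and the intra-group variance
    are then estimated per candidate, the bias is shrunk toward zero by its
    estimated signal-to-noise ratio, and the stability value is the mean
    over groups of |shrunken bias| + standard error.  The best pair
    minimizes the same quantity computed for the average of two
    candidates' signals (opposite biases cancel).
    """
    if isinstance(table, NanoStringTable):
        counts = table.counts
        groups = table.condition if groups is None else groups
    else:
        counts = table
        if groups is None:
            raise ValueError("groups required when passing a bare DataFrame")
        groups = pd.Series(groups, index=counts.columns) if not isinstance(
            groups, pd.Series) else groups
    if candidates is None:
        candidates = list(counts.index)
    if len(candidates) < 3:
        raise ValueError("normfinder requires at least 3 candidates")

    data = counts.loc[candidates]
    excluded = [c for c in candidates if (data.loc[c] <= 0).any()]
    if excluded:
        warnings.warn(
            f"excluding candidates with non-positive counts: {excluded}",
            stacklevel=2,
        )
        candidates = [c for c in candidates if c not in excluded]
        if len(candidates) < 3:
            raise ValueError("fewer than 3 usable candidates after exclusion")
        data = counts.loc[candidates]

    labels = [groups[s] for s in data.columns]
    group_names = sorted(set(labels))
    group_index = [
        np.array([i for i, g in enumerate(labels) if g == name])
        for name in group_names
    ]
    if any(len(idx) < 2 for idx in group_index):
        raise ValueError("normfinder requires >= 2 samples per group")

    x = np.log2(data.to_numpy(dtype=float))
    x = x - x.mean(axis=0, keepdims=True)  # remove sample effects

    means, var_of_mean = _group_summaries(x, group_index)
    # group bias: candidate's group mean relative to its cross-group mean
    d = means - means.mean(axis=1, keepdims=True)
    k = len(candidates)
    n_groups = len(group_names)
    # variance of the true biases, freeing the sampling noise share
    gamma2 = max(
        0.0,
        float(np.sum(d**2) / ((k - 1) * max(1, n_groups - 1))
              - var_of_mean.mean()),
    )

    def _stability(d_row: np.ndarray, v_row: np.ndarray) -> float:
        shrink = gamma2 / (gamma2 + v_row) if gamma2 > 0 else np.zeros_like(v_row)
        d_tilde = d_row * shrink
        return float(np.mean(np.abs(d_tilde) + np.sqrt(v_row)))

    stability = pd.Series(
        [_stability(d[i], var_of_mean[i]) for i in range(k)],
        index=candidates,
        name="stability",
    )
    ranking = list(stability.sort_values(kind="stable").index)

    best_pair = ("", "")
    best_pair_value = math.inf
    for i, j in itertools.combinations(range(k), 2):
        # pair stability is evaluated on the averaged log profile of the
        # two candidates: biases average (opposite signs cancel) and the
        # intra-group variance is measured empirically on the averaged
        # signal, so correlation between the candidates is accounted for
        # intra-group variance of the averaged signal, floored at the
        # independence value: apparent negative correlation between two
        # candidates is overwhelmingly sampling noise at these group
        # sizes, and minimizing over all pairs would cherry-pick it
        y = (x[i] + x[j]) / 2.0
        d_pair = (d[i] + d[j]) / 2.0
        v_pair = np.maximum(
            np.array([y[gi].var(ddof=1) / len(gi) for gi in group_index]),
            (var_of_mean[i] + var_of_mean[j]) / 4.0,
        )
        value = _stability(d_pair, v_pair)
        if value < best_pair_value:
            best_pair_value = value
            best_pair = (candidates[i], candidates[j])

    return StabilityResult(
        stability=stability,
        ranking=ranking,
        best_single=ranking[0],
        best_pair=tuple(sorted(best_pair)),
        pair_stability=best_pair_value,
        excluded=excluded,
    )
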