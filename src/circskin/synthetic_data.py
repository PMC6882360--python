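"""Synthetic paired-cohort study generator with known ground truth.

Generates a toy genome, exon annotation, repeat track, per-sample reads
and count tables, NanoString-style panels and mature miRNA sequences that
emulate the statistical structure of a paired lesional/non-lesional skin
cohort: six patient pairs, negative-binomial counts, a global
multiplicative downregulation of circRNA abundance in the lesional
condition that is largely independent of host-gene changes, a subset of
circRNAs with inverted Alu pairs planted in the flanking introns, and
control/reference probes with known lane effects.

Everything planted is recorded in a :class:`TruthSet` so the pipeline's
recovery can be checked exactly.  All outputs are deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri as _norm_ppf

from .io_formats import (
    AnnotationSet,
    GenomicInterval,
    RepeatFeature,
    Transcript,
    alu_subfamily,
    circ_id,
)
from .nanostring_norm import NanoStringTable

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "PlantedCirc",
    "PlantedIae",
    "CountTables",
    "simulate_genome_annotation",
    "simulate_counts",
    "simulate_reads",
    "simulate_nanostring",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_ALU_NAMES = {
    "AluJ": ("AluJb", "AluJo"),
    "AluS": ("AluSx", "AluSz"),
    "AluY": ("AluYa5", "AluYb8"),
}
ALU_LENGTH = 300

LESIONAL = "lesional"
NON_LESIONAL = "non-lesional"


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the emulated cohort: six patient pairs, strong global
    circRNA downregulation in the lesional condition mostly independent of
    host genes, overdispersed counts, and 44% of circRNAs flanked by an
    inverted Alu pair.
    """

    seed: int = 0
    n_pairs: int = 6
    n_genes: int = 200
    n_circ: int = 100
    circ_down_factor: float = 0.25
    down_factor_spread_log2: float = 1.5
    frac_host_dependent: float = 0.3
    nb_dispersion: float = 0.1
    frac_iae_flanked: float = 0.44
    iae_same_subfamily_frac: float = 0.5
    read_length: int = 100
    anchor_length: int = 20
    depth: float = 1.0
    n_mirnas: int = 60
    mirna_coupling: bool = False
    nanostring_background: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.circ_down_factor <= 1):
            raise ValueError("circ_down_factor must be in (0, 1]")
        if self.down_factor_spread_log2 < 0:
            raise ValueError("down_factor_spread_log2 must be >= 0")
        for name in ("frac_host_dependent", "frac_iae_flanked",
                     "iae_same_subfamily_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_pairs", "n_genes", "n_circ", "read_length",
                     "anchor_length", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_circ >= self.n_genes:
            raise ValueError("n_genes must exceed n_circ")
        if self.read_length < 2 * self.anchor_length:
            raise ValueError("read_length must be >= 2 x anchor_length")
        if self.nb_dispersion < 0 or self.depth <= 0:
            raise ValueError("nb_dispersion >= 0 and depth > 0 required")


@dataclass
class PlantedCirc:
    """One planted circRNA and its true per-condition means."""

    circ_id: str
    transcript_id: str
    gene_id: str
    exon_span: tuple[int, int]  # genomic-sorted exon indices, inclusive
    nl_mean: float
    les_mean: float
    host_dependent: bool
    donor_linear_nl_mean: float
    acceptor_linear_nl_mean: float

    @property
    def interval(self) -> GenomicInterval:
        from .io_formats import parse_circ_id

        return parse_circ_id(self.circ_id)

    def linear_mean(self, side: str, condition: str) -> float:
        """Linear junction mean; hosts of dependent circles follow the
        circle's own planted lesional factor."""
        base = (
            self.donor_linear_nl_mean if side == "donor"
            else self.acceptor_linear_nl_mean
        )
        if condition == LESIONAL and self.host_dependent:
            return base * (self.les_mean / self.nl_mean)
        return base


@dataclass
class PlantedIae:
    circ_id: str
    upstream_name: str
    downstream_name: str
    gap_upstream: int
    gap_downstream: int
    same_subfamily: bool

    @property
    def total_distance(self) -> int:
        return self.gap_upstream + self.gap_downstream


@dataclass
class TruthSet:
    """Everything the generator planted, for exact recovery checks."""

    circs: list[PlantedCirc] = field(default_factory=list)
    iae_pairs: dict[str, PlantedIae] = field(default_factory=dict)
    mirna_sequences: dict[str, str] = field(default_factory=dict)
    mirna_nl_means: dict[str, float] = field(default_factory=dict)
    mirna_les_means: dict[str, float] = field(default_factory=dict)
    planted_sites: dict[str, dict[str, int]] = field(default_factory=dict)  # mirna -> circ -> n
    gene_nl_means: dict[str, float] = field(default_factory=dict)
    gene_les_means: dict[str, float] = field(default_factory=dict)
    lane_factors: dict[str, float] = field(default_factory=dict)
    library_factors: dict[str, float] = field(default_factory=dict)
    nanostring_background: float = 0.0
    designated_stable_pair: tuple[str, str] = ("", "")
    reference_probes: list[str] = field(default_factory=list)
    coupled_mirna: str = ""

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["iae_pairs"] = {k: asdict(v) for k, v in self.iae_pairs.items()}
        payload["circs"] = [asdict(c) for c in self.circs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        payload["circs"] = [
            PlantedCirc(**{**c, "exon_span": tuple(c["exon_span"])})
            for c in payload["circs"]
        ]
        payload["iae_pairs"] = {
            k: PlantedIae(**v) for k, v in payload["iae_pairs"].items()
        }
        payload["designated_stable_pair"] = tuple(payload["designated_stable_pair"])
        return cls(**payload)


@dataclass
class CountTables:
    """Ready-made per-sample count tables (detection can be bypassed)."""

    bsj: pd.DataFrame  # circ x sample
    donor_linear: pd.DataFrame
    acceptor_linear: pd.DataFrame
    genes: pd.DataFrame
    mirna: pd.DataFrame
    total_reads: pd.Series
    condition: pd.Series  # sample -> condition
    pairing: pd.Series  # sample -> patient id


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sample_names(n_pairs: int) -> tuple[list[str], pd.Series, pd.Series]:
    samples, condition, pairing = [], {}, {}
    for cond, prefix in ((NON_LESIONAL, "NL"), (LESIONAL, "LS")):
        for i in range(1, n_pairs + 1):
            name = f"{prefix}{i}"
            samples.append(name)
            condition[name] = cond
            pairing[name] = f"P{i}"
    return samples, pd.Series(condition), pd.Series(pairing)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial draw with mean and dispersion (var = mu + mu^2 phi)."""
    if mean <= 0:
        return 0
    if dispersion < 1e-8:
        return int(rng.poisson(mean))
    size = 1.0 / dispersion
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


# --------------------------------------------------------------------------
# genome + annotation + repeats
# --------------------------------------------------------------------------

def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], AnnotationSet, list[RepeatFeature], TruthSet]:
    """Build the toy genome with planted circles, Alu pairs and miRNA sites.

    Every multi-exon transcript carries canonical GT/AG intron signals at
    its exon boundaries (reverse-complemented for minus-strand genes), the
    two bases framing each planted backsplice are chosen so the junction
    breakpoint is unambiguous, and the planted Alu pairs sit fully inside
    the introns flanking the circle with recorded per-flank gaps.
    """
    rng = np.random.default_rng([config.seed, 0])
    truth = TruthSet()

    # mature miRNA sequences (RNA alphabet) and the 8mer site plan
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    for mid in mirna_ids:
        seq = "".join(rng.choice(_BASES, size=21)).replace("T", "U")
        truth.mirna_sequences[mid] = seq

    # per-circ expression truth drawn up front so the site plan can point
    # the coupled miRNA at the strongest movers.  Lesional/non-lesional
    # fold factors are planted on a fixed lognormal quantile grid centered
    # on circ_down_factor (median exactly circ_down_factor; with the
    # default spread ~25% of circles stay above a 2-fold drop and a few
    # rise), permuted at random across circles.
    circ_nl_means = np.exp(
        rng.uniform(np.log(10), np.log(100), size=config.n_circ)
    )
    grid = _norm_ppf((np.arange(config.n_circ) + 0.5) / config.n_circ)
    circ_factors = config.circ_down_factor * np.power(
        2.0, config.down_factor_spread_log2 * grid
    )
    circ_factors = circ_factors[rng.permutation(config.n_circ)]
    circ_host_dep = rng.random(config.n_circ) < config.frac_host_dependent

    n_site_mirnas = min(8, config.n_mirnas)
    site_plan: dict[int, list[tuple[str, int]]] = {}  # circ index -> (mirna, n)
    for mid in mirna_ids[:n_site_mirnas]:
        truth.planted_sites[mid] = {}
        for circ_idx in rng.choice(config.n_circ,
                                   size=min(3, config.n_circ), replace=False):
            n_sites = int(rng.integers(1, 4))
            site_plan.setdefault(int(circ_idx), []).append((mid, n_sites))
    if config.mirna_coupling:
        # concentrate the coupled miRNA's sites in the circles with the
        # largest absolute planted expression loss
        coupled = mirna_ids[-1]
        truth.coupled_mirna = coupled
        truth.planted_sites[coupled] = {}
        loss = circ_nl_means * (1.0 - circ_factors)
        strongest = np.argsort(-loss)[: min(5, config.n_circ)]
        for circ_idx in strongest:
            site_plan.setdefault(int(circ_idx), []).append((coupled, 3))

    chrom = "chr1"
    pieces: list[str] = []
    offset = 0
    annotation = AnnotationSet()
    repeats: list[RepeatFeature] = []
    n_iae = round(config.frac_iae_flanked * config.n_circ)
    n_same_subfamily = round(config.iae_same_subfamily_frac * n_iae)

    for g in range(config.n_genes):
        spacer = int(rng.integers(1500, 2501))
        pieces.append("".join(_random_seq(rng, spacer)))
        offset += spacer

        is_circ_gene = g < config.n_circ
        strand = "+" if rng.random() < 0.5 else "-"
        if is_circ_gene:
            span_len = int(rng.choice([2, 2, 3]))
            n_exons = int(rng.integers(span_len + 2, span_len + 4))
            intron_lens = [int(rng.integers(1400, 1801)) for _ in range(n_exons - 1)]
        else:
            span_len = 0
            n_exons = int(rng.integers(2, 6))
            intron_lens = [int(rng.integers(400, 901)) for _ in range(n_exons - 1)]
        exon_lens = [int(rng.integers(150, 301)) for _ in range(n_exons)]
        exon_seqs = [_random_seq(rng, ln) for ln in exon_lens]

        # circle occupies genomic-sorted exon indices [1, span_len]
        if is_circ_gene:
            genomic_span = (1, span_len)
            if strand == "+":
                tx_first, tx_last = genomic_span
            else:
                tx_first = n_exons - 1 - genomic_span[1]
                tx_last = n_exons - 1 - genomic_span[0]
            # unambiguous breakpoint: circle must not start or end with G
            # (G would extend into the GT/AG splice signals)
            first = exon_seqs[tx_first][0]
            if first == "G":
                exon_seqs[tx_first][0] = "A"
            last = exon_seqs[tx_last][-1]
            if last == "G":
                exon_seqs[tx_last][-1] = "A"
            # plant 8mer sites into the circle's exons (transcript sense),
            # away from exon edges so boundary bases stay fixed
            for mid, n_sites in site_plan.get(g, []):
                motif = _eightmer_motif_dna(truth.mirna_sequences[mid])
                target_exons = list(range(tx_first, tx_last + 1))
                used: dict[int, list[tuple[int, int]]] = {e: [] for e in target_exons}
                planted = 0
                attempts = 0
                while planted < n_sites and attempts < 200:
                    attempts += 1
                    e = int(rng.choice(target_exons))
                    ln = exon_lens[e]
                    pos = int(rng.integers(2, ln - 10))
                    if any(pos < b + 8 and s < pos + 8 for s, b in used[e]):
                        continue
                    exon_seqs[e][pos : pos + 8] = list(motif)
                    used[e].append((pos, pos + 8))
                    planted += 1
                truth.planted_sites[mid][f"__pending_{g}"] = planted

        # assemble gene in transcript orientation
        parts: list[str] = []
        local_exons: list[tuple[int, int]] = []
        cursor = 0
        for i in range(n_exons):
            seq = "".join(exon_seqs[i])
            parts.append(seq)
            local_exons.append((cursor, cursor + len(seq)))
            cursor += len(seq)
            if i < n_exons - 1:
                intron = "GT" + "".join(_random_seq(rng, intron_lens[i] - 4)) + "AG"
                parts.append(intron)
                cursor += len(intron)
        gene_seq = "".join(parts)
        gene_len = len(gene_seq)
        if strand == "-":
            gene_seq = _revcomp(gene_seq)
            local_exons = [(gene_len - e, gene_len - s) for s, e in local_exons]
        exon_intervals = sorted(
            GenomicInterval(chrom, offset + s, offset + e, strand)
            for s, e in local_exons
        )
        transcript = Transcript(f"TX{g + 1}", f"G{g + 1}", exon_intervals)
        annotation.add(transcript)
        pieces.append(gene_seq)
        offset += gene_len

        if is_circ_gene:
            span_start, span_end = genomic_span
            interval = GenomicInterval(
                chrom,
                exon_intervals[span_start].start,
                exon_intervals[span_end].end,
                strand,
            )
            cid = circ_id(interval)
            # resolve pending site records now that the id exists
            for mid in list(truth.planted_sites):
                pending = truth.planted_sites[mid].pop(f"__pending_{g}", None)
                if pending is not None:
                    truth.planted_sites[mid][cid] = pending
            nl_mean = float(circ_nl_means[g])
            host_dependent = bool(circ_host_dep[g])
            truth.circs.append(
                PlantedCirc(
                    circ_id=cid,
                    transcript_id=transcript.transcript_id,
                    gene_id=transcript.gene_id,
                    exon_span=genomic_span,
                    nl_mean=nl_mean,
                    les_mean=nl_mean * float(circ_factors[g]),
                    host_dependent=host_dependent,
                    donor_linear_nl_mean=float(
                        np.exp(rng.uniform(np.log(15), np.log(80)))
                    ),
                    acceptor_linear_nl_mean=float(
                        np.exp(rng.uniform(np.log(15), np.log(80)))
                    ),
                )
            )
            circ_idx = len(truth.circs) - 1
            if circ_idx < n_iae:
                same_sub = circ_idx < n_same_subfamily
                repeats.extend(
                    _plant_iae_pair(rng, truth, cid, interval, same_sub)
                )
            elif rng.random() < 0.5:
                # non-inverted decoy: same-strand pair in the flanks
                for side, pos in (("up", interval.start), ("down", interval.end)):
                    gap = int(rng.integers(100, 501))
                    if side == "up":
                        iv = GenomicInterval(chrom, pos - gap - ALU_LENGTH, pos - gap, "+")
                    else:
                        iv = GenomicInterval(chrom, pos + gap, pos + gap + ALU_LENGTH, "+")
                    name = _ALU_NAMES["AluS"][0]
                    repeats.append(RepeatFeature(iv, name, alu_subfamily(name)))
        elif rng.random() < 0.25:
            # sparse intergenic decoys, all forward strand
            pos = offset - gene_len - spacer + int(rng.integers(0, max(1, spacer - ALU_LENGTH)))
            iv = GenomicInterval(chrom, pos, pos + ALU_LENGTH, "+")
            name = "AluYa5"
            repeats.append(RepeatFeature(iv, name, alu_subfamily(name)))

    pieces.append("".join(_random_seq(rng, 2000)))
    genome = {chrom: "".join(pieces)}

    # drop empty site entries
    truth.planted_sites = {
        m: {c: n for c, n in d.items() if n > 0}
        for m, d in truth.planted_sites.items()
    }

    # miRNA expression truth: strong regulated tails planted balanced by
    # construction — each upregulated miRNA is paired with a downregulated
    # one at the reciprocal fold change, so the panel-wide planted
    # condition effect sums to zero in log space and reference selection
    # over the candidate pool is not confounded by net co-regulation.
    # All remaining miRNAs get a modest lognormal condition effect (no
    # endogenous miRNA is exactly condition-free; only the designated
    # NanoString stable probes are).  When coupling is on, the coupled
    # miRNA is additionally forced strongly up.
    n_reg = int(round(0.15 * config.n_mirnas))
    order = [mirna_ids[i] for i in rng.permutation(config.n_mirnas)]
    effects: dict[str, float] = {}
    for i in range(n_reg):
        up = float(rng.uniform(2.0, 4.0))
        effects[order[i]] = up
        effects[order[n_reg + i]] = 1.0 / up
    bulk = order[2 * n_reg:]
    bulk_logs = rng.normal(0.0, 0.2 * np.log(2), size=len(bulk))
    # the balance contract is exact, not just in expectation: the bulk
    # effects are centered in log space so the panel's net log2 effect is
    # zero in every realization, like the mirrored tails above
    bulk_logs -= bulk_logs.mean()
    for mid, log_effect in zip(bulk, bulk_logs):
        effects[mid] = float(np.exp(log_effect))
    if truth.coupled_mirna:
        effects[truth.coupled_mirna] = 3.0
    for mid in mirna_ids:
        nl = float(np.exp(rng.uniform(np.log(10), np.log(300))))
        truth.mirna_nl_means[mid] = nl
        truth.mirna_les_means[mid] = nl * effects[mid]

    # gene-level truth: hosts follow their circle's dependence class, and
    # the down-regulated hosts are balanced by an equal number of
    # up-regulated inflammation-program genes among the non-host genes
    # (lesional skin carries a strong induced inflammatory signature), so
    # median-of-ratios size factors see two-sided regulation rather than a
    # one-sided contamination that would bias the per-sample median
    dep_factor = {
        c.gene_id: c.les_mean / c.nl_mean
        for c in truth.circs
        if c.host_dependent
    }
    gene_ids = [f"G{g + 1}" for g in range(config.n_genes)]
    hosts = {c.gene_id for c in truth.circs}
    free = [g for g in gene_ids if g not in hosts]
    order = rng.permutation(len(free))
    up_factor = {
        free[i]: 1.0 / f
        for i, f in zip(order, dep_factor.values())
    }
    for gid in gene_ids:
        nl = float(np.exp(rng.uniform(np.log(80), np.log(400))))
        factor = dep_factor.get(gid, up_factor.get(gid, 1.0))
        truth.gene_nl_means[gid] = nl
        truth.gene_les_means[gid] = nl * factor

    return genome, annotation, repeats, truth


def _eightmer_motif_dna(mirna_seq: str) -> str:
    seq = mirna_seq.upper().replace("U", "T")
    return _revcomp(seq[1:8]) + "A"


def _plant_iae_pair(
    rng: np.random.Generator,
    truth: TruthSet,
    cid: str,
    interval: GenomicInterval,
    same_subfamily: bool,
) -> list[RepeatFeature]:
    gap_up = int(rng.integers(100, 501))
    gap_down = int(rng.integers(100, 501))
    if same_subfamily:
        family = str(rng.choice(list(_ALU_NAMES)))
        up_name, down_name = _ALU_NAMES[family]
    else:
        fam_up, fam_down = rng.choice(list(_ALU_NAMES), size=2, replace=False)
        up_name = _ALU_NAMES[str(fam_up)][0]
        down_name = _ALU_NAMES[str(fam_down)][0]
    up_strand = "+" if rng.random() < 0.5 else "-"
    down_strand = "-" if up_strand == "+" else "+"
    up = RepeatFeature(
        GenomicInterval(
            interval.chrom,
            interval.start - gap_up - ALU_LENGTH,
            interval.start - gap_up,
            up_strand,
        ),
        up_name,
        alu_subfamily(up_name),
    )
    down = RepeatFeature(
        GenomicInterval(
            interval.chrom,
            interval.end + gap_down,
            interval.end + gap_down + ALU_LENGTH,
            down_strand,
        ),
        down_name,
        alu_subfamily(down_name),
    )
    truth.iae_pairs[cid] = PlantedIae(
        circ_id=cid,
        upstream_name=up_name,
        downstream_name=down_name,
        gap_upstream=gap_up,
        gap_downstream=gap_down,
        same_subfamily=same_subfamily,
    )
    return [up, down]


# --------------------------------------------------------------------------
# counts
# --------------------------------------------------------------------------

def simulate_counts(config: SimulationConfig, truth: TruthSet) -> CountTables:
    """Draw negative-binomial count tables around the planted means.

    Lesional circRNA means are the non-lesional means times
    ``circ_down_factor``; for host-independent circles the linear junction
    and gene means are identical across conditions.  Per-sample library
    scale factors (lognormal, recorded in ``truth.library_factors``)
    multiply every RNA-seq-derived mean, so downstream size-factor
    normalization has real depth variation to remove; the miRNA assay is
    a separate library and is left unscaled.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples, condition, pairing = _sample_names(config.n_pairs)
    disp = config.nb_dispersion
    depth = config.depth
    library = {s: float(np.exp(rng.normal(0.0, 0.15))) for s in samples}
    truth.library_factors = library

    def draw(mean: float, sample: str) -> int:
        return _nb_draw(rng, mean * depth * library[sample], disp)

    circ_ids = [c.circ_id for c in truth.circs]
    bsj = pd.DataFrame(0, index=circ_ids, columns=samples, dtype=int)
    donor = pd.DataFrame(0, index=circ_ids, columns=samples, dtype=int)
    acceptor = pd.DataFrame(0, index=circ_ids, columns=samples, dtype=int)
    for c in truth.circs:
        for s in samples:
            cond = condition[s]
            mean = c.les_mean if cond == LESIONAL else c.nl_mean
            bsj.loc[c.circ_id, s] = draw(mean, s)
            donor.loc[c.circ_id, s] = draw(c.linear_mean("donor", cond), s)
            acceptor.loc[c.circ_id, s] = draw(
                c.linear_mean("acceptor", cond), s
            )

    gene_ids = sorted(truth.gene_nl_means, key=lambda g: int(g[1:]))
    genes = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=int)
    for gid in gene_ids:
        for s in samples:
            mean = (
                truth.gene_les_means[gid]
                if condition[s] == LESIONAL
                else truth.gene_nl_means[gid]
            )
            genes.loc[gid, s] = draw(mean, s)

    mirna_ids = list(truth.mirna_sequences)
    mirna = pd.DataFrame(0, index=mirna_ids, columns=samples, dtype=int)
    for mid in mirna_ids:
        for s in samples:
            mean = (
                truth.mirna_les_means[mid]
                if condition[s] == LESIONAL
                else truth.mirna_nl_means[mid]
            )
            mirna.loc[mid, s] = _nb_draw(rng, mean * depth, disp)

    total = genes.sum(axis=0) + bsj.sum(axis=0) + donor.sum(axis=0) + acceptor.sum(axis=0)
    return CountTables(
        bsj=bsj,
        donor_linear=donor,
        acceptor_linear=acceptor,
        genes=genes,
        mirna=mirna,
        total_reads=total.astype(float),
        condition=condition,
        pairing=pairing,
    )


# --------------------------------------------------------------------------
# reads
# --------------------------------------------------------------------------

def simulate_reads(
    config: SimulationConfig,
    truth: TruthSet,
    counts: CountTables,
    genome: dict[str, str],
    annotation: AnnotationSet,
) -> dict[str, list[tuple[str, str]]]:
    """Emit per-sample reads matching the count tables exactly.

    Backsplice reads cross the junction with at least ``anchor_length``
    bases on each side; linear reads cross the donor/acceptor splice
    junctions colinearly; each gene additionally contributes fully exonic
    background reads equal to its gene count.
    """
    from .mirna_integration import assemble_circ_sequence

    rng = np.random.default_rng([config.seed, 2])
    L = config.read_length
    anchor = config.anchor_length
    if L < 2 * anchor:
        raise ValueError("read_length must be >= 2 x anchor_length")

    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in counts.bsj.columns}
    serial = 0

    def emit(sample: str, seq: str, tag: str) -> None:
        nonlocal serial
        serial += 1
        reads[sample].append((f"{tag}_{serial}", seq))

    tx_by_id = annotation.transcripts
    spliced_cache: dict[str, str] = {}
    junction_pos_cache: dict[str, dict[int, int]] = {}

    def spliced(tx: Transcript) -> str:
        if tx.transcript_id not in spliced_cache:
            chrom_seq = genome[tx.chrom]
            exon_seqs = [chrom_seq[e.start : e.end] for e in tx.exons]
            if tx.strand == "+":
                spliced_cache[tx.transcript_id] = "".join(exon_seqs)
            else:
                spliced_cache[tx.transcript_id] = "".join(
                    _revcomp(s) for s in reversed(exon_seqs)
                )
        return spliced_cache[tx.transcript_id]

    def junction_spliced_pos(tx: Transcript, genomic_k: int) -> int:
        """Spliced-coordinate position of genomic intron k of a transcript."""
        if tx.transcript_id not in junction_pos_cache:
            n = len(tx.exons)
            lens = [len(e) for e in tx.exons]
            mapping = {}
            if tx.strand == "+":
                cum = 0
                for k in range(n - 1):
                    cum += lens[k]
                    mapping[k] = cum
            else:
                # transcript exon t = genomic exon n-1-t
                cum = 0
                for t in range(n - 1):
                    cum += lens[n - 1 - t]
                    mapping[n - 2 - t] = cum
            junction_pos_cache[tx.transcript_id] = mapping
        return junction_pos_cache[tx.transcript_id][genomic_k]

    for c in truth.circs:
        tx = tx_by_id[c.transcript_id]
        interval = c.interval
        mature = assemble_circ_sequence(interval, annotation, genome).sequence
        if len(mature) < L:
            raise ValueError(f"circle {c.circ_id} shorter than read length")
        span_start, span_end = c.exon_span
        tx_seq = spliced(tx)
        up_junction = junction_spliced_pos(tx, span_start - 1)
        down_junction = junction_spliced_pos(tx, span_end)
        if tx.strand == "+":
            donor_junction, acceptor_junction = down_junction, up_junction
        else:
            donor_junction, acceptor_junction = up_junction, down_junction

        for sample in counts.bsj.columns:
            for _ in range(int(counts.bsj.loc[c.circ_id, sample])):
                o = int(rng.integers(anchor, L - anchor + 1))
                seq = mature[len(mature) - o :] + mature[: L - o]
                emit(sample, seq, "bsj")
            for pos, table, tag in (
                (donor_junction, counts.donor_linear, "lin_d"),
                (acceptor_junction, counts.acceptor_linear, "lin_a"),
            ):
                lo = max(anchor, pos - (len(tx_seq) - L))
                hi = min(L - anchor, pos)
                for _ in range(int(table.loc[c.circ_id, sample])):
                    o = int(rng.integers(lo, hi + 1))
                    seq = tx_seq[pos - o : pos - o + L]
                    emit(sample, seq, tag)

    # exonic background reads per gene
    for tx in annotation:
        gid = tx.gene_id
        if gid not in counts.genes.index:
            continue
        chrom_seq = genome[tx.chrom]
        big_exons = [e for e in tx.exons if len(e) >= L]
        if not big_exons:
            continue
        weights = np.array([len(e) - L + 1 for e in big_exons], dtype=float)
        weights /= weights.sum()
        for sample in counts.genes.columns:
            n = int(counts.genes.loc[gid, sample])
            choices = rng.choice(len(big_exons), size=n, p=weights)
            for idx in choices:
                e = big_exons[int(idx)]
                start = e.start + int(rng.integers(0, len(e) - L + 1))
                seq = chrom_seq[start : start + L]
                if tx.strand == "-":
                    seq = _revcomp(seq)
                emit(sample, seq, "bg")
    return reads


# --------------------------------------------------------------------------
# NanoString panels
# --------------------------------------------------------------------------

def simulate_nanostring(
    config: SimulationConfig, truth: TruthSet
) -> tuple[NanoStringTable, NanoStringTable]:
    """Simulate the circRNA CodeSet analog and the miRNA panel analog.

    Both tables share per-sample lane scale factors (recorded in truth),
    six positive controls on a concentration ladder, six negative controls
    at the background level, and probes with zero planted condition
    effect: seven reference probes in the CodeSet and two designated
    most-stable miRNA probes in the panel.
    """
    rng = np.random.default_rng([config.seed, 3])
    samples, condition, pairing = _sample_names(config.n_pairs)
    background = config.nanostring_background
    lane = {s: float(np.exp(rng.normal(0.0, 0.2))) for s in samples}
    truth.lane_factors = lane
    truth.nanostring_background = background

    pos_means = [20000.0, 5000.0, 1250.0, 312.0, 78.0, 20.0]

    def control_rows(rows, classes) -> None:
        for i, mean in enumerate(pos_means):
            rows[f"POS_{chr(65 + i)}"] = {
                s: _nb_draw(rng, mean * lane[s], 0.002) for s in samples
            }
            classes[f"POS_{chr(65 + i)}"] = "positive"
        for i in range(6):
            rows[f"NEG_{chr(65 + i)}"] = {
                s: int(rng.poisson(background)) for s in samples
            }
            classes[f"NEG_{chr(65 + i)}"] = "negative"

    def endogenous(mean_nl: float, mean_les: float, disp: float) -> dict[str, int]:
        return {
            s: _nb_draw(
                rng,
                (mean_les if condition[s] == LESIONAL else mean_nl) * lane[s],
                disp,
            )
            + int(rng.poisson(background))
            for s in samples
        }

    # ---- circRNA CodeSet analog -------------------------------------
    rows: dict[str, dict[str, int]] = {}
    classes: dict[str, str] = {}
    control_rows(rows, classes)
    scale = 8.0  # counts per junction-read unit for the CodeSet
    for c in truth.circs:
        rows[c.circ_id] = endogenous(
            c.nl_mean * scale, c.les_mean * scale, config.nb_dispersion
        )
        classes[c.circ_id] = "endogenous"
    biogenesis = {"ADAR": 1.7, "DHX9": 1.0, "FUS": 1.0, "QKI": 1.0, "HNRNPL": 1.0}
    for gene, effect in biogenesis.items():
        base = float(np.exp(rng.uniform(np.log(500), np.log(2000))))
        rows[gene] = endogenous(base, base * effect, config.nb_dispersion)
        classes[gene] = "endogenous"
    truth.reference_probes = [f"REF{i + 1}" for i in range(7)]
    for ref in truth.reference_probes:
        base = float(np.exp(rng.uniform(np.log(400), np.log(3000))))
        rows[ref] = endogenous(base, base, 0.01)
        classes[ref] = "reference"
    circ_table = NanoStringTable(
        counts=pd.DataFrame(rows).T[samples],
        probe_class=pd.Series(classes),
        condition=condition,
        pairing=pairing,
    )

    # ---- miRNA panel analog -----------------------------------------
    rows, classes = {}, {}
    control_rows(rows, classes)
    # panel counts sit well above background even for downregulated
    # probes, so background subtraction does not censor any candidate
    # and the balanced up/down tails stay balanced in the candidate pool
    for mid in truth.mirna_sequences:
        rows[mid] = endogenous(
            truth.mirna_nl_means[mid] * 50.0,
            truth.mirna_les_means[mid] * 50.0,
            max(config.nb_dispersion, 0.05),
        )
        classes[mid] = "endogenous"
    stable = ("miR-stable-1", "miR-stable-2")
    truth.designated_stable_pair = stable
    # the designated pair is planted as genuinely low-variance: abundant
    # (so counting noise is negligible) with tight technical dispersion
    for mid in stable:
        base = float(np.exp(rng.uniform(np.log(8000), np.log(16000))))
        rows[mid] = endogenous(base, base, 0.0005)
        classes[mid] = "endogenous"
    mirna_table = NanoStringTable(
        counts=pd.DataFrame(rows).T[samples],
        probe_class=pd.Series(classes),
        condition=condition,
        pairing=pairing,
    )
    return circ_table, mirna_table
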