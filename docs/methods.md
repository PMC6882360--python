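# Methods

This note records the algorithms, statistical conventions, and generator
design used by `circskin`, in pipeline order.

## Backsplice-junction detection (`bsj_detect`)

Reads are placed with two exact anchors of `anchor_length` (default 20)
nt taken from the read's ends and looked up in a k-mer index of the
genome. A read whose anchors map uniquely to the same chromosome and
strand in *reversed* genomic order is a backsplice candidate; anchors in
colinear order are linear placements and are discarded. The exact
breakpoint is refined by extending both anchors toward the middle of the
read; a candidate is kept only when

- the breakpoint is flanked by the canonical splice signal (AG upstream
  of the acceptor, GT downstream of the donor, on the annotated strand),
- the breakpoint ambiguity (number of equally consistent shifts) is at
  most the configured maximum,
- the genomic span is at most `max_span`.

Each detected junction carries per-sample supporting-read counts.
Linear donor/acceptor junction reads are counted by matching reads that
cross the corresponding forward splice junctions colinearly.

## Quantification (`circ_quant`)

- RPM = backsplice reads / total reads × 10⁶.
- Circular-to-linear ratio CTL = bsj / ((donor + acceptor)/2 + 1); the
  single pseudo count keeps circle-only loci finite.
- A circRNA is *detected* in a condition when at least one sample has
  ≥ 2 backsplice reads, and *high-abundance* when the condition's mean
  backsplice count is ≥ 5.
- Host transcripts are chosen by most exons contained within the
  backsplice span, ties broken by spliced length; a circle is
  splice-consistent when both backsplice ends coincide with exon
  boundaries of a single transcript.

## Differential analysis (`differential`)

Implemented from first principles and verified against SciPy to
≤ 1e−8 in p (measured ≤ 1e−14):

- Welch two-sample t and classical paired t.
- Wilcoxon signed-rank: exact null distribution for n ≤ 25 without
  zeros/ties, otherwise the normal approximation with tie correction
  and no continuity correction.
- Mann-Whitney U: exact null for tie-free samples with n·m ≤ 400,
  otherwise the normal approximation with tie and continuity
  correction.
- Pearson chi-squared without Yates correction; degenerate marginals are
  flagged instead of producing NaN p-values silently.
- Simple OLS with the slope F test (equivalent to the two-sided t test
  on the slope); `slope_ci95` gives the t-based confidence interval.
- Benjamini-Hochberg adjustment is available; the default pipeline
  reports raw p-values.

Counts are normalized with DESeq-style median-of-ratios size factors
estimated from the *gene* count table, and backsplice counts are divided
by these factors before testing. RPM is reported as a descriptive unit
but deliberately not used for differential testing: the global circRNA
downregulation plus downregulated host genes shrink the lesional library
total, so RPM inflates lesional abundances by a compositional bias of
roughly one third at the default parameters.

## Inverted Alu elements (`iae_analysis`)

For each circle, the nearest pair of oppositely-stranded Alu elements
with one member fully upstream and one fully downstream of the
backsplice is searched in two modes: any inverted pair with total flank
distance ≤ 2300 nt, and same-subfamily pairs within 10 000 nt (Alu
subfamily = AluJ/AluS/AluY name prefix). Total distance is the sum of
the two flank gaps. Association between IAE flanking and > 2-fold
downregulation uses the chi-squared test; flank distances between groups
are compared with Mann-Whitney.

## NanoString normalization (`nanostring_norm`)

The chain mirrors nSolver conventions: per-lane background subtraction
(maximum of the negative controls, floored at 1 before
log-transformation), positive-control normalization by the per-lane
geometric mean of the positive ladder (rungs that are not strictly
positive in every lane after background subtraction — the lowest rung
sits at background — are excluded), and reference normalization against
the geometric mean of chosen reference probes.

NormFinder models the log2 signal as probe + sample + group bias +
noise. Sample effects are removed by centering each sample on its
candidate average; per-candidate group bias d and intra-group sampling
variance v are estimated, the bias is shrunk by its estimated
signal-to-noise ratio, and stability = mean over groups of |d̃| + √v.
The best pair minimizes the same quantity computed on the average of the
two candidates' log profiles; the pair's intra-group variance is
measured empirically on the averaged signal but floored at the
independence value (v_i + v_j)/4, because apparent negative correlation
between two probes at n = 6 per group is overwhelmingly sampling noise
that a minimum over ~2000 pairs would otherwise cherry-pick.

Because the centering step transfers any *net* regulation of the
candidate panel onto every candidate as a common bias, NormFinder's
"zero-effect" designation is only recoverable when the panel has no net
regulation; the generator enforces this exactly (below). Even then, the
centering injects an irreducible common-bias noise of ≈ 0.02 log2 at
panel size ~60 and dispersion 0.05, so the designated pair loses to a
lucky endogenous probe in roughly 1 seed in 10–20.

## miRNA integration (`mirna_integration`)

Mature circRNA sequences are the concatenated exons of the chosen host
transcript inside the backsplice span (reverse-complemented for
minus-strand circles). The 8mer site of a miRNA is the reverse
complement of its positions 2–8 followed by `A`. Scanning is circular:
every start position of the circle counts once, including sites spanning
the backsplice junction; this equals a brute-force scan over all
rotations. The sponge score of a miRNA is Σ over circles of site count
× ΔRPM, with ΔRPM = mean lesional RPM − mean non-lesional RPM. miRNA
fold change and absolute expression difference are each regressed on the
sponge score with OLS and the slope F test; miRNAs without sites are
excluded.

## Synthetic-study generator (`synthetic_data`)

Defaults: 6 patient pairs, 200 genes, 100 circles, 60 panel miRNAs.
All randomness flows from `numpy.random.default_rng([seed, stage])`
substreams (stage 0 = genome/truth, 1 = counts, 2 = reads,
3 = NanoString); the same seed reproduces byte-identical outputs.

- Genome/annotation: multi-exon genes with canonical GT..AG introns;
  44% of circles get a planted flanking inverted Alu pair within
  2300 nt total distance, half of them same-subfamily.
- Circle regulation: lesional/non-lesional fold factors sit on a fixed
  lognormal quantile grid
  `circ_down_factor · 2^(spread · Φ⁻¹((i+0.5)/n))` (spread 1.5 log2
  units), randomly assigned to circles. The grid's median equals
  `circ_down_factor` (0.25) by construction, which is what the
  fold-change recovery criterion estimates, while the spread leaves
  ~25% of circles above 0.5 so the IAE 2×2 table is never degenerate.
- Host dependence: 30% of circles are host-dependent — their host gene
  shares the circle's factor — and each such down gene is mirrored by
  an inflammation-program gene planted up at exactly the reciprocal
  factor. Mirroring keeps the median-of-ratios size factors unbiased:
  one-sided differential contamination shifts the per-sample ratio
  median into a different quantile of the stable genes.
- Per-sample library factors (lognormal, σ = 0.15) multiply all
  sequencing count tables and are recorded in the truth so size-factor
  recovery is actually exercised.
- miRNA panel truth: 15% of miRNAs are planted up and 15% down in
  exactly reciprocal pairs; the remaining bulk effects are lognormal and
  mean-centered in log space per realization, so the panel's net log2
  regulation is exactly zero — the contract NormFinder's centering
  requires. Two designated stable probes carry zero condition effect
  and low dispersion.
- Counts are negative binomial with configurable dispersion; reads are
  emitted to match the count tables exactly (backsplice reads cross the
  junction with at least one anchor on each side).
- Optional coupling plants extra 8mer sites for one miRNA in the five
  most strongly downregulated circles and forces that miRNA up 3×; with
  coupling on it is the extreme point of the sponge-score scatter, with
  coupling off the regression slope is null.

## Limitations

- The detector requires exact anchor matches; sequencing errors are not
  simulated.
- The exact Wilcoxon/Mann-Whitney distributions are limited to the
  small-sample regimes used here; larger designs fall back to the
  normal approximation.
- NormFinder best-pair recovery is inherently ~90–95% per 20-seed block
  (common-bias noise of the centering step); this matches the stated
  recovery criterion but is not exact.
- The NanoString simulation shares the generator's truth rather than
  modelling probe-level chemistry.
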