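# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical and design choices behind `circlife`.

## Data model and conventions

All genomic intervals are 0-based, half-open (BED-style) internally. GTF
input is converted on read; the circRNA-annotation reader takes a
`one_based` flag because backsplice callers differ in their exported
convention. circRNA length is taken from the annotation's mature-length
column, not `end − start`: a multi-exon circle's mature length excludes
its internal introns, and the length filter is meant to act on the mature
molecule. Sample sheets allow `sex = NA` (the temperature experiment does
not stratify by sex) and arbitrary age grids.

## Normalization and filters

Size factors are median-of-ratios against a geometric-mean pseudo-reference,
computed on the circular and linear matrices stacked together (intronic
rows included only when the intron analysis is run) so both compartments
share one library-size estimate. Features not expressed in every sample
are ignored by the estimator; an all-disjoint matrix is an error advising a
pre-filter. Filtering happens before normalization by default (the
alternative order is a caller choice: the filter functions and
normalization are independent).

Two filter rules are implemented literally:

- aging: keep a circRNA iff mature length ≥ 50 nt AND (mean raw count ≥ 1
  within *every* age group OR some single sample has ≥ 10 reads);
- temperature: keep iff some condition has *all* replicates strictly
  greater than 3 counts.

The differing strictness (≥ 10 vs > 3) is intentional; each rule follows
its own stated wording. Quantile read shares are computed per replicate
and then averaged; ties in expression are broken by stable feature order,
assigning ties to the lower quantile, for reproducibility.

Ratios: `circ/linear` with the `all_reads` method excludes circRNAs whose
host is `intergenic`/`ambiguous`/`no_single_host`; the `junction_reads`
method substitutes 1 for a zero linear junction count, so the ratio equals
the circRNA count itself. Brain/head ratios substitute 1 for a zero head
count for the same reason.

## Negative-binomial GLM

The two-group NB GLM (log link, log size factors as offsets) is fit per
feature by vectorized IRLS; the group coefficient is the natural-log fold
change. Dispersions are per-feature method-of-moments on normalized
counts, pooled across the two groups and floored at 1e-8 (the Poisson
limit); no information is shared across features — parameter recovery, not
parity with any particular DE package, is the goal.

Numerical choices:

- **Wald reference.** The Wald statistic is referred to a t distribution
  with residual degrees of freedom (n − 2) rather than the normal. With
  the dispersion itself estimated from ~4 residual degrees of freedom, the
  normal reference is anti-conservative (simulated type-I error ~0.12 at
  nominal 0.05 with 3 vs 3 replicates and dispersion 0.1); the t reference
  restores calibration (~0.05). This is the standard small-sample
  correction used by quasi-likelihood DE frameworks. The cost is reduced
  power after multiplicity adjustment at small replicate numbers, which is
  why designs intended for discovery should use ≥ 5 replicates (see the
  temperature generator below).
- **Zero group means.** When a group mean is zero the reported log2FC uses
  a pseudo-count of 0.5 on the normalized group means to stay finite;
  features at zero in both groups yield an all-NA row. Coefficients are
  clipped at |ln FC| = 30 to keep separated fits finite.
- **Multiplicity.** Benjamini-Hochberg across all tested features per
  contrast.

DE calls are strict: `log2FC > 0.5` (or `< −0.5`) and `padj < 0.05`. The
temperature analysis chains contrasts: a circRNA DE between 29 °C and
18 °C is kept only if also DE versus pre-treatment in at least one arm,
and its direction versus pre-treatment is recorded.

PCA operates on log2(x+1), feature-centered and (by default) scaled
expression; both transform steps are configurable and recorded in the
result, since reasonable analyses differ here. Contributors are ranked by
squared loading.

## Trajectory clustering

Trajectories are per-circRNA fold changes to the first age point (baseline
column ≡ 1), clustered on the log2 scale, which symmetrizes increases and
decreases. Consensus k-means runs `n_rep` (default 500) k-means fits with
independent random initializations; consensus(i, j) is the co-assignment
frequency. The final partition cuts an average-linkage tree of
(1 − consensus) at k — the standard consensus-clustering consolidation; a
`final="best_run"` flag instead returns the lowest-inertia single run, for
the reading in which hierarchical clustering is a separate display step.

k is selected where the Rand index between the two sexes' independent
clusterings (restricted to shared circRNAs) increases the most, over a
default range of 2–10; a never-increasing Rand profile falls back to the
smallest k attaining the maximum, flagged as weak evidence. The plain
(unadjusted) Rand index is the primary statistic, with the adjusted Rand
reported as a secondary column. WSS and silhouette are advisory only.

## Genomic features

Feature extraction excludes sentinel-host circRNAs and genomic spans
< 20 nt. Member exons are exons fully contained in the circle interval
(backsplices join exon boundaries); partial overlaps are flagged, not
counted. "circ GC" is the GC of the concatenated mature sequence;
"average exonic GC" is the unweighted mean of per-exon GC — two distinct
quantities. Since "exon span" is ambiguous in the field, both the
member-exon count (`exon_span`) and the genomic span (`genomic_span`) are
emitted. Flanking introns are the gene-model gaps abutting the circle
boundaries, labeled 5′/3′ in transcript orientation (swapped on the minus
strand); a boundary that is not an annotated exon edge yields an NA flank
with a warning, not an error.

Cluster comparison: Kruskal-Wallis per feature; where p < 0.05, Dunn's
pairwise rank test with tie correction, adjusted by Benjamini-Hochberg
across the pairs of that feature (the adjustment method is configurable —
the convention is not standardized). Pairwise Z scores are reported as an
antisymmetric tile matrix with 0.05/0.01/0.001 star annotations.

## Splicing screen

ΔPSI is the difference of per-condition means. An event changes when
|ΔPSI| ≥ 15 percentage points AND the replicate [min, max] intervals of
the two conditions are disjoint; intervals are closed, so a shared
endpoint counts as overlap, and a single replicate forms a point interval.
The absolute value is used because inclusion and exclusion events are both
of interest. Fold-change/ΔPSI association uses Pearson correlation on
(log2FC, ΔPSI) — the conventional first choice for this diagnostic — with
Spearman as a secondary column; fewer than 3 matched pairs or zero
variance yields NA.

## Pulse-chase half-life model

The decay clock starts at day 10 (end of treatment): production during
the 10-day pulse is collapsed into the day-10 excess pool
`E₀ = B(10)·(FC₁₀ − 1)`, assuming the induced excess does not further
alter that gene's circRNA production. `B(t)` is an OLS line through
per-age mean normalized reads at ages ≥ 10 (male aging arm by default);
it must be positive over the evaluated range. FC₁₀ combines the RNA-seq
and qPCR day-10 estimates by arithmetic mean (equal weights; geometric
mean available). Evaluation days default to the qPCR collection ages (31,
52), with the model-grid days (30, 50) available via a flag.

Estimation minimizes Σ(log FC_pred − log FC_obs)² over h on a 400-point
log grid spanning [0.5, 1000] days, refined by bounded scalar minimization
in the bracketing interval. The estimate is infinite when the error is
non-increasing up to the upper bound and the closed-form no-decay model
fits at least as well. Two half-life fields are reported:

- `h_hat` — the raw continuous estimate (used for round-trip and recovery
  statistics);
- `h_reported` — collapses `h_hat` beyond the largest finite grid value
  (50 days) to infinity. With recovery measurements only 21 and 42 days
  after treatment, decay slower than ~50 days changes the observed fold
  change by less than typical qPCR noise (σ ≈ 0.1 on the log scale), so
  larger finite estimates are not experimentally distinguishable from no
  decay.

Estimates at the lower search bound are flagged "fast decay"; observed
fold changes above the no-decay prediction are flagged "model exceeded"
and reported as infinite rather than extrapolated. qPCR relative
expression is 2^(mean reference Ct − target Ct), the arithmetic mean of
reference-gene Cts being the geometric mean of their linearized
expression.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

- **Aging.** Six ages (0–50 days, 10-day spacing), two sexes sharing one
  truth, three replicates, NB counts with dispersion 0.1 (a conventional
  bulk-RNA-seq value; no dispersion estimate is available to emulate)
  around linear mean trajectories floored at 0.5. Five archetypes are
  planted: three increasing at clearly distinct rates (slopes 40, 12, 4
  normalized reads/day on a baseline of 100, i.e. roughly 21×, 7×, 3× over
  50 days — spanning the range of strongly age-accumulating circRNAs, with
  adjacent rates spaced comparably in log fold-change space, as in real
  data where accumulation rates form a continuum), one sharp developmental
  decrease (slope −3.8 on baseline 200) whose host mRNA and intronic signal
  co-decrease, and one flat cluster (baseline 150). Host coupling applies
  only to the decrease archetype; all other host/intron means are flat
  with age. Host mRNAs are 10× and intronic signal 0.5× the circRNA
  baseline.
- **Temperature.** Conditions pre/18 °C/25 °C/29 °C with five replicates
  (the exposure experiments collected three to five); lognormal baseline
  means (median 50 counts); the configured induced subset is multiplied by
  `pulse_fold` at 29 °C only.
- **Pulse-chase qPCR.** Fold changes from the closed-form decay model plus
  multiplicative lognormal noise (σ = 0.1), so zero-noise tables are exact
  fixed points of the estimator.
- **PSI.** Beta-distributed PSI (concentration 300 ≈ 3-point replicate
  scatter at mid-range PSI); changed events shift linearly with age by 30
  points at the last age, direction chosen to stay inside [5, 95]; events
  can be tied round-robin to circRNA flanks.
- **Genome fixture.** One random chromosome; 4–6 exons per gene with
  controlled per-gene GC, exon lengths 100–300 nt, introns 80–200 nt; each
  circRNA spans exons 2–3 so both flanking introns exist and are known.

What the generators do *not* emulate: shared dispersion structure across
features, GC/length biases in counting, batch effects, correlated
replicates, partial host-gene overlap of circRNAs, sequence motifs, or
isoform structure beyond one circle per host. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
noise models, not robustness to every artifact of real libraries.

## Problem sizes in the test suite

Tests validate each operation against independent oracles (brute-force
enumeration for the Rand index and GC, hand-computed closed forms for size
factors, decay fold changes and OLS, statsmodels GLM fits and pydeseq2
size factors as cross-checks) at the scales the analyses are designed for:
clustering recovery uses 200 circRNAs per archetype with 500 consensus
repetitions; GLM calibration uses 2,000 features; half-life recovery uses
500 noisy simulations per condition; the end-to-end study runs at a
reduced 60-circRNAs-per-cluster scale with 100 consensus repetitions.

## Known limitations

- Per-feature method-of-moments dispersion is noisy at 3 replicates; the
  t-referenced Wald test is calibrated but conservative after BH
  adjustment, so small designs favor sensitivity-limited DE calling.
- The decay model is single-compartment with age-constant stability and a
  linear accumulation baseline; it cannot represent age-varying turnover
  or saturating accumulation.
- The k-selection rule (greatest Rand increase) assumes the two sexes are
  biological replicates of the same cluster structure; strongly
  sex-dimorphic trajectories would mislead it.
- `select_events` treats replicate ranges as closed intervals; with many
  replicates the no-overlap condition becomes increasingly strict.
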