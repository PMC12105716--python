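# circlife

Analysis pipeline for circular RNA (circRNA) dynamics in the aging
*Drosophila* head: from backsplice-junction count matrices through
filtering, joint normalization, negative-binomial fold-change estimation,
consensus trajectory clustering, genomic-feature comparison, splicing
screens, temperature differential expression, and an exponential-decay
model that estimates circRNA half-lives in vivo from a temperature
pulse-chase.

circRNAs are covalently closed RNAs produced by backsplicing and are
quantified solely by reads spanning their head-to-tail junction. Because
they largely escape normal mRNA turnover, their levels in post-mitotic
tissue rise with age; whether that rise reflects stability or increased
biogenesis is the central question this kind of study asks. The package is
aimed at transcriptomics analysts who already have count matrices (circRNA
backsplice reads, linear host-gene reads, linear junction reads, intronic
reads) plus a sample sheet, and want a tested, reproducible implementation
of the downstream statistics. Read alignment, backsplice junction
discovery, and PSI calling are out of scope.

A first-class synthetic-data module generates every pipeline input with
known ground truth (planted trajectory clusters, a known temperature-induced
circRNA subset, pulse-chase fold changes under known half-lives, PSI tables,
and a genome/GTF fixture), so the whole pipeline is testable without any
download.

## Core models

**Normalization.** Median-of-ratios size factors computed jointly over
circular and linear (optionally intronic) counts: for sample *j*,
`s_j = median_f count(f, j) / geomean_f`, over features expressed in all
samples.

**Fold changes.** Per-feature negative-binomial GLM with log link and
`log s_j` offsets:

    y_fj ~ NB(mean = s_j · exp(β₀ + β₁·x_j), dispersion α_f)

with x the group indicator, α_f estimated by method of moments (floor
1e-8), and a Wald test on β₁ referred to a t distribution with residual
degrees of freedom. Differential expression: `|log2FC| > 0.5` and BH
`padj < 0.05`; temperature contrasts additionally require support against
the pre-treatment condition ("chained" rule).

**Trajectory clustering.** Per-circRNA fold changes to the first age are
clustered in log2 space by consensus k-means (500 random-initialization
repetitions aggregated into a co-assignment matrix, consolidated by
average-linkage hierarchical clustering). The number of clusters is chosen
where the Rand index between the male and female clusterings shows its
greatest increase; WSS and silhouette are reported as advisory.

**Half-life.** A 10-day 29 °C pulse creates an excess pool
`E₀ = B(10)·(FC₁₀ − 1)` over the 18 °C control, where `B(t)` is a linear
age-accumulation baseline fitted on ages ≥ 10 days. The predicted
29 °C/18 °C fold change during recovery is

    FC(t) = 1 + E₀ · 2^(−(t−10)/h) / B(t)

and the half-life `h` minimizes squared log-FC residuals against qPCR
fold changes at 3 and 6 weeks of recovery (fly ages 31 and 52 days).
Estimates beyond the largest finite grid half-life (50 days) are reported
as infinite (no detectable decay).

## Worked example

Run the full pipeline on one synthetic study:

```bash
circlife run --seed 5 --out study/
```

prints

```json
{
  "chosen_k": 5,
  "rand_vs_truth": 0.9895652173913043,
  "age_regression_r2": 0.9899235027349361,
  "n_temperature_de": 29,
  "halflife_h_hat": 16.136827129389168,
  "artifacts": 21
}
```

meaning: the cross-sex Rand rule selected 5 trajectory clusters and the
recovered partition agrees with the planted archetypes on 99% of circRNA
pairs; total normalized circRNA signal rises linearly with age (R² = 0.99,
mirroring the linear accumulation this analysis is designed to detect);
29 circRNAs pass the chained temperature DE rule (the study planted 30
induced ones); and the pulse-chase fit for the example target estimates a
half-life of ~16 days against a planted truth of 20 days under qPCR-level
noise. Each stage's table (normalized counts, trajectories, assignments,
diagnostics, features, ΔPSI, DE calls, half-life grid) is written under
`study/`.

Every stage is also exposed individually (`circlife simulate`, `normalize`,
`filter`, `de`, `cluster`, `features`, `splicing`, `halflife`, ...) and as
plain library functions (`circlife.counts_norm`, `circlife.diffexp`,
`circlife.clustering`, `circlife.halflife`, ...).

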