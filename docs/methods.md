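# Methods

## Data model

A lane is one sample's raw digital counts over a fixed probe set:
endogenous genes, housekeeping candidates, six positive controls on a
four-fold titration (128, 32, 8, 2, 0.5, 0.125 fM) and eight
target-free negative controls, plus two imaging attributes (percent of
attempted fields of view counted; binding density in spots/µm²). Lanes
assemble into a genes × samples count matrix tagged `raw`, `normalized`
or `log2`. The design crosses two binary factors (amyloid transgene ×
myeloid gene dose) with three pooled samples per cell (n = 12).

## Quality control

Four rules per lane, all tunable through `QCThresholds`:

| rule | statistic | default pass condition |
| --- | --- | --- |
| imaging | FOV counted (%) | strictly > 75 |
| binding density | spots/µm² | within [0.1, 2.25] inclusive |
| positive linearity | R² of log2 count on log2 fM | strictly > 0.95 |
| limit of detection | 0.5 fM probe count | > mean(neg) + 2·SD(neg), per lane |

The FOV rule is read literally as strict; the binding-density band is
inclusive. R² uses simple least squares on log2 counts, with a +0.5
offset applied only when a zero count would make the log undefined, so an
exact power-law titration scores exactly 1.

**Standard-deviation convention.** The sample (n − 1) SD is used
everywhere — LOD, background threshold, geNorm ratio SDs. The counts
involved are small samples, not populations, and one convention
throughout keeps thresholds comparable.

## Background

One pooled threshold: mean + 2·SD over all negative-control counts across
all lanes (a per-lane variant is available as
`background_thresholds_per_lane`). A gene is removed when its count falls
below threshold in strictly more than `obs_freq` (default 0.5) of samples
— at exactly half the samples the gene is kept. Controls are never
filtered.

## Housekeeping selection (geNorm)

For candidates *j*, *k*: `V_jk = SD_samples( log2(x_j / x_k) )` and
stability `M_j = mean_{k≠j} V_jk`. The gene with the largest M is removed
and M recomputed until the requested number (default 6) remains. Ties
break on gene name (lexicographically last removed first), making the
kept set deterministic. Zero counts are shifted by +0.5 before logs. The
pairwise-variation V-statistic stopping rule is deliberately not
implemented: the selection count is the user's call, matching how a fixed
housekeeping budget is chosen in panel studies.

## Normalization

Per lane *i*, two multiplicative factors:

1. positive-control factor `p_i = mean_lanes(Σ pos) / Σ pos_i` (on by
   default — the titration is present, so use it);
2. housekeeping factor `h_i = mean_lanes(g) / g_i`, where `g_i` is the
   geometric mean of the selected housekeeping counts after p-scaling.

Normalized values are returned as `log2(raw·p_i·h_i + 0.5)` with positive
and negative probes dropped. The +0.5 offset keeps logs finite at zero
counts; its bias is negligible above ~30 counts. Per-lane scaling of the
input is absorbed exactly up to one global log2 shift, which is why all
downstream statistics (differences, t statistics, PCs) are unaffected by
lane-scale noise.

## Differential expression

Two-group contrasts use the pooled-variance t-test on log2 expression
(log2FC = difference of group means, df = nA + nB − 2). With three
samples per group, zero within-group variance is reachable; the pooled SD
is then floored at 1e-8 and the gene flagged `degenerate` rather than
dropped. DEGs are called at unadjusted p < 0.05 — the convention for
these focused panel comparisons — with BH q-values reported alongside.
PCA is on per-gene centered, unscaled log2 data (samples as
observations); scaling is available by flag but off by default, since
count panels carry meaningful amplitude differences between genes.

## Pathway scoring

A pathway's per-sample score is the projection on the first right
singular vector of its centered log2 submatrix. Because every gene is
centered, scores sum to zero across samples by construction. The PC sign
is arbitrary, so scores are oriented by the sign of the sum of gene
loadings (an exact zero sum falls back to the correlation with the set's
mean expression); after orientation, raising every set gene in one sample
raises that sample's score. Sets with fewer than five measured genes are
skipped and reported — sparsely detected pathways produce unstable first
components.

## Gene set analysis

Per-gene t statistics come from the additive two-factor linear model
`log2 expr ~ A + B` over all 12 samples (df = 9); a univariate
single-factor alternative sits behind `adjust=False`. The directed global
significance score of a set is `sign(m)·sqrt(|m|)` with
`m = mean_g sign(t_g)·t_g²`; the undirected score drops signs and always
bounds the directed one in magnitude, with equality exactly when all set
t-statistics share one sign.

**Operating characteristics of the ±1.3 cutoff.** The null distribution
of the directed GSS depends on set size: Monte Carlo with independent
t₉ variates gives false-flag rates of ≈11% for 5-gene sets, ≈5% at 10,
≈2.4% at 15 and ≈1.3% at 20. The cutoff therefore behaves as a ≈5% test
for sets of about ten genes at this design's residual df, and is more
conservative for larger sets. The packaged calibration experiment
(`calibration.gss_null_flag_rate`) measures this through the full
pipeline — negative-binomial counts, housekeeping normalization,
background filtering — on no-effect panels partitioned into ten-gene
sets, and lands at ≈0.05.

## Cell-type profiling

A cell type's score is the arithmetic mean of its marker genes' log2
values per sample. Marker-set validity is a permutation QC: the statistic
is the mean pairwise Pearson correlation among markers; the null draws
random same-size sets (without replacement) from the measured non-marker
genes; the p-value uses the add-one estimator `(1 + #{null ≥ obs}) /
(1 + R)`, which is never zero and finite-sample valid. Pearson (not
Spearman) is used on log2 data. The mean pairwise regression slope is
reported descriptively but not gated — no numeric slope rule is
established. Single-marker sets return qc_p = 1 with a flag.

## Glial signatures

Seven amyloid-associated glial signatures ship with the package. The
17-gene plaque-induced set (PIGs) is the published panel intersection;
the other six (DAM 15, HM 9, MGnD 20, M0 25, DAA 15, OLIGs 30) are
synthetic stand-ins of the published sizes whose overlap with PIGs
follows the published decomposition (41% DAM/MGnD, 41% HM/M0, 12% DAA,
6% other) and whose remaining members are well-known genes of the
respective literature signatures. `curate_signature` rebuilds any of them
from a ranked reference (−log10 p thresholded from above; log2 FC
thresholded from above for up- and below for down-regulated lists),
preserving reference order and intersecting with the panel.

Overlap decomposition assigns each base gene to the first matching group
in the user-given order; integer percentages are reconciled to a 100
total by largest remainder. The composite amyloid-glial score is the
unweighted mean of the seven signature scores.

## Factorial statistics

The balanced 2×2 ANOVA uses the closed-form type-I decomposition
(identical to type-III under balance): cell, marginal and grand means
give SS_A, SS_B, SS_AB; the residual MS has df = n − 4. The closed form
exists so calibration can run tens of thousands of replicates; unbalanced
layouts fall back to a sum-coded type-III linear-model fit with a
warning. Fisher's PLSD compares group means with
`t = Δmean / sqrt(mse·(1/n₁ + 1/n₂))`, df = n − 4. Comparisons are
reported even when the omnibus test is non-significant — focused
comparisons and trends are part of this analysis style — with a
`protected` flag recording the omnibus state. Under a simulated global
null the pairwise test's type-I error at α = 0.05 is ≈0.045 over 10,000
replicates.

## Synthetic data generator

The generator emulates the *structure* of the study — not any real count
distribution. Per gene *g* and lane *i*:

- endogenous: count ~ NB(mean = 2^(b_g + Σ effects·x_i + s_i),
  size = 15), with baselines b_g ~ U(2, 11) log2 counts so a realistic
  ~15% of genes sit below background, and lane factors
  s_i ~ N(0, 0.15 log2);
- housekeeping: high-abundance (b ~ U(8, 11)) and nearly Poisson
  (size 300), with a per-lane stability deviation of 0.05 log2 for the
  six true housekeeping genes and 0.35 for four decoy candidates — the
  structure geNorm assumes and is meant to detect;
- negative controls ~ Poisson(5); positive controls ~ Poisson(40·fM·2^s_i),
  so positive-control normalization has signal.

The default effect template spikes activated microglia (+1.0), AD causal
risk (+0.8) and autophagy (+0.8) for the amyloid factor, and myelination
(+0.4) and lipid metabolism (+0.35) for the myeloid factor — a
qualitative mirror of the biology, chosen once for test realism. One root
seed spawns a panel-level stream (baselines) and one substream per lane,
so lanes are independent given the seed and runs are bit-reproducible.

What passing tests on this generator do **not** show: fidelity to real
nCounter noise (no lane-position effects, no probe-specific capture
efficiencies, no sex effects), nor correctness of the shipped stand-in
signature members beyond the published overlap structure.

## Calibration experiment sizes

The packaged experiments use: 1,000 no-effect panels of 200 genes for the
GSS null flag rate (ten-gene sets, both covariates); 10,000 replicates of
12 unit-normal values for PLSD type-I error; 200 full-size panels for
spike power (+1.5 log2FC on a 15-gene set, flagged in ~100% of
replicates); 50 panels for fold-change recovery (recovered mean within
±0.01 of +1.5). The reduced panel size in the null experiment keeps the
whole calibration under a minute without changing the per-set statistic,
which depends on set size and residual df, not panel width.

## Known limitations

- No mRNA-content (total-count/quantile) normalization alternatives and
  no batch correction.
- No negative-binomial or empirical-Bayes DE models; the pooled t on
  log2 data mirrors the panel-software convention.
- geNorm's V-statistic stopping rule is not implemented.
- Cell-type scores are relative abundance proxies; they are comparable
  across groups within a cell type, not across cell types.
- The exact DE model of the commercial analysis software is not
  documented; its p-values are not reproduced bit-for-bit, only the
  pipeline contract above.
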