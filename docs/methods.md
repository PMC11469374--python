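# Methods

This note records the models, estimators and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions that make results reproducible.

## Synthetic data model

A cohort is a genes × samples matrix of log2 expression

    x_gs = b_g + σ ε_gs + δ_{g,group(s)}

with per-gene baselines `b_g ~ N(7, 2²)` (log2 units), residual noise
standard deviation `σ` (`noise_sd`, default 0.5 — typical of bulk RNA-seq
log2 expression after normalization), and planted log2 fold changes
`δ` applied to non-control groups.  Effect magnitudes are |N(`effect_mean`,
`effect_sd`²)| with defaults 1.0 / 0.2, comfortably above the 0.26
call threshold so power studies measure the statistics rather than the
generator.  Defaults mirror the emulated study design: a control group
plus intoxication / withdrawal / abstinence stages, two sexes, 10 samples
per group per sex (cohort sizes for the rodent arms of such studies are
rarely published; 10 is a realistic self-administration cohort and is
configurable).

Cross-cohort structure is planted per gene as a concordance class:
`conc_up` / `conc_down` (same-sign effects in both cohorts), `disc`
(opposite signs), `unique_a` / `unique_b` (one cohort only), or `null`.
Class proportions are design parameters; a paired draw shares one truth
object so recovery can be scored exactly.

Modules use an equicorrelated latent factor: gene `g` in module `m` is
`√r f_ms + √(1−r) ε_gs` with one factor draw `f_ms` per module per
sample, giving exactly `r` expected pairwise correlation — analytically
checkable, and group-dependent (`r_control` vs `r_treatment` in the
module's named group) to plant connectivity gains and losses.

The ortholog map covers a configurable fraction of genes and uses
upper-case symbols in cohort a versus title-case in cohort b, so the
case-insensitive matcher is exercised on every run.  Biotype labels are a
seeded multinomial draw (default proportions 0.892 / 0.075 / 0.033 for
protein-coding / lncRNA / pseudogene, the biotype mix typical of a
DE transcript set in brain bulk RNA-seq); they affect summaries only.

Not emulated: count-level overdispersion and library-size effects
(the generator works directly on log2 expression), batch effects,
covariate structure (age, PMI, RIN), correlated effect sizes between DE
and module membership, and read-level artifacts.  Passing recovery tests
therefore demonstrates correctness of the statistics under a clean
Gaussian world, not robustness to those real-data complications.

All randomness flows through `numpy.random.Generator` objects seeded
explicitly; the pipeline derives stage seeds as
`sha256(master_seed:stage_name) mod 2^31` so any stage can be rerun
independently and reproducibly.

## Moderated differential expression

The two-group model is an unadjusted difference of means per gene
(log2FC), with pooled variance `s_g²` on `d = n_a + n_b − 2` degrees of
freedom.  Sex stratification is implemented as subsetting, matching the
pooled-then-split presentation of the motivating study design; covariate
regression and precision weights are out of scope.

Variance moderation assumes `s_g² | σ_g² ~ σ_g² χ²_d / d` with a scaled
inverse-chi-square prior `σ_g² ~ s0² d0 / χ²_{d0}`.  On
`e_g = log s_g² − ψ(d/2) + log(d/2)` this implies
`Var(e) = ψ'(d0/2) + ψ'(d/2)` and
`E(e) = log s0² + ψ(d0/2) − log(d0/2)`, which the estimator inverts:
`ψ'` is inverted by bisection to tolerance 1e-8, and an excess variance
≤ 0 yields `d0 = ∞` (complete shrinkage).  Zero sample variances are
floored at the 1st percentile of positive variances; an all-zero vector
is rejected as degenerate.  The moderated `t` uses the posterior variance
and `d0 + d` degrees of freedom; `d0 = 0` reduces exactly to the ordinary
`t`.

DE calls use unadjusted `p < 0.01` together with `|log2FC| > 0.26`
(≈ 1.2-fold), both strict, since that is the stated rule of the emulated
analysis; BH q-values are always reported and a flag switches calling to
`q` for users who prefer FDR-controlled calls.

## Signed RRHO

Scores are `sign(log2FC) · min(−log10 p, 300)`; the cap prevents
float underflow artifacts, zero log2FC takes positive sign, and ties are
broken by lexicographic gene id so orderings are total and deterministic.
The default stride is `⌊√N⌋` (the literature convention when no stride
is stated); stride 1 gives the exact map used by the oracle tests.

The split construction computes four quadrant grids.  For quadrant
(end_a, end_b), both lists are ordered from the stated ends and cell
(i, j) scores the overlap `k` of the two prefixes by the exact
hypergeometric upper tail `P(X ≥ k)`, evaluated through the log survival
function (never by subtraction from 1); cells with `k` at or below the
expectation `ij/N` store 0, so the map shows enrichment only.  Swapping
the signatures transposes the grids with down–up and up–down exchanged —
a property test guards this.  Per quadrant, the maximum cell, its
thresholds, and the genes in its prefix intersection are recorded; the
concordant-quadrant gene union is what downstream enrichment consumes.

## Co-expression networks

Adjacency is unsigned, `|cor|^β` (signedness is a free choice here; the
unsigned form keeps planted negative-correlation structure visible and is
the common default).  β is chosen as the smallest power in 1..20 whose
binned log–log degree distribution fits a declining line with R² ≥ 0.8,
falling back to the conventional 6.  TOM follows
`(Σ_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij)`.

Module detection clusters `1 − TOM` by average linkage with a **static
absolute height cut at 0.99**.  Noise-level TOM dissimilarities crowd
immediately below 1, so a quantile-of-merge-heights rule degenerates to
cutting at the root; the absolute cut cleanly separates planted blocks
(ARI 1.0 on the four-module benchmark) while pure noise fragments into
sub-threshold clusters and lands in grey.  Clusters under `min_size`
(default 30) are unassigned; modules whose eigengenes correlate above
`1 − merge_height` (default 0.15) are merged iteratively; surviving
modules are named by size rank from the standard color palette.  The full
dynamic tree cut is deliberately out of scope — the static cut is
deterministic and sufficient for planted-block recovery.

Eigengenes are the first right singular vector of the gene-standardized
module block, unit-norm over samples and sign-aligned with mean module
expression; kME is the gene–eigengene Pearson correlation.

The MI network bins each gene's samples into `⌊√n⌋` equal-frequency bins
and uses the plug-in MI estimate; the edge threshold can be calibrated
from permuted-sample MI (95th percentile).  DPI pruning marks, in every
triangle, the weakest edge if it is below `(1 − tolerance)` times both
others, and removes marked edges only after scanning all triangles — an
edge that is the strongest in every triangle containing it is never
removed.  Hubs are the top-k genes by intramodular MI degree (kME as
fallback when no edge list is available).  "Condition-specific hub" has
no standard operational definition; here it is a case-network top-k hub
whose control-network rank falls outside the top 2k — a rank-displacement
rule chosen so that identical networks yield none.

## Module differential connectivity

`MDC = Σ tril(A_case) / Σ tril(A_ctrl)` over the module's adjacency
submatrices (diagonal excluded), recomputed from each group's samples at
the globally chosen β (β is not re-tuned inside permutations, for
tractability).  Two permutation schemes address different nulls:
shuffled sample labels (are the two groups exchangeable for this gene
set?) and random same-size gene sets from the analyzed universe (is this
gene set special among peers?).  Each yields an add-one two-sided
p-value on |log MDC|, `p = (1 + #{|log r*| ≥ |log r|}) / (1 + B)`, never
exactly zero.  Each permutation draws from a stream derived from
(seed, permutation index), so estimates are nested in `B` and stable as
`B` grows.  The per-module `p_final` is the maximum of the two schemes —
the conservative conjunction, since no combination rule is standard —
with both components reported; BH runs across modules and calls require
`q < 0.05` together with the ratio's direction.

## Enrichment and cell scoring

Fisher/hypergeometric enrichment always takes an explicit background
(the analyzed-gene universe, never inferred from the collection); the
odds ratio is `ad/bc`, with 0.5 added to all cells only when the
denominator is zero (a zero overlap keeps its natural OR of 0), flagged
when applied.  The p-value is the same exact hypergeometric tail used by
RRHO, so the two modules share one oracle-tested primitive.

AUCell scoring truncates each cell's gene ranking at
`W = ⌊top_fraction · N⌋` (default 0.05; small enough to reward
front-loading, large enough to be stable for modules of tens of genes)
and integrates the module-gene recovery curve over the window.  The area
is normalized by the rectangle `W · min(|M|, W)`: a module packed at the
very top scores `1 − (|M|−1)/(2W)` (the unavoidable within-window ramp)
and a module entirely below the window scores 0.  Group comparisons use
the rank-sum test per cell type (AUC distributions are bounded and
skewed) with BH across cell types.

## Problem sizes

The validation suite and acceptance script run the simulation studies at
fixed sizes chosen to estimate each rate with useful precision on a
single CPU in about a minute: 200 null and 100 planted-gain MDC
simulations at 100 permutations per scheme, 600-gene module recovery,
5000-gene moderation recovery, 50 seeds for the sex-specific concordance
motif, and 100 Gaussian-chain runs for DPI.  Larger runs only narrow the
Monte Carlo error of the reported rates.

## Known limitations

* The two-group DE model carries no covariates; real post-mortem designs
  need them.
* Static tree cut and unsigned adjacency are simple defaults, not tuned
  reproductions of any published network; parameters are configurable and
  logged.
* The plug-in MI estimator is biased upward at small n; the permutation
  threshold compensates operationally but MI values are not debiased.
* ORA results depend entirely on the supplied GMT collections; no
  annotation databases ship with the package.
* The generator's Gaussian world understates the heavy tails and
  dependence of real expression data (see above).
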