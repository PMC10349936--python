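# Methods

This note records the models behind `tfredist`, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical decisions a maintainer would want written down.

## Count model and differential testing

Counts in features are negative-binomial: K ~ NB(μ, α) with
Var(K) = μ + αμ². Sequencing depth enters as per-sample size factors
s_j estimated by median-of-ratios: over features positive in every sample,
s_j = median_i(K_ij / geomean_i(K_i·)), rescaled to geometric mean 1.
This estimator assumes that differential features are either a minority or
direction-balanced. Strongly unidirectional change shifts the per-sample
ratio median and is partially absorbed into the factors (at 25%
one-directional features with |log₂FC| = 2 the absorbed shift is of order
0.3 log₂ units); this is a property of the normalization shared by the
standard tools, and the parameter-recovery tests therefore plant
direction-balanced effects.

Dispersions are estimated in three steps:

1. **raw**: α̂_i = max(floor, (v_i − m_i)/m_i²), with m_i the grand mean of
   normalized counts and v_i the within-replicate-group pooled variance
   (groups share condition and timepoint). Floor default 1e-8.
2. **trend**: OLS of log α̂ on log m over features with α̂ above the floor.
   Because the fit targets E[log α] while the tests need E[α], the
   intercept gets a smearing (retransformation) correction of half the
   residual variance.
3. **shrinkage**: log-linear blend exp((1−w)·log α̂_i + w·log trend_i). The
   trend weight w defaults to a precision ratio: the sampling variance of a
   log moment-dispersion with m residual degrees of freedom is approximately
   trigamma(m/2); the prior variance is the observed residual spread around
   the trend minus that sampling variance, floored at 0.05; and
   w = sampling/(sampling + prior). With 4 replicates per group this puts
   roughly 60% of the weight on the trend. A fixed weight can be supplied
   instead. The adaptive default exists because a fixed 50/50 blend leaves
   enough per-feature noise at n = 4 that the Wald test's type-I error rises
   to ≈0.086 at nominal 0.05, while with the true dispersion plugged in the
   test is calibrated almost exactly — the inflation is entirely dispersion
   noise, so the weighting is where the fix belongs.

The Wald test fits a per-feature NB GLM (log link, intercept + condition,
offset log s_j) by IRLS (statsmodels, max 100 iterations, deviance
tolerance 1e-8); log₂FC = β/ln 2, z = log₂FC/SE, p = 2(1 − Φ(|z|)). The
time-course LRT compares intercept + timepoint-factor against intercept
only, 2Δll ~ χ² with (T − 1) df. Features with all-zero counts, or
non-converged fits, get NA statistics, are logged, and are excluded from
the BH multiplicity count m. Because an LRT has no single effect size, its
reported log₂FC/SE are the treated-timepoint coefficient of largest
magnitude — this only feeds the directional classification.

Fold-change shrinkage uses a normal prior with moment-matched variance
τ² = max(0, var(β̂) − mean(SE²)) and posterior mean β̂·τ²/(τ² + SE²);
τ² = 0 collapses all shrunken values to zero. Classification at FDR
threshold f (default 0.1, the threshold the analyses downstream consume):
increased iff padj < f and log₂FC > 0; decreased for the mirror; everything
else, including NA, unchanged.

This module is deliberately *inspired by* the standard NB differential
tools rather than numerically identical to any: no outlier replacement, no
independent filtering, moment rather than Cox–Reid dispersions, normal
rather than apeglm priors. Downstream conclusions consume directional calls
at FDR 0.1, not the tools' internals.

## Motif scanning and prevalence

Scores are log₂ odds of pseudocount-smoothed position probabilities
(pseudocount 1e-3·background, renormalized) against a 0-order background.
P-values are exact under that background: each position's four possible
score contributions are discretized to bins of δ = 0.001 bit and the
per-position distributions convolved into the full score distribution,
whose survival function is the p-value (total mass checked to 1e-9).
Rounding per position accumulates at most L·δ/2 of score error for an
L-mer, so equivalence tests against exhaustive 4^L enumeration bracket the
exact tail within (L/2 + 1) bins; at δ = 0.001 bit that bracket is ~0.003
bit wide. Both strands are scanned (reverse-complement matrix), the better
strand kept per position, hits reported at p ≤ 1e-4 (FIMO's conventional
threshold). Windows containing non-ACGT letters are excluded via a −∞
sentinel.

A peak "has" a motif iff a hit center falls within summit ± 150 bp. The
window half-width is a configurable design choice (reported in outputs):
the source analyses say only "around peak summits", and 150 bp is
footprint-scale. Prevalence across peak classes is tested with Pearson χ²
without continuity correction, df = classes − 1; a degenerate table (no
peak, or every peak, containing the motif) returns χ² = 0, p = 1 with a
warning, and expected cells < 1 attach a warning.

## Interval geometry

Coordinates are 0-based half-open throughout; summits and TSSs are bp
points; chromosome names match exactly. TSS-to-peak distance is 0 inside
the interval, else min(|TSS − start|, |TSS − (end − 1)|), ties to the
leftmost subject then name; genes with no same-chromosome subject are
flagged with infinite distance and excluded (but counted) in CDF
comparisons. The distance-to-anchor analysis uses summit-to-summit
distances instead — both conventions appear in the source analyses, for
different figures. Two-sample KS uses the asymptotic Kolmogorov p with
effective n = n_a·n_b/(n_a + n_b); a seeded permutation alternative exists
for small samples. Distances are absolute (unsigned); whether the original
analysis signed them is unknown.

## Kinetic clustering

Profiles are size-factor-normalized counts averaged over replicates per
timepoint, then z-scored per feature (zero-variance features dropped and
logged). Replicate averaging precedes standardization because the traces of
interest are per-timepoint. Clustering: 1 − Pearson correlation distance,
Ward linkage, tree cut at k; automatic k takes the smallest k whose
silhouette is within 5% of the best over 2..8. Clusters under min_size
(default 15) merge into the nearest centroid by correlation distance, or
are discarded on request. Rows are sorted by feature id before clustering
so results are independent of input order. The exact internals of the
clustering package used in the original analyses are not public; all knobs
here are explicit and recorded in outputs, and the cluster count is a
reported choice, not a reproduction target.

## Redistribution grouping

A second TF's per-peak log₂FCs are grouped (a) by the classes of genes
whose TSS lies within 100 kb of the peak summit — a peak near several
classes joins each by default, with an exclusive nearest-TSS mode — and
(b) by summit-to-summit distance to the nearest anchor peak, default bins
[0, 10 kb), [10 kb, 100 kb), [100 kb, ∞). The original bin edges are not
published; these spans express "proximal" versus "distal" and are
configurable and written to outputs. Each group's mean log₂FC is tested
against zero with a two-sided one-sample t; an all-zero group is reported
as the exact null (t = 0, p = 1) rather than 0/0. Annotation follows the
figure convention: `***` iff p < 10⁻³, `N.S.` iff p > 0.1. Rank-sum
comparisons use exact enumeration for ≤ 20 pooled values without ties, an
exact permutation of the U statistic with ties, and the tie- and
continuity-corrected normal approximation otherwise.

## Regulon activity (dES) and classification

Sign conventions are the most error-prone point and are pinned in
`tfredist.enrichment`'s docstring and its tests: the regulon's *activated*
half = genes up upon depletion = the TF's repressed targets; the
*repressed* half = genes down upon depletion = the TF's activated targets.
Per patient, genes are ranked by cohort z-score (x − cohort mean)/cohort
sd, descending, gene id as tie-break, zero-variance genes dropped. Each
half gets a weighted KS enrichment score: hits step up by
|w|^p / Σ_hits|w|^p, misses down by 1/(N − |S|); ES is the signed extreme
of the running sum and always lies in [−1, 1]; weight exponent p defaults
to 1 (0 gives the classic KS statistic used by several oracle tests).
Significance is a gene-label permutation p: random same-size gene sets on
the same ranking, p = (1 + same-sign null ES at least as extreme)/(1 +
same-sign nulls), 1000 permutations and α = 0.05 by default — the original
criterion is unstated, so the default is simply explicit and reproducible.
dES = ES(up half) − ES(down half). Class high requires ES_up < 0 and
ES_down > 0, both significant (an active repressor holds its repressed
targets down and its activated targets up); low is the mirror; otherwise
intermediate. High-activity patients therefore sit at the negative end of
the dES ranking, and recovery tests check |Spearman| against the latent
activity. NES normalization is not applied before ranking patients.

## Survival and growth

Kaplan–Meier estimation and the unstratified, unweighted logrank test are
delegated to lifelines; both are verified against first-principles
implementations in the tests (product-limit by hand; O−E/V for two
groups). The growth model is ln N = β₀ + β₁·day + β₂·treated +
β₃·day·treated versus the reduced ln N = β₀ + β₁·day; the treatment main
effect is included even though only the interaction is tested, because
omitting it would confound the intercepts. F = ((RSS_r − RSS_f)/2)/(RSS_f/
df_f); noiseless fixtures drive both RSS to rounding level, so differences
below ~1e-12·Σy² are treated as exactly zero (F = 0, p = 1). Doubling
times are ln 2/rate and are invariant to the log base.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a config (including its seed); each
draws from its own RNG stream derived from the master seed by a fixed
label, so adding a generator never perturbs another's output.

The landscape places ~2000 accessibility peaks (spacing 3 kb, width
400 bp) on one synthetic uniform-background chromosome; 25% are planted
increased and 10% decreased with |log₂FC| ~ N(2, 0.5), matching a
repressor whose loss mostly opens chromatin. Increased peaks are mostly
primary (full effect by 30 min); 40% are secondary with onsets of 4 or
24 h and background-level motif content, which is what makes the
increased-class motif prevalence decay across later classifications.
A GATA-like 10-mer is planted around 80% of primary increased summits vs
20% elsewhere; a nuclear-receptor half-site around 60% of both directional
classes vs 20% of unchanged — the prevalence contrasts the source analyses
report. The synthetic PWMs (0.95 consensus probability per position) are
in-repo stand-ins for database matrices, which are not redistributable;
ten informative positions are needed for strong matches to clear a 1e-4
score p-value. Anchor-TF peaks sit at 90% of primary increased peaks (5%
elsewhere); half the second-TF sites are planted within 800 bp of an
anchor with log₂FC ~ N(+0.8, 0.3), the other half ≥ 200 kb away with
N(−0.8, 0.3) — the planted redistribution. Activated genes' TSSs land
0.5–5 kb from primary increased peaks, repressed genes' TSSs near the
distal second-TF sites, unchanged genes uniformly across the peak region.
Counts are NB with lognormal baselines (log-mean 5, log-sd 1), lognormal
size factors (log-sd 0.2), dispersion 0.05, six timepoints
(0, 30, 60, 120, 240, 1440 min; 0 = vehicle) × 4 replicates — the study's
time-course design.

The cohort draws latent activity a ~ N(0, 1) per patient; depletion-up
regulon genes are shifted −β·a and depletion-down genes +β·a (β = 2) on
unit-normal expression noise, and survival is exponential with hazard
0.01·e^{γ·a} per month (γ = 1) under independent exponential censoring
(0.005/month) capped at 360 months. The expression-shift signs are chosen
so that high latent activity produces the high classification — an active
repressor keeps its repressed (depletion-up) targets low — and a worse
hazard; with the opposite signs the generator would contradict the
classification rule it is meant to exercise. Growth tables are
N₀·e^{r·day}·lognormal(0, 0.1) with N₀ = 12500 cells, days 0–14 (the
enumeration design), control rate 0.35/day (≈2-day doubling, typical for
the cell line) and treated rate 0.25/day.

Not emulated: read-level artifacts (fragment sizes, insertion bias, GC,
mappability), peak calling, overlapping/nested peaks, chromosome
structure beyond one synthetic contig, inter-gene correlation in cohort
expression, informative censoring, and batch effects. Passing tests
therefore demonstrate the statistics are implemented correctly and recover
planted effects under the assumed models — not that those models capture
every property of real libraries.

## Numerical choices and problem sizes

GLM fits: IRLS, 100 iterations max, 1e-8 deviance tolerance,
non-convergence → NA + log entry. Dispersion floor 1e-8. Score DP bins
0.001 bit. Permutation p-values are deterministic given a seed and bounded
below by 1/(1 + n_perm). Ties everywhere break on identifiers so outputs
are order-independent. The test-suite simulations use 2000 features for
null calibration, 500 + 500 planted features for fold-change recovery,
200-patient cohorts with 100-gene regulon halves, and 50–100 repeated runs
for the power checks — sizes at which every calibration bound and recovery
band is resolvable in about a minute of compute; the acceptance script
uses the same defaults in a single pass.

## Known limitations

- No Cook's-style outlier handling or independent filtering; heavy
  contamination of a feature's counts will reach the tests directly.
- Median-of-ratios composition bias under strongly unidirectional change
  (see above).
- The LRT's reported effect size is a summary of the largest timepoint
  coefficient, not a model-based trajectory effect.
- Exact rank-sum enumeration is only used up to 20 pooled observations.
- The asymptotic KS p is anti-conservative for very small samples; use the
  permutation mode there.
- `patient_activity` recomputes a full permutation null per patient and
  regulon half; ~200 patients × 1000 permutations is seconds, but cohorts
  of tens of thousands of patients would want a shared-null approximation.
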