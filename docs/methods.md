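# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical choices and the known limitations of `progressionkit`.

## Somatic calling: permutation χ² on 2×3 allele-count tables

For each site we form the 2×3 table of (ref, alt) read counts in germline,
t1 and t2.  Under the null that all three samples share one allele
fraction, the conditional distribution of alt counts given all margins is
multivariate hypergeometric; we draw `n_perm` such reallocations (default
10 000, seedable) and report

p = (1 + #{χ²_perm ≥ χ²_obs}) / (1 + n_perm),

with ties counted as ≥.  The +1 correction keeps p strictly positive and
makes the p-value valid (slightly conservative).  A site is called somatic
when p < 0.001 **and** the germline alt fraction alt/(alt+ref) is < 0.10;
the germline filter removes inherited heterozygous and homozygous variants
regardless of p.  Table-level calls spawn one RNG stream per site from the
seed, so results do not depend on row order.

Note on asymptotics: the conditional permutation null is a lattice
distribution.  On a balanced 300-read table its p-value differs from the
continuous χ² approximation by up to a few hundredths (e.g. 0.288 vs
0.264); the implementation agrees with an independent Monte-Carlo
permutation oracle within sampling error, and with the asymptotic χ² only
to ~0.03.  Tests assert both statements separately.

## Drift testing and classification

Allele-frequency change between t1 and t2 uses the two-sided Fisher exact
test (sum of hypergeometric probabilities ≤ that of the observed table) on
deep-amplicon counts, followed by Benjamini–Hochberg FDR at 0.05.  FDR is
applied **within each patient**: classification is per patient, so the
error rate that matters is per patient's set of validated sites.  Direction
comes from the allele-fraction point estimates; exact ties carry no
directional evidence and count toward neither direction.

Classification from (n_up, n_down) significant sites: evolving (≥1, ≥1),
expanding (≥2, 0), static (n_up + n_down ≤ 1).  The (0, ≥2) quadrant is
not covered by the three-way scheme; it is reported explicitly as
`contracting` (an option folds it into `static`) rather than silently
absorbed.  Per-patient summaries include the median |ΔAF| among significant
sites and the fraction of tested sites that changed.

No minimum absolute allele-frequency change is required beyond statistical
significance; the per-site |ΔAF| is reported so downstream consumers can
impose one.

## sCNA grouping

Segments from both time points are merged per patient by single-linkage on
genomic gap: same chromosome, gap ≤ `merge_distance` (default 1 Mb — wide
enough to absorb segmentation jitter, narrow enough to keep focal events
apart).  A group present at both time points counts once per patient.
Groups are labeled by overlap with a bundled coordinate table (hg19) of the
four recurrently altered CLL loci — 11q (q arm of chr11), trisomy 12
(whole chromosome), 13q (q arm), 17p (p arm, TP53) — kept as configuration
data, not code.

## Cell-composition deconvolution and adjustment

Bulk leukemia samples are unsorted blood mononuclear cells, so beta values
mix leukemic B cells with residual NK/T/neutrophil signal, and tumor load
typically *rises* between the two draws.  Composition is estimated per
sample by constrained least squares against a marker-CpG reference panel R
(markers × 5 cell types):

min ‖R·w − β‖²  s.t.  w ≥ 0, Σw = 1.

With five cell types the program is solved **exactly** by enumerating all
31 supports of the simplex and solving each equality-constrained KKT
system; no iterative QP and no tolerance tuning.  The simplex constraint
(sum exactly 1, rather than ≤ 1) treats the five types as exhaustive and
stabilizes the downstream regression.  A rank-deficient reference matrix is
rejected.

Adjustment regresses each CpG's betas (OLS, across samples) on an intercept
plus four of the five proportions — Neutrophil is dropped, fixed, because
the five sum to one — and keeps grand mean + residual, clamped to [0, 1].
With identical compositions the regression explains nothing and betas pass
through unchanged; re-adjustment is a no-op to 1e-10 away from the clamp.

Caveat: when the planted/true progression effect is correlated with the
composition shift (t2-only effects alongside t2-higher tumor load), part of
the effect is absorbed by the regression.  On the default synthetic cohort
this attenuates recovered effect sizes by roughly a quarter to a third
while removing the much larger composition-driven drift; the paired test
operates on the adjusted values, so its discoveries are conservative with
respect to this collinearity.

## Progression-CpG discovery

Per CpG, per-patient (t1, t2) betas are paired and the two-sided Wilcoxon
signed-rank test is applied to the deltas: zeros dropped (signed-rank
convention); exact null when the non-zero n ≤ 25 with untied magnitudes;
otherwise the normal approximation with continuity correction and average
ranks.  CpGs with fewer than 6 complete pairs or all-zero deltas are
flagged untested (p = 1, excluded from FDR).  BH-FDR runs across tested
CpGs; `significant` means q < 0.05; direction is the sign of the median
paired delta.

Scores: the **B-cell score change** is the mean signed beta change over
B-cell-specific marker sites, each site oriented (+/−) so that rising
B-cell load raises the score; the **progression score** is Σ|Δβ| over the
progression-associated CpGs (cumulative deviation).  Both are score
definitions of this package: the mean oriented change is the simplest
statistic monotone in tumor-load change, and the cumulative deviation is
the natural per-patient magnitude summary over a fixed CpG set.

## Enrichment

*Peak windows.*  A probe at 1-based position p is near a peak when its
0-based interval [p−1−w/2, p−1+w/2+1) intersects a peak, i.e. the probe
base lies within w/2 bp of peak sequence (default w = 200: "within 100
bp").  The boundary is inclusive at exactly w/2 and exclusive one base
further, tested explicitly at both edges.  Strand is ignored throughout.
Enrichment is the upper-tail hypergeometric probability.

*Gene sets.*  Methylation arrays give probe-rich genes more chances to
contain a significant CpG.  A gene is a "hit" when ≥1 of its probes is
significant; the null distribution of per-set hit counts is built by
resampling the observed number of hit genes without replacement with
probability proportional to probe count (Efraimidis–Spirakis Gumbel top-k
sampling, seedable), and p = (1 + #{null ≥ obs})/(1 + n_resamples).  With
equal probe counts this reduces to the plain hypergeometric (verified in
tests).  An explicit resampling null was chosen over the Wallenius
approximation: same bias correction, no analytic approximation.

*Published lists.*  Fixed CpG/gene lists are compared by a 2×2 Fisher
exact test over an explicit universe; a platform-restriction list (e.g.
probes shared with an older array) is intersected first.  The universe is
an input because published comparisons differ in what they condition on.

## B-cell development comparison

Group means of naive B cells, memory B cells and the first CLL time point
are differenced pairwise; |Δ| ≥ 0.10 ("±10%") flags a CpG as differing.
Progression CpGs (and their H3K27me3-flagged stratum) are tested for
over-representation among differing CpGs by the hypergeometric tail.
Direction concordance is the percent of overlapping CpGs whose progression
delta and group-mean delta share a sign (zero deltas excluded from the
denominator).  Sample clustering restricted to the progression CpGs uses
average-linkage on Euclidean distance — fixed defaults, since nothing in
the analysis depends on the tree beyond the nearest-reference calls, which
use mean distance to the naive vs memory reference samples.

## Synthetic cohort model

*Genetic.*  Each patient carries 2–9 subclones with Dirichlet-distributed
prevalences and 26–80 heterozygous diploid variants (~50% truncal, the
rest assigned uniformly to subclones).  Expected alt fraction at time t is
purity_t × prevalence_t / 2.  Depths are Poisson around the configured
mean with floor 1 (the emulated designs state coverage ranges, not a
distribution): ~120× for exome discovery, ~850× for amplicon validation;
counts are binomial.  Germline sites are emitted at alt fractions exactly
0 / 0.5 / 1.0.  Planted dynamics by category — evolving: one subclone
gains 0.25 prevalence from another; expanding: purity rises 0.15 (from
U(0.70, 0.80)); static: identical fractions and purity.  Category mix
defaults to (0.26, 0.26, 0.48).  Clones are independent (no phylogenetic
nesting): the classification operates on marginal prevalence shifts, so a
tree constraint would not change what is being tested.

*Methylation.*  Five cell-type profiles share a bimodal Beta(0.4, 0.4)
base with N(0, 0.05) between-type divergence, clipped to [0.02, 0.98];
250 marker CpGs (50 per type) get a 0.8-beta cell-type contrast.  Samples
are mixtures: B fraction U(0.75, 0.90) at t1, drifting up by U(0, 0.08) at
t2 — the tumor-load confounding the adjustment must remove — with the
remainder Dirichlet-split across the other four types.  Progression
effects are planted at 1% of CpGs (never markers), at the second time
point only: increases with probability 0.77, magnitudes
Beta(2, b)-distributed on [0.005, 0.095] with b chosen so the median is
0.029.  H3K27me3 flags are drawn at background rate 0.20 and at planted
CpGs at the odds implied by a planted odds ratio of 3.  Noise is Gaussian
(sd 0.02, the scale of array replicate noise) and betas are clamped to
[0, 1].  Naive/memory reference panels reuse the B-cell profile: memory
differs from naive at the planted progression CpGs in the planted
direction (plus 300 unrelated CpGs in random directions), so developmental
concordance is recoverable by construction.

What the generator does **not** emulate: sequencing error in germline
reads, CNV–VAF interaction, probe type I/II chemistry, batch effects,
spatially correlated methylation, or biological heterogeneity of planted
effects across patients (every patient receives the same planted delta).
Passing recovery tests therefore demonstrate the statistical machinery is
correct and calibrated under the generative model — not that real cohorts
of this size would yield the same power.

## Problem sizes and determinism

Test and demo cohorts are scaled for quick iteration: recovery tests use
60 patients (genetic) and 27 patients × 6000 CpGs (methylation);
calibration uses 1e5 null permutation tables at n_perm = 1999 (the
smallest count that can resolve p < 0.001 under the +1 correction) and 200
null drift cohorts; the CLI demo uses 20 patients × 3000 CpGs.  All
generators and Monte-Carlo procedures take explicit seeds; given a seed,
cohorts, permutation p-values and pipeline outputs are bit-identical
across runs.

## Known limitations

- The permutation χ² p-value is conservative for sparse tables (discrete
  null, +1 correction); at germline alt fraction exactly 0 and high depth
  it is powerful, but power at 75× exome depth for subclonal variants is
  limited — by design, the validation/drift stage runs at ~850×.
- Composition adjustment attenuates effects collinear with tumor-load
  change (above); two-step "estimate then regress" also ignores
  uncertainty in the composition estimates.
- The ±10% difference rule and the 10% "large change" drift threshold act
  on point estimates of group means; no uncertainty is propagated.
- Locus labels use arm-level coordinate windows; they identify recurrent
  loci, not minimally deleted regions.
- `contracting` leukemias (≥2 falling, none rising) have no counterpart in
  the three-way scheme; downstream summaries report them separately unless
  folded.
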