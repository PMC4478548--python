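# Methods

This note documents the models behind `polymap`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want spelled
out.

## Intensity model and genotype calling

Two-channel signals (X, Y) are reduced to polar coordinates
theta = (2/π)·atan2(Y, X) ∈ [0, 1] and R = X + Y. All cluster
structure of interest lives on theta (the allelic contrast); R is used
only as a signal floor: samples with R below `r_floor` (default 0.5,
with simulated clusters near R = 1 and null-allele failures near
R = 0.1) are uncallable. Real data should be scaled so genuine
clusters sit near R ≈ 1, or `r_floor` adjusted.

Per marker, theta of callable samples is modelled as a 1-D Gaussian
mixture with k ∈ {1, 2, 3} components, initialised deterministically
from theta quantiles (no random restarts, so runs are reproducible)
and fitted by scikit-learn's EM. k is chosen by BIC, with an extra
component accepted only when it improves BIC by more than
`bic_margin` (default 6, "strong evidence" on the usual scale). The
margin exists because truncation at the [0, 1] edges skews single
clusters enough for an unpenalised BIC to split them occasionally.
Genotypes are maximum-posterior assignments; a call is withheld (NC)
below `posterior_min` (default 0.85). Call frequency bins follow the
observed four types: < 0.5 failed, [0.5, 0.99) deviant,
[0.99, 1) near-complete, 1 complete; the (0, 0.5) gap is assigned to
"failed" by convention and 0.99 is inclusive on the left.

## Separation score S

GenTrain, the commercial cluster-quality statistic, is proprietary; S
is this package's open surrogate and is calibrated, not claimed equal,
to it. For adjacent fitted components the Ashman separation is
D = |μ₂ − μ₁| / sqrt(2(σ₁² + σ₂²)), squashed to D/(D + D₀), and S is
the minimum over adjacent pairs (1 for a single cluster). D₀ = 1.875
makes the canonical diploid-like marker — homozygotes at 0.05/0.95,
heterozygote at 0.50, cluster sd 0.03 — score exactly 0.80. S is
monotone in every pairwise gap and invariant to the theta mirror
θ → 1 − θ (allele relabelling).

## Marker classification

Order of decisions per marker:

1. **failed** — no usable fit or call frequency < 0.5;
2. **intergenomic** (homeo-SNP) — ≥ 95% of called inbred samples
   heterozygous. This check precedes the single-cluster rule because
   a homeo-SNP *is* a single tight heterozygous cluster at θ ≈ 0.5.
   The 95% threshold tolerates a little calling noise around "appears
   heterozygous in all lines";
3. **monomorphic** — one fitted component, no wider than an assay
   cluster (`max_single_sd`, default 0.05 on theta);
4. **polymorphic** — everything else, with the pattern bin taken from
   S: ≥ 0.60 → pattern 3 (diploid-like), 0.30–0.59 → 4, 0.21–0.29 →
   5, < 0.21 → 6. A homozygote component within 0.1 of θ = 0.5 marks
   the shifted two-locus geometry of pattern 4 whenever S ≥ 0.30; the
   gate matters because compressed patterns 5/6 also place their
   homozygotes near 0.5. Pattern-6 markers can optionally be demoted
   to failed (`demote_pattern6`), mirroring how such assays are
   usually handled in production cluster files. The bin edge overlap
   in the source bins (0.21–0.29 vs < 0.20) is resolved by assigning
   [0.20, 0.21) to pattern 5.

**Compressed constellations.** Patterns 5 and 6 are defined by S bins
that force adjacent clusters ~1–1.6 σ apart, which a free
three-component mixture cannot resolve from a few hundred samples —
BIC rightly prefers k = 1 or 2, and the raw fitted S is biased upward.
Two measures make automated binning workable where the original
workflow fell back on manual curation: (a) when the selected model is
visibly under-resolved (any component broader than `max_single_sd`, or
a k = 2 fit whose own S < 0.60), the pattern is binned on a forced
k = 3 EM with mixture weights fixed at the Mendelian 1:2:1 of a
segregating genotype triple, which removes two barely identifiable
parameters; (b) the S of that fit is bias-corrected by a parametric
bootstrap (simulate from the fitted model, refit with the same
estimator, report 2·S_fit − mean S_boot over B = 4 replicates, seeded
internally for determinism). The Mendelian-weight assumption is exact
for F2-type samples and approximate for mixed germplasm panels; it
affects only pattern binning, never the genotype calls, which always
come from the BIC-selected model. Per-marker assignment between
patterns 5 and 6 retains roughly a ±1-bin uncertainty — that is a
property of the statistics, not the implementation.

## Linkage mapping

**Recombination fractions.** For each marker pair the 3×3 joint
genotype counts feed an EM estimator of the F2 codominant two-point
likelihood; the double-heterozygote cell mixes parental
(probability (1−r)²/2) and recombinant (r²/2) phase and contributes
its expected recombinant count each iteration. LOD =
log₁₀ L(r̂)/L(0.5); the test of r = 0.5 is a boundary LRT whose null is
a 50:50 mixture of a point mass at zero and χ²₁. The all-pairs path
computes the nine count matrices as one-hot matrix products and runs a
single vectorised EM, so a 520-marker genome (135k pairs) takes
seconds.

**Grouping** is single-linkage closure over pairs with adjusted
p ≤ α (default 0.05) and LOD ≥ 3. The p-value is Bonferroni-adjusted
for the number of pairs examined by default: a genome-wide search at a
raw per-pair 0.05 — or even a bare LOD 3 — admits enough spurious
links among 10⁵ pairs for transitive closure to fuse chromosomes.
`GroupingConfig(adjust_for_tests=False)` restores the raw criterion.

**Ordering** minimises the sum of adjacent recombination fractions
(SARF). Identical columns collapse to bins first; groups of ≤ 6 bins
are solved exactly by enumeration (this small-case solver doubles as
the test oracle), larger groups by greedy seriation from the
most-linked pair refined with 2-opt segment reversals plus single-bin
reinsertion until no move improves. Positions are cumulative Kosambi
distances of adjacent r̂ (capped at r = 0.4999). Group orientation is
free up to reversal.

**Cleaning** iteratively removes, among markers with more than
`max_singletons` (default 2) singleton double recombinants (nearest
non-missing flanks agree with each other but not with the marker), the
marker whose exclusion most shortens the group, stopping when no
candidate shortens it. With markers a few cM apart and hundreds of
individuals, genuine double crossovers can legitimately exceed the
default threshold, so cleaning is meant for dense maps or clearly
corrupted markers. **Framework reordering** fixes the relative order
of markers shared with a trusted map and inserts the rest at their
SARF-minimising positions, warning if the result is longer.

**Crossovers and bins.** Crossovers per individual per group are
genotype transitions in map order (A↔H or H↔B = 1, A↔B = 2), skipping
missing codes; individuals exceeding `outlier_multiple` (2×) of a
group's mean are flagged but not silently dropped — at 20 markers per
group, count noise makes the 2× rule fire on ordinary individuals, so
exclusion is left to the caller. Recombination bins merge map-adjacent
markers whose columns are compatible (missing = wildcard) with the
running bin consensus. **Segregation distortion** is the 2-df χ²
against 1:2:1 (codominant F2), with a heterozygote-deficit flag and
the favored parent (A = female) per marker, and a summary with the
distorted fraction and female:male favored ratio.

## Synthetic data

The generators produce exactly the structure the analyses assume: what
passing tests show is that the algorithms recover their own model, not
that real arrays obey it.

* **Intensity patterns.** Defaults (theta means / sds): pattern 1 —
  one cluster at 0.05; 2 — one heterozygous cluster at 0.50; 3 —
  0.05/0.50/0.95, sd 0.03 (the S = 0.80 calibration marker); 4 —
  0.10/0.30/0.50, sd 0.03 (shifted; homozygote at 0.5); 5 —
  0.42/0.50/0.58, sds 0.03/0.08/0.03 (true S = 0.261, mid pattern-5
  band); 6 — 0.45/0.50/0.55, sds 0.03/0.08/0.03 (true S = 0.181).
  The broader heterozygote sd in the compressed patterns reflects a
  het cloud blending several loci between tight homozygote clusters.
  Cluster R ~ N(1.0, 0.1); null-allele failures draw R ~ N(0.1, 0.04)
  and uniform theta, so they sit below the calling floor. Weights are
  1:2:1. No quantitative noise model for NormR exists to copy, so
  these are calibration choices, all exposed on `PatternSpec`.
* **Panel composition** (when simulating a whole array's worth):
  12% failed, 16% pattern 1, 10% pattern 2, 38/14/6/4% patterns 3–6 —
  echoing the observed array mix, where roughly an eighth of markers
  fail, a quarter are monomorphic or intergenomic, and well-separated
  patterns dominate the polymorphic remainder.
* **F2 populations** are Markov walks: per interval, a gamete
  recombines with probability inverse-Kosambi(interval cM),
  independently across intervals (no crossover interference — a
  chi-square interference model is out of scope). Distortion is
  induced by viability rejection sampling with per-genotype weights;
  missingness is i.i.d. Truth records genotypes, component of origin,
  null failures and true crossover counts per individual per group.
* **Inbred panels** draw each marker's minor-allele frequency from a
  user-supplied law on [0, 0.5], lines homozygous apart from a
  residual-heterozygosity rate.

Real arrays additionally show between-sample intensity scaling,
batch effects, cluster rotation in (theta, R), aneuploid and haploid
profiles, and germplasm structure; none of these are simulated.

## Problem sizes and runtime

The test-suite and acceptance-script simulations use the study-scale
conditions: 500-marker × 200-sample panels for classification
recovery; n = 1000 × 100 replicates for recombination-fraction
recovery at r ∈ {0.05, 0.10, 0.25}; a 26-group genome (20 markers per
135-cM group, n = 118, matching an interspecific F2) for map
reconstruction; 10,000 markers × 200 individuals for the distortion
type-I calibration. Everything runs in about a minute each on one CPU;
the vectorised pairwise EM is what keeps the 135k-pair step cheap.

## Known limitations

* Pattern 5 vs 6 assignment is intrinsically noisy (see above); status
  (polymorphic) is reliable, the bin less so.
* The two-point EM assumes codominant ABH data; dominant markers are
  out of scope.
* Ordering is two-point (SARF), not multipoint likelihood; for very
  short groups with noisy r̂ the SARF optimum can differ from the true
  order even when found exactly.
* kb/cM figures inherit the uncertainty of the assumed subgenome
  physical sizes; they are reported, not error-propagated.
* The intergenomic rule needs inbred samples; a panel of F1s would
  classify ordinary SNPs as homeo-SNPs.
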