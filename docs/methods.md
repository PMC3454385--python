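# Methods

## Statistical model and procedure

The pipeline treats continuous brain amyloid burden (average cortical
[¹¹C]-PiB uptake, relative units) as the endophenotype and asks which
plasma analytes carry information about it beyond five demographic
covariates: age at plasma draw (years), sex (male = 1, female = 0),
years of education, *APOE* ε4 allele count (0/1/2) and the signed gap in
days between PET scan and plasma sample.

**Partial Spearman screening.** All variables — analyte, burden and
every covariate — are replaced by their ranks (average ranks for ties)
and the partial Pearson correlation of the ranked analyte and burden
given the ranked covariates is computed by least-squares
residualization. The two-sided p-value uses t = ρ√((n−2−k)/(1−ρ²)) on
n−2−k degrees of freedom (k covariates). This rank-all-then-partial
convention matches the standard partial-correlation implementations and
makes the statistic invariant under strictly monotone transforms of any
single variable. Benjamini–Hochberg step-up adjustment is applied with
m equal to the full panel size (146 by default) even when only the
significant rows are carried forward, because all panel members were
tested. The adjusted values are floored at the raw p to protect the
q ≥ p invariant against floating-point rounding in p·m/rank.

**Redundancy reduction.** Screened analytes (raw p < α, default 0.05)
are clustered by complete-linkage agglomeration on the signed
correlation distance d_ij = 1 − ρ_ij, ρ_ij being the pairwise partial
SRC given the same covariates; anti-correlated analytes are maximally
distant (d up to 2). The agglomerator is a deterministic naive O(m³)
implementation: ties in the minimum inter-cluster distance are broken
toward the lexicographically smallest member-index pair. Cuts are
taken per cluster count k (equivalent to cutting between consecutive
merge heights), so the sweep over groupings is finite and exhaustive.
Within each cluster the representative is the analyte with the smallest
screening p, ties broken by larger |ρ| then name — a documented choice;
exact ties are not resolved by the underlying method description.

**Regression and validation.** Analyte predictors are divided by their
sample standard deviation (n−1 denominator) without mean-centering, so
each analyte has equal influence while raw intercept comparability is
retained. Scaling is computed once on the full sample before
cross-validation by default, replicating the original workflow; a
`per_fold_scaling` flag recomputes it inside each fold for a
leakage-free variant. For each k the design is the five covariates plus
the k representatives; leave-one-out predictions are obtained exactly
through the hat-matrix identity ŷ₍ᵢ₎ = yᵢ − eᵢ/(1−hᵢᵢ) (verified
against naive per-subject refits to 1e−10), and the LOO CV R² is the
squared Pearson correlation between the n LOO predictions and observed
burden. This is deliberately *not* 1 − PRESS/SST: it is the definition
the analysis validates. The chosen k maximizes CV R², ties resolved
toward fewer analytes (parsimony).

**Permutation null.** Burden is permuted uniformly across subjects B
times with the design fixed (covariates enter unpermuted), the CV R²
recomputed each time, and p = #{permuted ≥ observed}/B. The count/B
convention (p can be exactly 0) is the default because a reported
permutation p of 4×10⁻⁵ at B = 100,000 implies an unshifted count; an
`add_one` flag gives (count+1)/(B+1). A property worth knowing: the
squared-correlation statistic has a heavy null tail at small n and
small p (near-constant LOO predictions make the correlation unstable —
the null 99th percentile of CV R² at n=71, p=5 is ≈ 0.37), so
permutation power against moderate signals is intrinsically limited at
n ≈ 71 and grows quickly with n. The test suite verifies calibration
(type-I rate inside the 99% binomial envelope at B=99) and power at
n=150 where it is essentially 1.

**Classification.** Observed and LOO-predicted burden are dichotomized
at a fixed threshold (default 1.5; values exactly equal to the
threshold count as negative, since the rule is "positive iff > 1.5").
Sensitivity = tp/(tp+fn) over actual positives, specificity =
tn/(tn+fp) over actual negatives; an empty actual class raises because
the corresponding rate is undefined.

**LMG importance.** The full-data model R² is decomposed across
predictors by the LMG score — the Shapley value of sequential R²
contributions over all p! orderings — computed exactly by subset
enumeration: share_j = Σ_{S⊆P∖{j}} s!(p−s−1)!/p! · [R²(S∪{j}) − R²(S)].
Each subset's R² is solved from the centered Gram matrix. Enumeration
costs 2^p fits and is capped at p = 20 (≈10⁶ fits, well under a minute);
the amyloid model of interest has 18 predictors. Shares are
non-negative and sum to the full R² (asserted to 1e−8 on every call).

## Group-difference tests

Cohort summaries report per-group median and IQR (linear-interpolation,
type-7 quantiles — the IQR values depend on this convention) with a
tie-corrected Kruskal–Wallis χ² p for continuous characteristics, and
counts with a Monte-Carlo contingency-table p for categorical ones:
n_mc tables are sampled uniformly conditional on the observed margins
(Patefield algorithm) and p = (1 + #{tables at most as probable as
observed})/(n_mc + 1), the add-one estimator guaranteeing p > 0.
Ordering is by conditional table probability with an R-style rounding
tolerance; the reported statistic is −log of the observed table's
conditional probability.

## Synthetic cohorts

The generator emulates the structure of a restricted plasma/PET cohort:

* **Amyloid burden**: two-component Gaussian mixture, low mode
  N(1.3, 0.10²) and high mode N(2.05, 0.35²), positive-class weight
  49/71 ≈ 0.69 — matching the observed bimodality and class split.
  In `match_counts` mode the components are truncated at the 1.5
  threshold and sampled to hit the 49/22 split exactly (weighted
  Gumbel-key sampling without replacement preserves the ε4 gradient).
* **ε4 link**: each ε4 allele shifts the high-burden mixture *weight*
  up by 0.3 (clipped to [0.02, 0.98]); the weight route preserves
  bimodality, and the default size makes an ε4-only linear model reach
  a predictive R² near 0.1, the order of magnitude the analysis
  conditions assume.
* **Covariates**: age ~ N(75, (11/1.349)²), education ~ N(16,
  (5/1.349)²) floored at 6, sex Bernoulli(48/71), scan gap exponential
  with median 21.5 days, ε4 counts multinomial (34, 30, 7)/71 —
  medians/IQRs matching the cohort the analysis is designed for.
* **Planted analytes**: 16 signals with target |partial SRC| drawn
  uniformly in [0.24, 0.31], 12 negative and 4 positive. Each is built
  on the Gaussian-copula score g = Φ⁻¹(F(burden | ε4)) of the burden
  within its ε4 stratum, as latent = r·g + √(1−r²)·noise with
  r = 2 sin(πρ/6) (the exact Gauss-copula Spearman↔Pearson relation);
  large-n calibration is within ±0.03 of target. Latents are emitted
  as raw concentrations 10^(loc + 0.2·latent) — or linearly for the
  log-exempt analyte — so the I/O transform stage is exercised.
* **Redundant blocks**: designated signals get noisy latent copies
  (within-block correlation 0.6–0.75, a modelling choice; the source
  material gives no within-panel values), producing the correlated
  clusters the reduction step collapses.
* **Secondary phenotypes**: CSF Aβ₁₋₄₂, hippocampal volumes,
  entorhinal thicknesses, MMSE and ADAS-cog 13 are weakly linked
  (|ρ| 0.12–0.19) to designated analytes, with 5% missingness.
* **Ground truth** records the planted names, target correlations,
  block memberships, mixture component labels, and `true_r2` — the
  construction's predictive ceiling, estimated by OLS of burden on
  ε4 + the planted latents in an independently seeded n=20,000
  reference sample.

What the generator does **not** emulate: assay measurement-error
models, plate/batch effects, longitudinal visits, realistic analyte
marginal distributions, or correlation between covariates. Passing
recovery tests therefore demonstrates that the pipeline's inference
machinery is correct under its own assumptions, not that the markers
generalize to real cohorts.

## Numerical conventions and degenerate inputs

* Ranks: average ranks for ties throughout.
* Rank-deficient designs raise, listing the collinear columns;
  leverage-1 LOO folds raise rather than divide by ~0.
* A constant variable after ranking, an all-identical Kruskal–Wallis
  sample, a zero contingency margin, a zero-variance analyte column,
  and an empty complete-case set all raise with named offenders.
* Transform state is flagged on the table; a second log-transform
  raises instead of silently re-logging.
* Reports are byte-reproducible: a single seed drives simulation,
  Monte-Carlo table sampling and permutations through spawned
  substreams; floats are written with shortest round-trip formatting
  and no timestamps enter report files.

## Problem sizes used in the checks

The default test suite and the acceptance script run at deliberately
modest sizes chosen to make the statistical properties they assert
well-powered: oracle-equivalence checks at n ≤ 80, calibration at 200
replicates × B = 99, pipeline recovery at n = 400 over 10 seeds, and
the study-scale run at n = 71 with B = 100,000 permutations.

## Known limitations

* The screen's BH correction at the study scale (n ≈ 71) rarely
  survives multiple testing — exactly as with the restricted data the
  analysis mirrors; the pipeline reports both raw and adjusted p.
* Full-sample unit-SD scaling before LOO leaks a small amount of
  information across folds; it is the replicated convention, and the
  leakage-free flag quantifies the difference.
* The best-k sweep selects on the same data the permutation test then
  evaluates, so the chosen model's permutation p is mildly optimistic;
  the null-cohort pipeline test bounds the practical effect.
* The identity of QC-excluded analytes is cohort-specific; the
  exclusion registry ships empty and must be user-supplied.
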