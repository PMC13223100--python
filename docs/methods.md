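# Methods

## Two-sample MR on summary statistics

The package estimates the causal effect of an exposure (genetically
predicted gene expression, or a circulating metabolite) on a binary disease
outcome from two independent sets of summary statistics. Each instrument j
contributes an exposure effect b_Xj (SE s_Xj) and an outcome log-odds effect
b_Yj (SE s_Yj), aligned to a shared effect allele. The identifying
assumptions are the usual instrumental-variable ones: the variants are
associated with the exposure (enforced by the significance and F filters),
independent of confounders (justified by random allele assortment), and
affect the outcome only through the exposure (probed, not guaranteed, by the
sensitivity statistics).

### Harmonization

Variants are matched between datasets by identifier; a chromosome/position
disagreement warns rather than errors because public summary statistics
frequently disagree on genome build. When the outcome reports the opposite
effect allele, the outcome beta's sign is flipped. Palindromic variants
(A/T, C/G) carry no strand information in their alleles; they are retained
only when both allele frequencies exist and fall on the same side of the
ambiguity band — both below `palindromic_maf` or both above
1 − `palindromic_maf` — and dropped as ambiguous otherwise. The default
`palindromic_maf = 0.42` is the conventional ambiguity bound; nothing in the
analyses here is sensitive to values in the 0.30–0.45 range because the
synthetic generators emit non-palindromic alleles. Multi-allelic and indel
records are rejected at read time (v1 restriction).

### Instrument selection

Defaults follow standard pipeline settings: P < 5×10⁻⁸ significance,
greedy clumping at r² < 0.1 within a 10,000 kb window (window measured
center-to-center on base-pair position; the distance convention is a design
choice since only the thresholds are standard), per-SNP F = (β/SE)²
strictly above 10, and proxy substitution at r² strictly above 0.8 when an
instrument is missing from the outcome. Clumping is deterministic: ties in
p-value break on the lexicographically smaller variant id, so permuting the
input order cannot change the result. Proxy substitution adopts the proxy's
outcome beta and SE unchanged and relies on the harmonization step for
allele concordance; r² carries no phase sign, so sign correction from LD
phase is out of scope.

### Estimators

* **Wald ratio** (single instrument): β̂ = b_Y/b_X with first-order SE
  s_Y/|b_X|. A second-order option adding b_Y²s_X²/b_X⁴ exists but is off
  by default — at F > 10 the correction is below 10% of the variance.
* **IVW**: inverse-variance weighted mean of the ratios with weights
  w_j = b_Xj²/s_Yj². The default is the multiplicative random-effects
  model — fixed-effect SE inflated by max(1, √(Q/(k−1))) — because the
  heterogeneity level of the screened exposures is unknown a priori; the
  inflation floor of 1 prevents anti-conservative deflation under
  homogeneity. Fixed-effect mode is selectable.
* **MR-Egger**: pairs are oriented so b_X ≥ 0, then b_Y is regressed on b_X
  with weights 1/s_Y² and a free intercept. The slope estimates the causal
  effect under InSIDE (direct effects independent of instrument strength);
  the intercept with its t(k−2) test measures directional pleiotropy. Both
  SEs carry the max(1, √(Q_egger/(k−2))) inflation.
* **Weighted median**: ratios sorted with cumulative weight fraction
  p_j = (S_j − w_j/2)/S_k, linear interpolation at p = 0.5; consistent when
  at least half the weight is on valid instruments.
* **Weighted mode**: argmax of a weighted normal-kernel density over the
  ratios on a 512-point grid spanning the ratio range; bandwidth
  0.9·min(sd, iqr/1.34)·k^(−1/5) times a user factor (default 1). When all
  ratios coincide the bandwidth is zero and the common ratio is returned.
* Bootstrap SEs for median/mode are parametric — resample (b_X, b_Y) from
  normal(b, s), recompute, take the SD over n_boot = 1000 draws (explicit
  seed required by the pipeline layer).
* Ratio-based p-values use the normal distribution; Egger uses t(k−2).
  P-values are floored at 1e-300 so they remain in (0, 1].

### Sensitivity

Cochran's Q with df = k−1 (heterogeneity), the Egger intercept test
(directional pleiotropy), and leave-one-out IVW, flagging omissions that
flip the sign of the estimate or push it outside the all-instrument CI.

## Screens and multiplicity

Each screen runs the full selection chain per exposure and applies a
Bonferroni threshold α/n_tests where n_tests counts *feasible* exposures
(those with enough instruments); the denominator actually used is written to
every output and to the run log, since infeasibility handling is a reporting
choice. The candidate-gene screen permits single-instrument Wald ratios; the
cell-type and metabolite screens require at least three instruments, which
also gates the sensitivity analysis. Tiers: significant (below the family-
wise threshold), suggestive (nominal α only), null, infeasible. No FDR
control is offered — Bonferroni plus nominal tiers is the study design.

## Two-step mediation

Step 1 estimates exposure→mediator with the exposure's instruments; step 2
estimates mediator→outcome with the mediator's own instruments (not
conditioned on the exposure — this is two-step MR, not multivariable MR).
Indirect effect β1·β2; Delta SE √(β1²SE2² + β2²SE1²); z, two-sided normal p
and a normal-approximation CI; proportion mediated = indirect / total, where
the total is the exposure→outcome IVW estimate. Proportions with indirect
and total effects of opposite sign fall outside [0, 1] and are reported
verbatim with a `sign-discordant` flag rather than truncated. A leg with no
usable instruments yields an `infeasible` row, never a pipeline failure.

## Classical tests (stats_kit)

All test statistics are computed from first principles; scipy supplies only
distribution tails (normal, χ², t) and rank assignment. Policy choices:

* Contingency tables: Fisher's exact test for 2×2, Pearson χ² without
  continuity correction otherwise. This policy reproduces every verifiable
  published p-value of the clinical stage (0.007, 0.012, 0.026, 0.021,
  0.084, 0.397, 1.000).
* Two-sided Fisher uses the point-probability method — the sum of
  hypergeometric probabilities of all tables (with the observed margins)
  whose probability does not exceed the observed table's, compared at
  relative tolerance 1e-7. A zero margin gives the degenerate p = 1.
* Rank tests (Mann–Whitney U / Wilcoxon rank-sum, signed-rank,
  Kruskal–Wallis) use average ranks with tie-corrected variances and normal
  or χ² approximations; the Mann–Whitney test applies a 0.5 continuity
  correction by default. Exact enumeration is implemented only as a test
  oracle. At the smallest sizes (n ≈ 10) the approximation tracks the exact
  permutation null to about 0.01 on average with individual deviations up
  to about 0.017 — identical to the reference asymptotic implementations.
* Spearman correlation is the Pearson correlation of average ranks with a
  t-approximation p-value; zero rank variance yields NaN with a flag.
* Survival: product-limit Kaplan–Meier estimator over distinct event times
  and the two-group log-rank test with hypergeometric variance, referred to
  χ²(1).

## Spatial stage

Each spot carries deconvolved cell-type fractions (validated to sum to 1
within 1e-6) and a non-negative normalized expression value; normalization
is treated as upstream. The dominant type is the argmax fraction (ties break
lexicographically); a spot is malignant iff its tumor-cell fraction is
strictly positive — a deliberate knife-edge rule, so a fraction of 0.001 is
malignant. Section summaries give per-dominant-type mean expression,
z-scores across the type means using the population (n) standard deviation,
malignant/non-malignant means with standard errors and a Wilcoxon rank-sum
comparison, and spot-level Spearman correlations of expression against
every fraction plus the pairwise fraction correlation structure. Degenerate
cases (single dominant type, constant expression, empty region) set flags
instead of failing; spots with missing expression are dropped per section
with a logged count.

## Clinical stage

IRS = staining intensity (0–3) × positive-cell proportion (0–3), integer
sub-scores enforced; patients with IRS ≥ 6 form the high-expression group.
Table-1-style output tests each categorical variable with the shared
contingency policy and age with Mann–Whitney; overall survival is time from
surgery to death from any cause, censored at last follow-up, compared by
log-rank between the two expression groups using only (time, event, group).
The packaged 60-patient fixture is synthetic: the real per-patient data are
unpublished, so covariates are assigned independently within each expression
group to match the published per-variable group-wise margins — sufficient
for every single-variable contingency test to reproduce exactly, but
carrying no joint-covariate or survival information (its follow-up times are
placeholders).

## Synthetic generators

All generators are pure functions of (seed, config), built on numpy's
PCG64.

* **Summary-statistics pairs**: true exposure effects b_Xj ~ N(0.15, 0.05²)
  observed with SE 1/√(2·maf·(1−maf)·n) at maf ~ U(0.05, 0.5); outcome
  effects θ·b_Xj + α_j with per-variant direct effects α_j drawn balanced
  (InSIDE) or tied to instrument strength (InSIDE violation). Defaults
  emulate the source-cohort scale of the study design: an exposure panel of
  n = 30,000 (blood cis-eQTL scale) and an outcome effective size of
  n = 15,000 (biobank case-control scale); the default true effect 0.173 is
  the primary association's published magnitude, used as the recovery
  target. Binary-outcome effects are generated directly on the log-odds
  scale — the form the outcome GWAS reports — rather than through
  individual-level simulation; adequate for estimator testing and fast.
* **Mediation chains**: the exposure's instruments affect the mediator
  through β1 and the outcome through direct + β1β2; the mediator's own
  instruments affect the outcome through β2, so the true mediated
  proportion β1β2/total is known by construction. Defaults (β1 = −0.2,
  β2 = −0.0865, direct = 0.1557) give a true proportion of 0.10,
  mirroring the ~10% mediation the study design targets.
* **Spatial sections**: half the spots (configurable) lie in a malignant
  region with Dirichlet(4, 1, …, 1) fractions favouring tumor cells; the
  rest have an exactly-zero tumor fraction. Expression =
  1.0 + enrichment × tumor fraction + N(0, 0.3), clipped at 0.
* **Cohorts**: IHC sub-scores from a categorical mixture (default ≈ 45%
  high-expression), exponential survival with a group hazard ratio, and
  independent exponential censoring.

What the generators deliberately do not emulate: genome-wide variant
counts, realistic MAF spectra or LD maps, winner's-curse selection of
instruments, sample overlap between exposure and outcome cohorts, spatial
autocorrelation between neighbouring spots, and joint dependence among
clinical covariates. Passing tests therefore demonstrate correctness of the
estimators and calibration of their inference under the stated models, not
robustness to those real-data complications.

## Problem sizes

The calibration suites use 500 replicates for IVW recovery (k = 100
instruments), 1000 for its null rejection rate, 2000 for the
Egger-intercept type-I error (k = 30), 500 chains for mediation coverage,
10⁵ Monte-Carlo draws for the Delta-SE check, 400-spot sections for
enrichment and 500 seeded 200-spot sections for the null-uniformity check,
and 200 cohorts of n = 60 for log-rank power — sizes chosen so each study's
Monte-Carlo error is well inside the tolerance it is checked against while
the whole suite completes in well under a minute of simulation time.

## Known limitations

* No MR-PRESSO, Steiger filtering, colocalization or multivariable MR.
* LD matrices are inputs; the package never computes LD from genotypes.
* Proxy substitution ignores LD phase (r² is unsigned).
* The weighted-mode grid spans only the observed ratio range; a mode at the
  boundary is reported at the boundary grid point.
* The log-rank power of a 60-patient cohort at hazard ratio 2.5 with
  ~60% events is ≈ 0.75 (Schoenfeld approximation, confirmed by
  simulation); studies of that size should not expect 80% power.
* Exact rank-test enumeration is exponential and used only at n ≤ 10.
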