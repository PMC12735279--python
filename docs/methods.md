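# Methods

This note records the statistical model behind each pipeline stage, the
conventions fixed where several defensible choices existed, what the
synthetic cohort generator does and does not emulate, and known limitations.

## Panel and dosage conventions

A panel row designates, per variant, an *effect allele* and its published
odds ratio. Genotypes are stored as effect-allele dosage (0/1/2, `NaN` for a
missing call). The effect allele is the published risk-orientation allele,
not the minor allele: protective variants (e.g. *F5* rs4524, *TGFB2*
rs57615042) keep their published effect allele and enter the risk score with
a negative weight β = ln OR < 0. This makes the score's "number of risk
alleles" coding consistent with signed literature weights. Deletion alleles
are stored as the token `-`; VCF input is reduced to this minimal-allele
convention by stripping the shared leading anchor base, and sites whose
REF/ALT orientation is flipped relative to the panel are re-oriented
(dosage → 2 − alt count) with a logged note. Matching is by rsID, since the
panel is rsID-keyed; the genome build tag is informational only.

The bundled panel carries the 38 printed variants of the source cohort's
association table; the text of that study counts 39 loci, so the file format
deliberately accepts additional rows rather than resolving the discrepancy.

Missing dosages are never imputed at read time; each stage declares its own
policy (below).

## Quality control

* **Call rate** — exact fraction of non-missing calls per variant; a variant
  passes only if strictly greater than the threshold (default 0.95, i.e.
  "> 95%").
* **Hardy-Weinberg** — the exact conditional test: given the observed allele
  counts, the p-value sums the probabilities of all heterozygote counts no
  more probable than the observed one. Computed in controls only (deviation
  in controls indicates genotyping artefact; in cases it may be signal).
  The exact test rather than the χ² approximation because several panel
  variants are rare in this population; the default α is 0.05 and p ≤ α
  fails, with α = 0 disabling the filter. Probabilities are evaluated in
  log space (gammaln) and renormalized, with a 1 + 10⁻¹² tolerance on the
  "no more probable" comparison to make ties robust to rounding.
* **Replicate concordance** — fraction of cells non-missing in both runs
  that agree, for inter-assay reproducibility checks.

## Association

Allelic tables count alleles (each subject contributes two); dominant and
recessive models count subjects (carrier vs non-carrier; homozygous-effect
vs other). Fixed conventions, chosen for bit-reproducibility where the
field's software differs:

* χ² without Yates continuity correction, used when every expected cell
  count is ≥ 5 (the conventional cutoff); otherwise the two-sided Fisher
  exact test by the point-probability method (scipy's convention).
* Woolf CI on the log scale where all cells are positive. With a zero cell
  the point estimate is reported as 0 or +∞ (no Haldane correction) and the
  interval is the conditional-exact (Cornfield-type) one, obtained by
  inverting noncentral-hypergeometric tail probabilities at α/2 per side via
  Brent root-finding on the log-odds scale. A table with no exposure at all
  yields (0, ∞) and is flagged uninformative. Note that published intervals
  for zero-cell tables vary widely across software conventions (mid-P,
  Baptista-Pike, …); this package's exact interval is validated against its
  own tail-search oracle, not against any one program's output.
* Monomorphic/degenerate variants are always reported, flagged, never
  silently dropped.
* Covariate-adjusted ORs: maximum-likelihood logistic regression (Newton,
  relative tolerance 10⁻⁸, ≤ 100 iterations) on dosage (additive) or the
  model's indicator coding plus age (years), sex (male = 1) and BMI (kg/m²).
  Complete separation is flagged with no estimate rather than raised; a
  rank-deficient design raises, naming the collinear columns. By default
  adjusted models run only for variants with unadjusted p < 0.05, mirroring
  the way small-cohort panel studies report them; this is overridable.
* Raw p-values are reported (no multiple-testing correction by default),
  matching practice for curated-candidate panels.

The cross-check that the univariate published ORs are allele-count
cross-products (not univariate logistic on dosage) was confirmed by
reconstructing them from the published two-decimal frequency pairs at
n = 122/87; both computations are available.

## Retrospective power

Exposure counts in cases and controls are independent binomials: allele
counts (2n per group) under the log-additive/allelic reading, subject counts
with Hardy-Weinberg-derived exposure probabilities for dominant/recessive
models. The alternative's case frequency comes from applying the odds ratio
on the exposure-odds scale. The default method computes power *exactly* by
enumerating both binomial distributions and applying the identical
chi-square/Fisher selection rule used by the association stage — this makes
the power statement self-consistent with the analysis it describes, is
deterministic, and at these sample sizes costs only a ~250 × 180 grid. The
classical two-proportion normal approximation (the closed form behind
standard genetic-power calculators) is retained as `method="approx"`; the
two agree to well under a percentage point at this cohort's size. At the
null (OR = 1) the approximation returns exactly α while the exact route
returns the test's true (slightly conservative, discrete) size. The
detectable OR at a target power is found by bisection to 10⁻⁴.

## Polygenic risk score

PRS = Σ βᵢ·dosageᵢ with βᵢ = ln ORᵢ. Default weights are the panel's
published odds ratios — using in-cohort estimates as weights and then
contrasting cases against controls with the same data is circular, so
in-cohort weighting is offered only as an explicit sensitivity option, with
per-variant fallback to the literature weight (flagged) where an in-cohort
OR is undefined. Missing dosages are replaced by the variant's mean control
dosage by default (keeps scores comparable across subjects with different
completeness); a strict zero policy is available. Standardization is the
z-transform against the control mean and sample SD (ddof = 1); by
construction control z-scores have mean 0 and SD 1. Note that the source
study prints standardized-PRS group means far from (0, 1), which is
incompatible with this definition; the formula is implemented as defined and
both raw and standardized scores are reported. The median split (default
reference: all scored subjects) sends ties to "low" so the high group
strictly exceeds the median; OR-by-bin reports default to control z-score
quartiles with the lowest bin as reference, both fully configurable since no
published binning exists.

## Recurrence survival analysis

Follow-up runs from anticoagulant discontinuation, administratively censored
at 24 months. Within each clinical stratum (provoked/unprovoked) the
high-vs-low-PRS contrast uses the Kaplan-Meier product-limit estimator with
Greenwood 95% CIs, the standard two-group log-rank test, and a univariable
Cox proportional-hazards model (lifelines; Efron tie handling — appropriate
for the heavy ties month-granular data produce). The Cox model is
univariable because the contrast of interest is the single group indicator;
monotone partial likelihoods (all events in one arm) are flagged rather than
raised. Records with negative times are rejected at I/O, not clipped.

## Synthetic cohort generator

Defaults emulate the source study's shape: 122 cases / 87 controls; control
genotypes in Hardy-Weinberg proportions at the observed control frequencies
and case genotypes at the observed case frequencies (marginal emulation —
the published table gives marginal frequencies, not a liability model); a
logistic-selection mode (per-variant ORs applied to control frequencies) for
designed experiments. Demographics: age ~ Normal(44.5, sd from the 32–57
IQR, clipped to 18–95), BMI ~ Normal(24.5, 4.0), 54.9% male, diagnosis mix
79.5/13.1/7.4% (DVT/PE/both), 70.5% provoked. Recurrence times are
exponential with a baseline hazard of 0.028 month⁻¹ — chosen so that the
2-year recurrence fraction at hazard ratio 1 is ≈ 49%, matching the reported
overall recurrence — multiplied by a group hazard ratio (defaults 1.0
provoked, 3.53 unprovoked) for subjects above the cohort-median true PRS,
then censored at 24 months. A single integer seed drives a spawned stream
per stochastic block, so every output is reproducible from (config, seed)
and fixtures are byte-identical across runs.

Deliberately not emulated: linkage disequilibrium between panel variants
(the analysis treats variants marginally — notably the real *ABO* variants
are strongly linked), population structure, covariate–genotype confounding
under the default marginal mode, non-exponential hazard shapes, and
non-administrative (dropout) censoring. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those real-data features.

## Problem sizes used in the test suite

Parameter-recovery tests run at sizes where the estimator's sampling error
is small relative to the effect being recovered: logistic conditional-OR
recovery at n = 2,000–4,000; Cox hazard-ratio recovery at n = 500 (with an
n = 36 arm to show the order-of-magnitude CI width typical of the
unprovoked-stratum size); log-rank calibration over 1,000 null replicates;
Monte-Carlo power validation at 20,000 tables per grid cell; end-to-end OR
recovery at n = 5,000/5,000 with a ±4-SE band (38 simultaneous checks) and
direction-stability at the study's own 122/87 over 200 replicates.
Simulation-based assertions generally use ±3-SE bands: with many
simultaneous checks per test, a 2-SE band would reject a correct
implementation by construction in a substantial fraction of runs.

## Known limitations

* The exact-CI convention for zero-cell tables is one of several in use;
  numbers will differ from software using mid-P or score intervals.
* The power model treats alleles as independent Bernoulli draws (2n per
  group), the standard log-additive approximation; it is not a trend test
  on genotypes, though the difference is negligible under Hardy-Weinberg.
* PRS missing-data substitution by control mean dosage slightly shrinks
  case-control contrast when missingness is heavy.
* The survival stage fits no covariates and no competing-risk structure.
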