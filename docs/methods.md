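# Methods

## The angle and its measurement rules

ABZA is defined on a single 2D anteroposterior DSA projection. Landmarks
are continuous coordinates in any consistent unit; no pixel grid or
display-axis convention is assumed — orientation is carried entirely by the
ordered (base, apex) midline pair, with apex pointing toward the
sagittal-sinus apex. This makes the measurement invariant under rigid
transforms, uniform scaling and mirror reflection, properties the test
suite checks to 1e-6 degrees.

The vertex `O` is the orthogonal projection of the ICA-bifurcation point
`T` onto the infinite midline. When several farthest-point candidates are
supplied for a complete occlusion, the terminal point `C` is their
**centroid** — the protocol names "the several farthest points" without a
reduction rule, so the symmetric choice is used and recorded, and a rater
can always override it by supplying a single point.

Anatomically `C` lies anterior to `O`, so α ≤ 90°. Measured values in
(90°, 90.5°] are clamped to 90° with a warning (marker jitter); anything
larger raises an error suggesting the midline pair was supplied in the
wrong order. Contralateral measurements are taken at face value: the caller
supplies the contralateral landmarks and sets the flag; no internal
mirroring is applied.

## Grading

`ABZA_trans = α / norm_upper_deg` with `norm_upper_deg = 23.0°`, the upper
limit of the 95% normal reference range established in prior work; the
constant is configurable but deliberately not re-derived here. The bins are
the explicit piecewise list (0: trans ≤ 1.0; 1: (1.0, 1.5); 2: [1.5, 2.5);
3: [2.5, 3.5); 4: [3.5, 90/23]); the looser description of the grade as
"rounding" trans is treated as a heuristic gloss, since naive rounding
would disagree on [0.5, 1.0]. The two clauses conflict at trans exactly
1.0 (both "grade 0" and "start of grade 1"); the more specific grade-0
clause wins by default, a warning is emitted, and
`GradingScheme.grade_at_unit_boundary` can flip the choice. Grades are
integers only, and good collaterals means grade > 2, equivalently
α ≥ 57.5° given the left-closed grade-3 bin.

## Statistics

* **Univariate screen** — the source names no per-variable tests, so a
  conventional routing is used and recorded in each result: continuous
  variables are screened with Shapiro–Wilk at 0.05 per group and sent to
  the equal-variance two-sample t-test or the Mann–Whitney U; categorical
  variables get a Pearson chi-square, switching to Fisher's exact for 2×2
  tables with any expected count below 5. All p-values are two-sided; no
  multiplicity adjustment is applied (none was applied in the source
  analysis).
* **Chi-square** statistics are Pearson without continuity correction, so
  they equal the textbook Σ(O−E)²/E, which the tests verify against an
  independent oracle.
* **Logistic models** are maximum-likelihood enter-method fits
  (statsmodels `Logit`): all listed covariates enter simultaneously,
  odds ratios are exp(coef) with Wald 95% CIs and Wald p-values (matching
  the SPSS defaults of the original analysis). Stroke etiology enters as a
  three-level factor with large-artery atherosclerosis as the reference
  level, and a pooled likelihood-ratio p-value is reported per factor. A
  single-class outcome, divergent coefficients (|β| > 15 or SE > 50) or
  non-convergence raise an explicit separation error rather than returning
  a silently unstable fit.
* **ROC** — candidate cutoffs sit at midpoints between consecutive sorted
  unique scores (plus sentinels outside the observed range), with
  "score > cutoff ⇒ predict favorable"; this convention is consistent with
  an empirical optimum falling strictly between the 57.5° grade boundary
  and the next observed angle. The optimal cutoff maximizes the Youden
  index with ties broken toward higher specificity. The AUC is the
  empirical area (equal to the concordance probability with ties counting
  ½) and its 95% CI uses the DeLong placement-value variance, implemented
  here and validated against R's pROC on a frozen fixture. Constant scores
  yield AUC 0.5 with a warning.
* **Inter-rater reliability** — the source's single reliability
  coefficient is not named, so both natural statistics are exposed:
  ICC(2,1) (two-way random, absolute agreement, single measures; via
  pingouin) for the continuous angle, and linearly weighted Cohen's kappa
  (via scikit-learn) for the ordinal grade.
* **Missing data** are handled complete-case per analysis with the
  exclusion count reported. The favorable-outcome dichotomy is mRS ≤ 2 at
  90 days, configurable.

## Synthetic cohorts

The generator emulates the *structure* of the 108-patient EVT cohort, not
its joint distribution: covariates are drawn independently (no correlation
structure is reported), with binary prevalences set to the published
marginal fractions, age Normal(68, 9) truncated to [30, 95] years
(approximating the published medians/IQRs; illustrative, not an estimate),
etiology at the published proportions (LAA 44/108, CE 59/108, other
5/108), and the grade drawn conditionally on etiology. The per-etiology
grade distributions are free parameters constrained to match the published
good-collateral fractions P(grade>2 | LAA) = 23/44 and P(grade>2 | CE) =
10/59, with the remaining mass concentrated adjacent to the dichotomy
boundary. Within a grade the angle is uniform over the grade's degree
interval (no within-grade distribution is reported).

The 90-day outcome is Bernoulli with logit p = β₀ + β_age·age +
β_gc·1[grade>2] (optionally + β_mtici·1[mTICI 2b/3], off by default). The
default slopes are the published Model 1 odds ratios — β_age = ln 0.939
per year, β_gc = ln 18.948 — and β₀ is calibrated by root bracketing so
the mean outcome probability over a 200 000-draw fixed-seed covariate
sample hits the published prevalence 37/108 = 0.343 within 1e-3. One
seeded PRNG stream drives each cohort; the same seed reproduces the table
bitwise, and the seed and true coefficients are written to a ground-truth
sidecar.

Because covariates are independent and outcomes truly logistic, passing
recovery tests demonstrates the correctness of the fitting pipeline — not
that real angiographic cohorts satisfy the model. Phantom tests likewise
validate the geometry under ideal and jittered landmarks, not the
upstream identification of landmarks on real DSA frames, which is out of
scope (landmarks are inputs; no DICOM or segmentation).

## Problem sizes and numerical choices

The odds-ratio recovery experiment uses 200 replicates of n = 2000
(seeds `base_seed .. base_seed+199`), sizes at which the logistic MLE's
finite-sample bias is small relative to the 5% acceptance band; the median
fitted OR for the large good-collateral effect still sits ~2–3% above the
generating value, the expected direction for exp of a near-unbiased
coefficient. Distributional checks (grade-by-etiology fractions,
prevalence self-consistency) use single cohorts of n = 100 000 with 3×MC-SE
or ±0.01 tolerances. Degenerate-line and coincident-point checks use a
relative tolerance of 1e-12 on the coordinate scale; grade-bin edges are
compared with a 1e-9 absolute tolerance.

## Known limitations

* The angle is a planar summary of a 3D vascular territory; the package
  treats the supplied projection as authoritative and does not model
  projection obliquity.
* The headline discrimination of the original cohort (AUC 0.868, optimal
  cutoff 57.8°) depends on patient-level data that are not deposited; the
  package reproduces every statistic derivable from the published counts
  and validates the ROC/cutoff machinery by property tests instead.
* The centroid reduction of multiple farthest points and the univariate
  test routing are this package's conventions where the protocol is
  silent; both are recorded in outputs so they can be audited or
  overridden.
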