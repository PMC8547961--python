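# Methods

## The measurement being modelled

Liquid-phase FTIR transmission spectroscopy of blood serum/plasma yields an
absorbance spectrum A(ν) over 950–3050 cm⁻¹ (4 cm⁻¹ resolution, sampled
here at 2 cm⁻¹, 1051 points). The spectrum of a sample measured against a
pure-water reference is, to a good approximation,

    A(ν) = solute(ν) − β · w(ν) + ε(ν),

where `solute` is the absorption of the dissolved biomolecules, `w` the
absorption spectrum of pure water, β the *water deficit* (solutes displace
water, so the sample cell contains less water than the reference; β scales
with total solute load), and ε measurement noise. Dried serum shows no
significant absorption over 2000–2300 cm⁻¹, so over that window the solute
term is flat and any residual slope is attributable to the −β·w term.

## Preprocessing

1. **Water correction.** "Minimizing the average slope" over the flat
   window is implemented as the OLS linear slope: the corrected spectrum is
   `s + α·w` with `α = −slope(s)/slope(w)`, the closed-form minimizer of
   the absolute window slope. This is exactly equivalent to a grid search
   over α (verified in the tests). The correction is unidentifiable when
   the water reference itself is flat in the window; that raises an error.
2. **Truncation and masking.** Spectra are truncated to 1000–3000 cm⁻¹ and
   the silent region between 1750 and 2800 cm⁻¹ is removed. Both printed
   endpoints are *retained* (the removal interval is open): the sources
   describing such pipelines say the region "between" the endpoints is
   removed and leave the endpoint fate open, so the inclusive convention
   was chosen and is asserted in the tests (477 retained points on the
   default grid: 376 in 1000–1750, 101 in 2800–3000).
3. **Normalization.** Euclidean (L2) norm per spectrum.
4. **Second derivative (optional).** Savitzky–Golay with window 9 and
   polynomial order 3 (a common chemometrics choice; both configurable),
   computed **per contiguous segment** so the filter never bridges the
   silent-region gap.

The chain is strictly per-sample: no statistic is estimated across samples,
so it cannot leak information across a cross-validation split.

## Outlier quality control

Classical LOF: k-distance (ties at the k-th distance enlarge the
neighbourhood), reachability distance `max(kdist(o), d(p,o))`, local
reachability density `lrd = 1/(mean reachability + 1e-10)` (the epsilon
keeps duplicated points finite), score = mean neighbour lrd / own lrd.
k defaults to 20. Flagging is either a fixed cutoff (default 1.5, inliers
score ≈ 1) or a top-fraction rule.

**QC feature space.** LOF runs on water-corrected, masked, but **not**
normalized spectra. L2 normalization erases a global attenuation — a
spectrum measured at 20% absorbance normalizes to the same unit vector as
its healthy original — so the anomalies this step exists to catch
(abnormally low absorbance) are only visible while absolute scale is
preserved. The QC space is fixed regardless of which preprocessing variant
the classifier later uses, so the retained sample set does not depend on
the classification configuration.

## Matching

Logistic regression (maximum likelihood) of group membership on age, sex
(0/1, included in the Mahalanobis metric) and BMI gives per-sample
propensities; the caliper is 0.2 × SD of the pooled logit propensity (the
standard observational-studies convention; configurable). Pairwise
Mahalanobis distances use the pooled within-group covariance. The optimal
match minimizes total distance over admissible pairs, solved exactly by the
Jonker–Volgenant assignment algorithm with forbidden pairs encoded as a
penalty larger than any feasible total distance — this makes the solution
maximize the number of matched cases first and minimize distance second,
which is the behaviour adopted when not every case has an admissible
reference (the alternative, failing outright, wastes cohorts). 1:k matching
replicates each case k times in the cost matrix; a case that cannot obtain
all k references is reported unmatched. Ties are broken deterministically
by lexicographic sample id. Balance is reported as
SMD = (mean_case − mean_ref)/pooled SD, computed on the full and on the
matched sample.

## Classification and evaluation

Linear soft-margin SVMs (scikit-learn SVC, linear kernel). Binary
evaluation uses stratified 10-fold CV repeated 10× with fold assignment
re-randomized per repeat from the global seed; the AUC is computed per
held-out fold and summarized as mean ± SD, and a pooled ROC is built from
the concatenated held-out decision scores (fold AUCs for statistics, pooled
scores for curves — reconciling per-fold descriptive statistics with single
smooth ROC curves). ROC construction is an explicit threshold sweep with
tied scores collapsed onto one vertex and trapezoidal AUC, which equals the
Mann–Whitney estimate with ties counted ½ (asserted against the U-statistic
implementation). Operating points: the vertex minimizing
√((1−sens)² + (1−spec)²), ties toward higher sensitivity; and the largest
sensitivity among vertices with specificity ≥ 0.95 (step convention, no
interpolation). Multiclass: one-vs-one linear SVMs with majority vote, ties
broken by aggregate decision values; confusion counts accumulate over
held-out folds, per-class accuracy is the class recall, overall accuracy is
mean ± SD over folds.

**Regularization.** `train_linear_svm` defaults to C = 1. The *pipeline*
default is **C = 100**: L2-normalized spectra put every sample on the unit
sphere with per-feature scale ~0.05, and at that scale C = 1 penalizes the
weight norm so strongly that the decision direction collapses (near-chance
AUC even for well-separated groups). C = 100 behaves like the value an
inner CV over the conventional grid {0.01…100} selects for unit-norm
spectra, without spending a nested CV in every run; C remains configurable.

## Per-wavenumber statistics

Student's pooled-variance t-test by default (Welch behind a flag, since the
equal-variance assumption is a choice); columns with zero variance in both
groups get p = 1 when the means agree and the smallest positive float
otherwise, keeping p ∈ (0,1]. The per-wavenumber AUC is U/(n₁n₂) computed
from midranks (exact tie handling, no normal approximation), oriented so
values above 0.5 mean cases exceed references; no folding about 0.5 and no
multiple-testing correction by default (a Benjamini–Hochberg view can be
applied downstream; the raw curves are what is plotted in practice). The
area under |Δ| is a trapezoidal integral per contiguous segment — the
silent-region gap contributes nothing. The PCA site check retains the
smallest number of components reaching 95% cumulative explained variance
and tests the weighted between-site centroid dispersion against 999 label
permutations.

## Synthetic cohorts: what they emulate, and what they do not

The generator emulates the statistical structure a real serum study
presents to this pipeline:

* **Bands.** Nine Gaussian bands (amide I 1652, amide II 1545, CH₂/CH₃
  1400/1450, carbohydrates 1080/1160, lipid ester 1740, CH stretches
  2870/2930 cm⁻¹), amide I dominant (0.30 AU); per-person band amplitudes
  are log-normal with CVs of 8–25% (protein-like constituents vary least,
  lipids most).
* **Biological variability.** Besides the band-amplitude variation, each
  person carries a smooth correlated deviation (Gaussian-kernel-smoothed
  noise, SD 0.004 AU, correlation length 25 cm⁻¹) **shaped by the solute
  band envelope**, so it vanishes in the solute-free window — real
  biological absorption does not extend into 2000–2300 cm⁻¹, and without
  this shaping the water-correction coefficient would absorb spurious
  window slopes. This component stands in for the many-molecule
  compositional variation that is not reducible to a few band amplitudes.
* **Measurement noise.** White, SD 0.002 AU — small against the biological
  variability, reflecting the reproducibility of automated FTIR
  instruments; the exact ratio is a free design choice since published
  studies report only the qualitative ordering.
* **Water deficit.** β log-normal with mean 0.1 at nominal solute load and
  proportional to the person's realized solute load (displacement physics),
  CV 30%.
* **Confounding.** Age scales amide II and BMI the lipid band (strength
  0.3 by default), and case/reference covariate distributions are shifted
  (age +5 y, BMI +1 kg/m², male fraction 0.6 vs 0.5), so matching has real
  work to do.
* **Disease signature.** A smooth unit-norm differential shape with centers
  *offset* from the bulk bands (1590, −1120, 1700, 2960 cm⁻¹): a disease
  changes shoulders and shape, whereas pure rescaling of healthy bands is
  exactly what between-person variability already produces. Stage
  amplitudes δ_T1..T4 = 0.005/0.013/0.024/0.040 AU were calibrated once so
  that a mixed-stage cohort of ~200 cases classifies at AUC ≈ 0.75–0.88 and
  the per-stage AUCs run from near-chance (T1) to near-perfect (T4) — the
  operating regime reported for real serum studies of this design — and
  then frozen.
* **Artifacts.** Injected anomalies are either a global ×0.2 attenuation or
  an added narrow contamination band (σ 6 cm⁻¹, 0.15 AU), the two anomaly
  classes spectral QC is meant to catch.

Not modelled: Beer–Lambert saturation and path-length effects, atmospheric
CO₂/water-vapour lines, scattering, instrument drift, site-dependent
spectral offsets (sites are labels only, so the PCA site check is null by
construction), and any real serum chemistry. Passing tests therefore show
that the *pipeline* behaves correctly on data with this covariance
structure — they say nothing about the detectability of any real disease.

## Numerical choices and degenerate inputs

* Water correction requires |slope(w)| > 1e-12 over the window; corrected
  window slopes are zero to ~1e-16 relative.
* LOF lrd epsilon 1e-10 (duplicates stay finite); all-pairs Euclidean
  distances (cohorts here are ≤ a few thousand spectra).
* Assignment penalty = total admissible distance + max + 1.
* Zero-variance t-test columns and zero-SD SMDs resolve to the exact-null
  values when the means agree and error otherwise.
* Every stochastic stage draws from `numpy.random.default_rng` seeded from
  one configuration seed; reruns are bit-identical.

## Problem sizes used in the checks

The validation suite runs null multiclass studies at 100/class with 10×10
CV (3 seeds), null binary pipelines at 200/200 (3 seeds), stage comparisons
at 600 cases/650 references (≈140 matched pairs per stage after matching),
|Δ|-area comparisons on group means at ~1000 cases per stage, the binormal
AUC limit at 2000/group, and 50-seed balance experiments at 100 cases/200
references. These sizes were chosen so each quantity's sampling noise is
well inside the tolerance being asserted.

## Known limitations

* Matching happens once per clinical question before cross-validation (as
  in real studies of this design), so the matched set is shared across CV
  folds. Matching uses only covariates, never spectra, so no spectral
  information leaks — but covariate balance is optimized on the full
  cohort.
* The per-fold AUC SD understates cohort-level uncertainty (folds share
  samples across repeats); it is a descriptive statistic, not a standard
  error.
* The area under |Δ| is biased upward by sampling noise (folded-normal
  floor ∝ 1/√n); comparisons across strata are only meaningful at matched
  group sizes, and the stage-monotonicity checks therefore use equal-size
  strata and group means at large n.
* 1:k matching is fixed-ratio; full/variable-ratio matching and matching
  with replacement are out of scope.
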