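# Methods

## Geometry and the quantification policy

All geometry is exact pixel counting on boolean masks with 0-based
(row, col) coordinates, row 0 at the top. An eye is a cornea mask, a pupil
mask (required to be inside the cornea; a `clip` load mode repairs
annotations that spill past the limbus), and up to five lesion masks.
Multi-component lesions (typical for neovascular tufts) are pooled by
union before any computation.

**Area grading.** The lesion is intersected with the cornea before
dividing by the corneal area, so the fraction is guaranteed to lie in
[0, 1] even when an annotation extends past the limbus; the quartile bins
are closed on their upper edges (0.25 → 1, 0.50 → 2, 0.75 → 3, 1.00 → 4)
and grade 0 is reserved for absent lesions, keeping the feature ordinal.
An annotated-but-empty mask is treated as absent.

**Quadrants.** Clinical quadrant conventions (nasal/temporal) need eye
laterality, which mask files do not carry, so quadrants are image-frame:
the four sign-quadrants of (row − r̄, col − c̄) about the corneal centroid,
indexed superior-temporal, superior-nasal, inferior-nasal,
inferior-temporal with temporal taken as the left image half. Pixels
exactly on an axis break deterministically toward the lower-index quadrant
of the eligible pair, so the four masks partition the cornea exactly. A
consequence worth noting: one quadrant holds at most ~25% of the corneal
area, so a lesion with area fraction above 0.25 necessarily occupies at
least two quadrants.

**Pupil occlusion.** The indicator is 1 iff the lesion and the pupil share
a pixel. The policy's written formula intersects with the cornea rather
than the pupil, but its stated intent is "blocks the pupil"; the pupil is
the default target and the cornea variant is selectable
(`occlusion_target="cornea"`), under which any lesion inside the cornea
trivially scores 1.

**Abscess depth.** A hypopyon is a settled horizontal fluid level, so its
severity tracks height, not area. The default grade uses the fraction of
distinct cornea rows (within the cornea's column span) that contain lesion
pixels; `mode="area"` grades the plain area fraction instead. Both lie in
[0, 1] and use the same quartile bins.

## Segmentation metrics

All metrics derive from one 4×4 pixel confusion matrix over
{background, cornea, pupil, lesion}. Per-class "accuracy" is class-wise
recall TP/(TP+FN) — the convention of the segmentation literature; IoU and
Dice are the usual one-vs-rest ratios and satisfy Dice = 2J/(1+J)
identically before rounding. Macro means are unweighted over all four
classes including background — the convention is confirmed by the fact
that it reproduces the reference panels' printed macro values from their
per-class rows. A class absent from both prediction and truth scores 100
(vacuous agreement). Reports round half-up to 2 decimals on the percentage
scale; full precision is kept internally. Scoring a dataset pools pixels
into one confusion matrix by default; per-image averaging is available
(`mode="per_image"`) since either convention is defensible for
image-set reporting.

## Prognosis modeling

**Fusion.** A patient imaged under several light sources gets the
element-wise maximum of each quantified feature across images — a
worst-lesion principle; `rule="mean"` averages instead. Etiology is
one-hot over {bacterial, fungal, viral, acanthamoeba}; sex is a male
indicator; age (years) and BCVA (logMAR) pass through. Patient names are
never stored. Missing outcomes drop the patient for that task only.

**Screening.** Features are standardized, an L1 logistic path over 25
penalties (C ∈ 10^[−2.5, 1.5]) is fit with liblinear, the penalty is
chosen by stratified 5-fold cross-validated log-loss, and features with
non-zero coefficients are returned. Zero-variance columns are dropped with
a warning. The deviance-minimizing rule is deliberately liberal: it
reliably keeps true effects at the cost of a few correlated passengers,
which the downstream boosted model can ignore.

**Boosting.** XGBoost and LightGBM binary classifiers with depth-3 trees,
up to 200 rounds at learning rate 0.1, early-stopped on a 20% stratified
internal holdout (skipped when the minority class is too small to
stratify). Single-threaded with fixed seeds, so fits are bit-reproducible.
All hyperparameters are exposed via `boost_params`.

**Metric panel.** Confusion-based metrics use score threshold 0.5
(configurable); ratios with zero denominators are reported as missing
rather than 0. AUC is the Mann–Whitney rank statistic (ties count ½). The
95% CI is a stratified percentile bootstrap (2000 resamples by default,
positives and negatives resampled separately, fixed seed); the interval is
widened to contain the point estimate in the rare degenerate case where it
falls on a percentile edge. Cross-validation is stratified k-fold
(default 5) with screening re-run inside each training fold, so feature
selection never sees a fold's held-out patients.

**Splitting.** The train/validation split is stratified by outcome at a
configurable ratio (default 8:2) and errors when either side would lose a
class.

## Synthetic generators

**Eyes.** Cornea and pupil are concentric discs (radii 0.42·size and
0.15·size by default). A lesion request names a target area fraction, a
quadrant set, and a pupil-overlap flag. The blob is built by allocating an
exact pixel budget round(f·|C|) across the requested quadrants
(proportional to capacity, at least one pixel each) and taking, within
each quadrant's candidate set (pupil excluded unless overlap is
requested), the pixels nearest a randomly seeded point — a seed inside the
pupil when overlap is forced. The realized fraction is therefore exact to
one pixel, and the realized grade/occlusion/quadrant count is known by
construction. Infeasible requests (budget exceeding the candidate
capacity, e.g. 30% of the cornea in one quadrant) raise an error rather
than being silently truncated. The abscess is generated as a bottom band
of cornea rows spanning the requested fraction of the cornea's vertical
extent, emulating a settled hypopyon, so the depth-mode grade round-trips
exactly. Identical specs give bit-identical masks.

These eyes are geometric idealizations: real slit-lamp annotations have
irregular limbus contours, specular highlights, eyelid crops, and
correlated lesion shapes. Passing round-trip tests therefore validates the
quantification arithmetic and policy logic, not robustness to annotation
noise.

**Cohorts.** Feature columns follow the fused schema; grades are drawn as
0 with probability 0.4 else uniform on {1..4}, indicators fair, quadrant
counts uniform on {0..4}, age ~ round N(55, 15) truncated to [5, 95], BCVA
uniform on the 0.0–2.0 logMAR grid, etiology categorical
(0.4/0.3/0.2/0.1). Outcomes are Bernoulli(logistic(α + β·(x − x̄))) with
the features mean-centered so prevalence is governed by the intercept
alone; each of the four outcome columns is an independent draw from the
same probabilities. Features in a real cohort are correlated (a deep ulcer
begets a scar); here they are independent, which makes the planted-signal
recovery benchmark cleaner but easier than reality. The documented
benchmark (`planted_cohort_spec`) uses n = 500, twelve candidate features
and three planted log-odds effects of magnitude 1.0 (+1 scar grade,
+1 blue-light ulcer grade, −1 BCVA).

## Problem sizes and numerical choices

Simulation-backed checks use 96–128 px grids, 200 round-trip eyes (5 lesion
types × 4 grades × 10 seeds), 100 random brute-force fixtures, 20-seed
screening/permutation studies at n = 500, and 200 bootstrap-coverage
replicates at 75 positives/negatives with 2000 resamples each — sizes at
which every targeted effect is decisively measurable while the whole suite
runs in well under a minute per study. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); ties in blob growth
break lexicographically, so generation is platform-stable.

## Known limitations

- Quadrants are image-frame, not anatomic; left/right eye laterality is
  ignored.
- The per-class accuracy definition (recall) and the pixel-pooled dataset
  default are conventions chosen where reporting practice varies; both
  alternatives are implemented but a different upstream convention would
  shift absolute numbers.
- The boosted models are evaluated on synthetic cohorts only; nothing here
  validates clinical transportability.
- Bootstrap percentile CIs are first-order; for AUCs very near 1 they can
  undercover slightly.
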