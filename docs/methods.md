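# Methods

This note documents the models, conventions and numerical choices behind
`specell`, in the spirit of a statistical package's methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The measurement model

A *data block* is one field imaged in 34 spectral channels (excitation
340–510 nm, emission 420–650 nm) plus a brightfield image and per-channel
reference images: dark (shutter closed), water (blank sample), and a
calibration fluid of 30 µM NADH + 18 µM FAD whose emission spans all
channels.  The per-channel excitation/emission table of the original
instrument is not publicly distributed, so the default `ChannelSet` is a
grid over the published ranges satisfying every per-channel invariant
(emission band above excitation, exposure in (0, 5] s); it is YAML-editable
so a real channel table drops in without code changes.

The synthetic generator assumes linear spectral mixing: the clean signal at
pixel x in channel c is

    clean_c(x) = illum(x) · texture(x) · Σ_f A_f · R_{c,f} · t_c

with illumination field `illum` (smooth off-centre quadratic vignette,
mean 1, coefficient of variation ≈ 12% at the default strength 0.5),
per-pixel lognormal cell texture (σ = 0.3), fluorophore abundances `A_f`,
endmember responses `R` and channel exposure `t_c`.  The observation adds a
constant stray background b, Poisson shot noise, a dark offset and Gaussian
read noise:

    observed = Poisson(clean + b) + dark + N(0, σ_read²)

then stamps hot pixels to the saturation level and dead pixels to zero
(default rates 10⁻⁴ each).  References are generated consistently — dark =
offset + noise, water = dark + b, calibration = dark + illum ·
L_cal · t_c — with noise reduced by frame averaging (25 frames).  Putting
the same constant background in the channel images and in the water
reference is what makes water subtraction an exact background removal; a
background modulated by the illumination would belong in the calibration
image instead.

### Endmembers and the group effect

Three endmembers are generated as smooth bumps over channel index: NAD(P)H
peaking at channel 2, flavins peaking at channels 15 and 32, and a broad
"lipofuscin-like" nuisance.  Seeded 3% jitter varies cohorts; the dominance
structure is re-imposed exactly so the invariants (argmax at ch2; ch15/ch32
the two largest flavin entries) hold for every seed.

The group difference is placed **only** on the NAD(P)H:flavins
log-abundance ratio r — the cellular redox ratio, the one biologically
anchored group-difference mechanism in this setting.  Per cell,

    r = effect · (g − ½) + u_patient + e_cell,
    u ~ N(0, σ_b²), e ~ N(0, σ_w²)

with defaults σ_b = σ_w = 0.25, and an independent lognormal overall
brightness (σ = 0.3) that cancels in ratios but contaminates single-channel
means — so ratio features are genuinely the better features, as they should
be.  Because r is Gaussian with total SD σ = √(σ_b² + σ_w²), the
Bayes-optimal AUC of the true log-ratio is Φ(effect / (√2 σ)), and
`effect_for_auc` inverts this to design cohorts at any separability.  This
closed form is the oracle for the end-to-end parameter-recovery checks.

The default cohort scale mirrors the reference study: two groups of 41 and
84 cells from 8 patients per group, 2–4 cells per field.  Images default to
256 × 256 (a desk-scale stand-in for the instrument's 1200 × 1200; the full
size is a config value, not a code change).

### What the generator does not emulate

No filter-cube spectral overlap, no chromatic registration error, no cell
morphology beyond textured ellipses, no focus drift, no per-channel
illumination differences (one field is shared by all channels).  Passing
tests therefore demonstrate that the *analysis chain* is correct and
leak-free under the stated noise model — not that the instrument model is
complete.  In particular the designed-AUC recovery says the pipeline
recovers the separability that exists; it cannot certify any particular AUC
on real patients.

## Preprocessing

Fixed order: **repair → subtract water → flat-field → equalize exposure.**
Repair runs first so sensor defects cannot poison the reference-based
corrections.  The upstream literature defers correction formulas to
instrument-specific references, so the conventions are fixed explicitly
here:

* **Repair.**  A pixel is flagged if it is at/above saturation, below the
  undetectable floor (dark mean + 2 · dark SD, per channel), dead according
  to the calibration image (calibration − dark ≤ 0), or a spike/dip.  The
  spike/dip rule requires *both* |value − local median| > k·σ̂ (k = 5,
  3 × 3 windows, σ̂ = 1.4826 · local MAD floored by a per-channel global
  robust scale and by 10⁻³ of the local level) *and* that the pixel
  dominate every neighbour by at least half its residual.  The dominance
  condition is what distinguishes single-pixel defects from sharp structure
  (cell boundaries), whose pixels have comparable neighbours.  The global
  scale uses the 97.5th percentile of |residual| (= 2.241 σ for Gaussian
  noise) rather than the median, because background clipped to zero after
  water subtraction would otherwise collapse the median-based estimate.
  Flagged pixels are replaced by the median of their non-flagged
  neighbours; a channel with > 20% flags aborts as unusable.
* **Water subtraction.**  The water reference is acquired shutter-open and
  contains the dark level, so one subtraction removes dark offset and
  stray/buffer background; negatives clip to zero by default.
* **Flat-fielding.**  `flat = corrected · mean(calib − dark) / (calib −
  dark)`, per channel and pixel.  The mean renormalization preserves the
  spatial mean of a uniform target.  On noise-free synthetic data this
  inverts the generator's illumination to float round-off (the acceptance
  suite verifies < 10⁻¹⁰); on noisy uniform targets it takes a raw CV of
  > 10% below 1%.
* **Equalization.**  Division by exposure puts all channels in counts/s.

A processed block's references and exposures are rewritten to the identity
configuration (zero dark/water, uniform calibration, unit exposures, no
finite saturation level), so re-running the composed map is a no-op —
*approximately*: borderline noise-tail pixels whose σ̂ shifts after
background clipping can be re-repaired on a second pass.  The property test
bounds this at < 10⁻⁴ of pixels; exact idempotence would require a defect
detector invariant to the background subtraction, which no local rule is.

## Features

Per cell and channel: arithmetic mean; top-decile mean (the ⌈0.1 n⌉ largest
pixels, minimum 1 — the concentration of fluorophores in compartments such
as mitochondria makes the brightest pixels informative); and in the
*extended* policy sample SD (n−1), adjusted Fisher–Pearson skewness and
excess kurtosis.  Ratios are means of one channel over another; the default
pair set is all ordered pairs among the interpretable channels {2, 15, 32}
(the full 34 × 33 set is a config switch — it mostly adds noise and
redundancy).  Degenerate rules: moments of constant vectors are 0; a ratio
with zero denominator is 0 with a warning — a degenerate cell must not
crash a cohort run.  The *conservative* policy (means, top-decile means,
ratios) keeps every feature interpretable in terms of fluorophore content;
*extended* adds the abstract moment features.

## Discriminant analysis

**Scoring.**  A feature's *minimum attainable classification error* is the
smallest misclassification fraction over all single-threshold rules:
thresholds at midpoints between consecutive sorted unique values plus ±∞,
both polarities, cells weighted equally (empirical priors — with 41 vs 84
cells the majority rule already achieves 0.328, which is the correct upper
reference for unbalanced data).  Error ties break toward the threshold in
the widest achieving gap (largest margin).  The implementation is O(n log
n); the test suite checks exact equality against an exhaustive oracle, and
the score is invariant under monotone transforms of the feature.

**Selection.**  Features are ranked ascending by min-error (ties by
canonical column order) and greedily selected subject to an absolute
correlation cap of 0.95 against already-kept features — the top of the
ranking is otherwise filled with near-duplicates (a channel's mean and its
top-decile mean).  The count n must stay below the smaller group's cell
count N; violating the guard is a hard error, not a warning.

**Projection.**  Features are standardized by training mean/SD.  The first
canonical axis is the Fisher direction w₁ ∝ S_w⁻¹(m₁ − m₀) with the pooled
within-class covariance shrunk toward its diagonal, S_w(γ) = (1 − γ)S_w +
γ diag(S_w).  γ is chosen from the fixed grid {0, 0.05, 0.2, 0.5} by
training min-error of the 1-D projection, preferring heavier shrinkage on
ties (stability with few cells and collinear ratios).  A two-class problem
has only one canonical variable; the second scatter axis is the Fisher
direction restricted to the orthogonal complement of w₁ — a documented
construction choice that yields the 2-D discriminative scatter without
inventing extra classes.  Both axes are unit length, signed so group 2
projects higher; equal class means degrade gracefully to the leading
within-class variance axis with a warning.  The 1-D projection used for
histograms and classification is w₁.

**Classifier.**  Score = 1-D projection; decision threshold = the
min-error threshold on training scores.  This keeps the conservative and
extended models directly comparable — both are "a specific linear
combination of cellular features" differing only in the admissible feature
set.

## Validation

**ROC/AUC** by threshold sweep with the midrank tie convention, so the
trapezoidal AUC equals U/(n₁n₂) exactly; the suite verifies the identity
against an all-pairs oracle.

**Nested CV.**  Outer folds (default 5) estimate held-out performance;
inner folds (default 5) on each outer-training set choose the feature count
n from a grid by mean inner AUC, with ranking and selection re-run inside
every training fold.  Folds stratify over the grouping unit.  The default
grouping is **patient**: cells of one patient correlate through the
patient-level random effect, and letting them straddle a train/test split
overstates performance (the classic pseudo-replication of cell-level CV —
the cell-level option exists, and its permutation null sits visibly above
0.5, which is exactly the point).  A hard assertion fails the run if any
grouping unit appears on both sides of a split.

**Permutation null.**  Labels are permuted at the grouping-unit level and
the (fixed-n) CV is re-run; the mean held-out AUC over 200 permutations
should sit near 0.5.  Two small-sample biases are worth knowing: pooled
CV-AUC under the null is pessimistic when the number of patients is small
(≈ 0.42 at 8 patients/group), and optimistic under cell-level grouping
(patient memorization).  The guard therefore runs on a cohort with 20
patients per group, where the patient-grouped null centres within ±0.05 of
0.5.

**Mann–Whitney U**, two-tailed, on the projected scores: exact enumeration
for tie-free n₁ + n₂ ≤ 12, otherwise a normal approximation with
continuity correction, tie-corrected variance, and a one-term Edgeworth
expansion in the exact excess kurtosis of U, g₂ = −3(n₁² + n₂² + n₁n₂ +
n₁ + n₂)/(2.5 n₁n₂(n + 1)).  The plain continuity-corrected normal
approximation errs by up to ≈ 0.022 against the exact p at unbalanced
n₁ + n₂ = 12 splits; the Edgeworth term brings the worst case to ≈ 0.003.
The correction is skipped for |z| > 5 where the expansion can turn the CDF
negative (the tie-free kurtosis formula is also used under ties, where it
is an approximation).  Significance tiers: * p < 0.05, ** p < 0.01,
*** p < 0.001.

## Problem sizes and determinism

Simulation studies use two generator paths: the full image path (renders
pixels, exercises preprocessing and feature extraction) and a feature-level
path that maps the same hierarchical abundance model directly to per-cell
channel means (`generate_feature_cohort`).  The feature-level path powers
the studies that need many cohorts — designed-AUC recovery over
{0.6, 0.75, 0.9, 0.99} × 10 seeds and the 200-permutation null — while the
image path backs the calibration, repair, ranking-recovery and end-to-end
checks at 96–256 px fields.  These sizes are the package's reference
conditions; all scale up by config.

All randomness flows from explicit seeds (one master seed per cohort or
pipeline run; per-field generators derive from it), so a rerun reproduces
every artifact byte-for-byte.  The run manifest records a SHA-256 per
output file; figures (PNG/SVG) are excluded from the manifest because
matplotlib embeds a creation timestamp in SVG metadata.

## Known limitations

* The channel wavelength table is a synthetic placeholder grid.
* Exact preprocessing formulas of the original instrument chain are not
  public; the conventions above are explicit, config-exposed choices.
* The defect detector is approximate at cell boundaries by design
  (dominance rule) and not exactly idempotent (see above).
* No probability calibration, multi-class support, or patient-level
  aggregation of cell scores.
* Synthetic effect sizes are free design parameters: recovery of a designed
  AUC validates the machinery, not any clinical claim.
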