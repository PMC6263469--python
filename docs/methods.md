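# Methods

## Problem

A wearable inertial sensor (3-axis accelerometer in g, 3-axis gyroscope in
rad/s) is worn at one of six body positions — right/left arm, hand or
thigh — and the task is to recover that position from the walking signal
alone. The six positions factor into a *side* (right/left) and a *segment*
(arm/hand/thigh), so instead of one flat 6-class classifier the package
optimizes seven small local classifiers (body-side, body-segment, the
per-side segment tasks and the per-segment side tasks) and composes them
top-down: a root node predicts one factor and routes each sample to the
child node that predicts the other. A sample is labeled correctly only if
both stages are correct, so end-to-end accuracy is bounded by root
accuracy on every fold — the package asserts this composition bound rather
than assuming it.

All axes are expressed in anatomical motion-direction coordinates — FB
(forward/backward), TA (toward/away from the midline), ML
(medial/lateral) — via a user-supplied signed bijection from the raw
sensor axes (`AxisMap`). The raw-to-anatomical mapping depends on how each
sensor is mounted, so it is configuration, not a constant.

## Preprocessing

Per axis, in order: a 10-point *trailing* moving average (equal weights;
the warm-up region averages the available prefix so length is preserved);
offset removal by subtracting the mean of the pre-walk standing phase
(residual sensor bias at rest must not masquerade as signal; the pre-walk
phase is used because the protocol guarantees it precedes walking); the
magnitude channel MAG = sqrt(FB² + TA² + ML²) computed from the
offset-removed axes; min–max normalization of FB/TA/ML onto [−1, 1].

Two numerical choices are deliberate:

* Normalization statistics are the min/max of the *walking* phase only.
  Standing samples sit near zero after offset removal and would otherwise
  compress the informative range. Samples outside the walk are clipped to
  [−1, 1] so the output invariant holds everywhere.
* MAG is never rescaled. Dominant-side limbs move with larger amplitude;
  normalizing the magnitude would erase exactly the left/right asymmetry
  the side classifiers need. Consequently a global gain s > 0 on the raw
  axes leaves the normalized axes unchanged and scales MAG by s — a
  property the tests check.

A constant axis (no walking signal) raises a degenerate-input error
rather than silently emitting zeros that would poison features.

## Features

The walking phase is cut into 5-s windows with 50% overlap (at 120 Hz:
600 samples, step 300; 600 samples yield 5 non-overlapping or 9
half-overlapping windows). Windows never straddle the walk boundary.
Each of the four channels contributes 28 features, 112 per sensor:

* 14 moment/order statistics — mean, rms, per25/per50/per75 (linear
  interpolation), std/var (population, ddof 0), min, max, range, iqr,
  skew (Fisher–Pearson g1), kurt (excess), energy (raw sum of squares).
  These conventions are stated so the values are reproducible
  bit-for-bit.
* 5 binned Shannon entropies (10–50 equal-width bins over the window's
  own [min, max], in bits, 0·log 0 = 0; bounded by log₂ m; constant
  windows give 0).
* 9 Higuchi curve lengths L(k), k = 2..10: the normalized average length
  of the signal subsampled at stride k, averaged over the k possible
  offsets. For a straight line L(k) = (N−1)/k exactly. The per-k lengths
  are the features (`k-2` … `k-10`); a single fitted fractal dimension
  would give one feature, not nine. The fitted dimension
  D = −slope of ln L(k) vs ln k is retained for validation: a line gives
  D = 1 to machine precision and white noise approaches D = 2.

Magnitude features carry bare names (`mean`, `k-2`); axis features are
suffixed (`mean-FB`, `k-4-TA`). Feature values depend only on the window's
samples, never on metadata.

Before classification, features are min–max scaled to [0, 1] with
statistics of the *training* rows only, refitted inside every
cross-validation fold; out-of-range test values are clipped and constant
training columns map to 0.

## Selection and tuning

Validation throughout is leave-one-subject-out (LOSO): every subject is
one held-out fold, guarding against subject-specific leakage; the score is
the macro-averaged F1 within a fold, averaged (unweighted) over folds.
Folds whose training set lacks a class are skipped with a warning.

1. **Correlation filter.** Features with |Pearson r| ≥ 0.9 against an
   already retained feature are dropped (absolute value: an
   anti-correlated copy is equally redundant), scanning in table order, so
   the earlier member of a redundant pair survives. Zero-variance features
   are retained but flagged.
2. **Ranking.** A gradient-boosted-tree model (fixed seed, single thread)
   fitted on the retained features orders them by gain importance, ties
   broken by name. The fit uses a canonically name-sorted column order so
   the ranking is invariant to the caller's column permutation.
3. **Recursive feature addition.** Starting from the top-ranked feature,
   each next candidate is kept only if it raises the kept-set LOSO F1 by
   at least 0.01; the kept-set trace is non-decreasing by construction,
   and a perfect first feature blocks all additions.
4. **Tuning.** Five classifier families are supported — one-vs-rest
   logistic regression, k-nearest neighbors, decision tree, SVM, and
   gradient-boosted trees — each with its published parameter grid
   (C/penalty; neighbors/weights/p/algorithm; criterion/depth/split/leaf
   fractions; C/gamma/kernel; learning-rate/depth/subsample). The full
   grids are far beyond desk scale (the SVM grid alone is 50×50×4 points,
   each costing a LOSO pass), so tuning evaluates the library defaults
   plus a seeded uniform random sample of `budget` grid points; the
   defaults are always candidates, so tuning can never fall below them.
   The boosted-tree grid omits an objective axis: modern gradient-boosting
   classifiers select the binary/multiclass objective from the label
   count, and regression objectives are not valid classifier settings.
5. **Tie-break.** Among families within 0.005 F1 of the best (scores are
   conventionally reported to two decimals), the one with the smallest
   measured fit+predict wall time wins: equal accuracy should not cost
   extra compute. Wall times are measured, hardware-dependent, and
   excluded from serialized reports so reports stay byte-reproducible.

Hierarchy evaluation offers two modes. The default refits the entire
selection inside every outer LOSO fold, so no held-out subject influences
feature choice. The faster `refit_per_fold=False` mode selects once on all
rows and refits only the classifiers per fold — this matches the workflow
whose per-node feature tables the method publishes, but it is optimistic:
the held-out subject's windows participated in selection. Which mode a
result used is always stated.

## Synthetic cohort

The study data this method was developed on is not deposited, so the
package ships a generator that emulates the protocol: default 10 subjects,
120 Hz, 10 s standing – 120 s walking – 10 s standing, all six positions,
both sensors. Per subject: gait frequency f ~ U(0.85, 1.05) Hz,
right-dominant gain α ~ U(1.1, 1.3) on all right-side channels,
hand-over-arm gain β ~ U(1.2, 1.5), plus per-axis offsets N(0, 0.05),
white sensor noise (0.05 g / 0.1 rad/s), extra hand jitter (0.08 g), and
1-s raised-cosine ML bursts every 6–8 s emulating turnarounds. Template
amplitudes (accelerometer, g): thigh FB/TA/ML = 0.8/0.3/0.2, arm =
0.5/0.25/0.15, hand = arm × β; gyroscope waveforms are the cosine
(phase-shifted) counterparts scaled ×2. Thighs swing in anti-phase left
vs right and each arm in anti-phase with its ipsilateral thigh.

Where the class signal lives is the deliberate part of the design:

* **Side.** The right-side gain α appears only in the unscaled magnitude
  (normalization erases it from the axes). In addition, the ML waveform
  of the left side is the sign-flipped mirror image of the right side's,
  and the arm/hand ML waveform carries a skewed (shape-asymmetric) second
  harmonic — mirror-image kinematics make left and right differ in
  normalized-axis shape, a subject-independent signature. The thigh ML
  waveform is kept shape-symmetric, so thigh-side discrimination must rely
  on amplitude alone and is the hardest side task, reproducing the
  qualitative ordering the method was designed around (hand/arm side easy,
  thigh side harder). Setting α = 1 and disabling the mirror asymmetry
  removes the side signal entirely and hand-side F1 collapses toward
  chance — a property the tests assert.
* **Segment.** Segments differ in template amplitudes (visible in MAG),
  harmonic content, and the hand's extra jitter (visible in the
  normalized-axis entropy/curve-length features).

What the generator does **not** model: biomechanically realistic joint
kinematics or ground reaction, gravity components and sensor orientation
drift, between-subject amplitude variability beyond the α/β gains,
left-handed subjects, and non-walking activities. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it
assumes, not that the published per-node scores transfer to any real
cohort.

## Problem sizes and budgets

The shipped evaluations use the default 10-subject cohort (2,820 windows
× 112 features per sensor) with a reduced tuning configuration — families
(logreg, knn), budget 2, ranking truncated to the top 10 candidates —
and the selection-once evaluation mode for hierarchy-level scoring; unit
and property tests run on a 3-subject, 30-s-walk cohort. All randomness
flows from a single master seed (subject draws, noise streams, tuning
draws, booster seeds), and running the pipeline twice with the same seed
yields byte-identical reports.

## Known limitations

* The correlation-filter drop rule, macro-F1 averaging, entropy bin
  range, and energy definition are stated conventions, not claims about
  the original study's exact choices, which are unpublished.
* Random-search tuning with a small budget can miss grid optima; the
  defaults-always-included guarantee bounds the loss.
* RFA's ceiling rule stops adding features once the inner CV is perfect,
  which can freeze a feature that separates the training subjects but is
  not subject-independent; the selection-inside-every-fold mode makes
  such fragility visible in the fold scores.
* The 6–8 s turn model and fixed templates make the synthetic task easier
  than real data; scores near 1.0 on the synthetic cohort are expected
  and are not a claim about field performance.
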