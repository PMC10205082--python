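# Methods

This note documents the models, conventions and parameter choices behind
`tkagait`, what the synthetic-cohort generator does and does not emulate,
and the numerical decisions a user may want to audit or change.

## Joint kinematics

**Frames and decomposition.** Both implant frames use x = anterior,
y = proximal, z = medio-lateral. A pose maps femoral-component coordinates
into the tibial-component frame (mm). Rotations follow the
joint-coordinate-system idea of one femur-fixed axis (flexion, about
femoral z), one tibia-fixed axis (internal/external rotation, about tibial
y) and a mutually perpendicular floating axis (ab/adduction), realized as
the factorization `R = Rz(flexion)·Rx(adduction)·Ry(internal)`. Signs:
flexion, adduction and internal rotation positive. The closed-form
extraction (`asin`/`atan2`) round-trips `compose → decompose` to well below
1e-9° across flexion −10..130°, ab/adduction ±15°, rotation ±30°; the
decomposition degenerates as |ab/adduction| → 90° and a `GimbalLockError`
is raised beyond 89°.

**Condylar A-P translation.** Condyle point clouds (femoral frame) are
mapped through the pose into the tibial frame. Per condyle, the 10 points
with the smallest *signed* distance to the tibial plateau plane are
selected — penetration counts as nearest, since the quantity is a contact
proxy — and their A-P coordinates (projection on the plane's A-P axis) are
averaged with weights ∝ 1/(|distance| + ε), ε = 0.1 mm, renormalized to
sum 1. The inverse-distance kernel is a package choice: the original
weighting is not public, so the kernel is isolated behind two parameters
(`n_nearest`, `eps_mm`) and can be swapped. The readout is exactly
equivariant under A-P translation of the pose.

**Cycles, RoM, events.** Tracks are resampled linearly onto 101 points
from heel-strike to heel-strike; both A-P tracks are referenced to the
medial condyle position at initial contact (so medial A-P starts at 0).
RoM is max − min per parameter, split into stance (point 1..toe-off) and
swing (toe-off..101); the toe-off sample belongs to both phases, matching
per-phase tables derived from one continuous trajectory. The intercondylar
A-P difference is `RoM_lateral − RoM_medial` per phase (negative = medial
pivot). Heel-strike is the first upward crossing of 25 N in the vertical
force.

## EMG conditioning

High-pass Butterworth, 50 Hz, 4th order; full-wave rectification; low-pass
Butterworth, 20 Hz, 4th order. Filters run zero-phase (forward–backward)
by default: this doubles the effective order but introduces no group delay
that would bias the centre-of-activity statistic; a `zero_phase=False`
flag gives the causal single-pass variant, and the printed cut-offs are
used as-is in both conventions. Envelopes are amplitude-normalized to the
per-channel maximum over all cycles of one subject-activity (an all-zero
channel normalizes to zero with a warning, never NaN) and time-normalized
to 200 points — stance `[heel-strike, toe-off)` onto 100 points, swing
`[toe-off, second heel-strike]` onto 100 — so envelopes are comparable
independently of absolute phase durations, and a uniform gain on the raw
signal cancels exactly.

## Muscle synergies

**NMF.** `V (8 × 200·cycles) ≈ W (8×k) · H (k×200·cycles)` by
multiplicative updates under the Frobenius objective; the objective is
non-increasing per iteration (asserted in tests). Defaults: 10 random
restarts advanced jointly, best final SSE kept; stop when the relative SSE
improvement over 20 iterations falls below 1e-6 in every restart, or at
1000 iterations. W columns are rescaled to unit maximum with compensating
scaling of H. Reconstruction quality is `R² = 1 − SSE/SStot` against the
input matrix.

**Rank.** Per subject-activity the rank is the smallest k with R² ≥ 0.90
(configurable; the criterion used by the original analysis is not public,
and 0.90 on 8 muscles is consistent with the reported mean ranks of
3.2–3.7). The group-level rank for an activity is the mean of the
per-group mean ranks, rounded half away from zero — reproducing 4 for
level/downhill walking and 3 for stair descent from the published means.

**Classification.** All synergies of one group-activity are clustered by
k-means (50 seeded restarts) on the concatenation of the unit-norm module
(8 values) and the unit-norm activation pattern averaged over cycles and
block-downsampled to 20 points. This feature construction is a package
contract, not a reconstruction of the original one. Within a cluster a
subject keeps only its member closest to the centroid; surplus members are
flagged unclassified, and the classifiable ratio is classified/total.
Clusters are labelled by the functional muscle group with the largest
summed centroid weight: quadriceps → knee extensors, gastrocnemii →
plantarflexors, tibialis anterior → dorsiflexors, hamstrings → knee
flexors; in the 3-synergy scheme used for stair descent the dorsiflexor
and hamstring groups merge. Subjects are processed in sorted order, so the
result is invariant to input ordering.

**Timing metrics.** FWHM subtracts the pattern minimum and counts samples
strictly above half the remaining maximum — integer-valued on the
200-point grid and well-defined for multi-burst patterns; threshold-
crossing interpolation was deliberately rejected. Values are reported in
points of the 200-point cycle with a `fwhm_to_pct` converter (the unit of
the published values is not stated). CoA places sample t (1-based) at
360°·(t−1)/200 — touchdown at 0° — and returns the angle of the resultant
activation vector; the alternative half-sample offset changes results by
< 1°.

## Group statistics

Pooled-variance two-sample t-tests (df = n₁+n₂−2) with Cohen's d on the
pooled SD; the pooled rather than Welch form is an evidence-based choice —
it reproduces the published clinical-score p-value (0.040) from the
printed summary statistics, which Welch does not. The 2×2 chi-squared is
Pearson's without continuity correction, again the form that reproduces
the published 0.168/0.019 from the printed counts. One-way ANOVA uses the
classic F decomposition; for two groups F = t² exactly. Zero-variance
degeneracies: equal means give the null result (t or F = 0, p = 1),
unequal means raise an explicit error.

**Permutation SPM.** Pointwise pooled t over the 101-point cycle; the null
distribution of the maximum |t| over the domain is built from group-label
permutations (exhaustive when ≤ `n_perm`, otherwise a seeded Monte-Carlo
subset that always contains the observed labelling). The critical
threshold is the (1−α) null quantile ("higher" interpolation, slightly
conservative); suprathreshold clusters get the max-statistic permutation p
of their peak. A ridge (default 1e-10) floors the pooled variance at
degenerate nodes. This controls the family-wise error over the time domain
with the same inference contract as random-field-theory SPM but without
its analytic constants; measured type-I error at α = 0.05 over 1000 null
simulations lies within [0.03, 0.07]. Random-field theory is an extension
hook, not implemented.

**Bonferroni families.** Kinematic RoM comparisons form one family per
activity (2 phases × 6 parameters = 12 by default); FWHM and CoA are
corrected within metric × activity, family = number of classified
synergies. The original family sizes are not printed; both sizes are
configurable (`kinematic_family_size`, `timing_family_size`) and recorded
in the config snapshot of every results directory. Cycles are averaged per
subject before any test — repeated cycles are not treated as independent
trials (a documented simplification; no mixed-effects modelling).

## Synthetic cohorts: what is emulated

Study conditions: 10 "stable" and 8 "unstable" knees, 3–5 cycles per
subject (default 4), three activities; poses at 30 Hz, EMG and force
plates at 2000 Hz.

**Kinematics.** Each angle/translation track is a PCHIP bump (or a pair of
opposite-signed half-bumps) per gait phase on top of a baseline; because
PCHIP never overshoots its control values, the drawn stance/swing RoM is
hit exactly. Stance/swing RoMs are drawn per subject from normal
distributions centred on the published group statistics (rotations and
medial A-P, per activity and group), cycles add 5 % multiplicative
amplitude jitter; `subject_noise=0, cycle_noise=0` gives the exact group
template. Toe-off defaults to 60 % (level/downhill) and 65 % (stair) of
the cycle — the published figures show toe-off only as dotted lines, so
these are package choices — with ±1.5 % between-subject jitter. Cycle
durations are 1.10/1.15/1.40 s with 5 % subject and 2 % cycle jitter; the
sources print no within-subject variance figures, so these magnitudes are
free parameters chosen to look like ordinary repeated gait cycles.

Poses are built by composing the angle curves; the vertical translation
seats the condyle spheres just above the plateau plane and the A-P
translation is solved per frame so the medial condylar readout equals the
prescribed track exactly (the readout is linear in that translation
component). The lateral track is then *derived*: physically it equals the
medial track plus the vertical-axis rotation times the intercondylar
separation (42 mm), which is why the internal-rotation and medial-A-P
phase shapes are de-phased — with in-phase unimodal bumps the lateral
condyle would barely move. The derived lateral RoM lands in a realistic
5–9 mm range but is not calibrated to the published lateral statistics;
treat lateral-condyle group comparisons on synthetic data as qualitative.

Acute-instability events superpose a posterior-then-anterior excursion
(half-sine-squared lobes) confined to the 55–80 % cycle window. 'both'
shifts the solved A-P translation directly; single-condyle variants act
through an internal-rotation increment of excursion ÷ (separation ×
cos flexion × cos rotation), because a rigid transform cannot translate
one condyle alone. The cancellation on the unaffected side is exact for
medial (it is re-solved) and leaves ≤ ~1 mm leakage on the lateral side
for 4 mm medial-only events — a geometric consequence, documented rather
than hidden.

**EMG.** Ground truth is k = 4 modules (level/downhill) or 3 (stair) with
near-disjoint muscle weightings and circular-Gaussian activation bumps
placed per the published timing descriptions (extensors early/throughout
stance, plantarflexors late stance or mid-late swing, dorsiflexors early
stance + early swing or sustained, flexors late swing/early stance). The
per-cycle envelope `W·H` (with 10 % per-subject module jitter and 5 %
per-cycle amplitude jitter) is mapped onto the trial's real time axis and
multiplies a zero-mean, unit-RMS, 50–450 Hz band-limited Gaussian carrier;
additive white noise has SD = 5 % of the envelope maximum plus a tiny
absolute floor. This carrier model is chosen because the conditioning
chain provably recovers the envelope up to a gain the amplitude
normalization absorbs. The module cross-talk is kept small (≈ 0.05) so the
planted rank is the true dimensionality of the data: the rank-(k−1)
reconstruction stays clearly below the 0.90 R² threshold while the rank-k
fit exceeds it through the full processing chain. A
`flexor_width_scale` knob widens the flexor-pattern σ to plant the
prolonged-flexor-activation group effect.

**Force.** Stance vertical force is the classic two-lobe shape
`BW·max(0, sin πu + 0.3·sin 3πu)` (body weight ~N(750, 100) N per
subject), zero in swing, with a 0.15 s zero lead-in; the stored
heel-strike is the first noise-free sample ≥ 25 N, so detection reproduces
it exactly without noise and within ~1 ms under 5 N sensor noise.

**Seeding.** One master seed; every (purpose, subject, cycle) gets an
independent `SeedSequence` spawn stream, so regeneration is bit-identical,
the three generators (poses, EMG, force) agree on trial timing without
sharing state, and adding a subject never perturbs existing ones.

**What is not emulated — and what passing tests therefore show.** No
fluoroscopic imaging or registration error, no soft-tissue artefact, no
electrode crosstalk or motion artefact, no waveform-level fidelity of the
kinematic curves (only their per-phase RoM statistics), no correlation
structure between kinematics and EMG within a subject, and no
patient-reported outcomes. Passing tests demonstrate that the analysis
chain is correct and well-calibrated (it recovers planted truths and holds
its nominal error rates); they do not certify performance on real
fluoroscopy/EMG recordings.

## Problem sizes used in checks

The recovery experiment uses 20 seeded runs of 10 subjects × 4 cycles
(the cohort-scale configuration); SPM calibration uses 1000 null
simulations with 400 permutations each; the end-to-end planted and null
runs use the full 10 + 8 cohort at 4 cycles on stair descent. These sizes
keep the whole verification suite in the minutes range on a single CPU
while leaving the statistics well-resolved.

## Known limitations

- Lateral condylar statistics of the generator are emergent, not
  calibrated (see above).
- The NMF rank threshold (R² ≥ 0.90) and the k-means feature space are
  package contracts; published results depending on different choices
  would differ.
- Bonferroni family sizes are configurable guesses, not reconstructions.
- The permutation SPM reports max-statistic cluster p-values; it does not
  reproduce random-field-theory cluster-extent inference.
- PLY reading requires the optional `trimesh` dependency; CSV point clouds
  are the native format.
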