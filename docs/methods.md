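# Methods

`egopoint` analyses (and simulates) an egocentric pointing test of spatial
orientation and memory: a participant stands at a fixed spot in a ~6 × 7 m
room and points a mobile phone at 15 named targets under four conditions —
eyes open (EO), eyes closed (EC), after a real 90° body rotation (RR), and
after an imagined 90° rotation (MR).  The device reports each trial as a
unit vector in East/North/Up (ENU) world coordinates.  This note documents
the model, the estimators, the numerical choices, and what the synthetic
cohort does and does not emulate.

## Geometry and conventions

The ENU vector (e, n, u) is converted to body-referenced angles:

- elevation = asin(u), degrees in [−90, 90], positive up;
- azimuth = atan2(e, n) − facing heading, wrapped to (−180, 180], positive
  to the participant's right (clockwise seen from above).

Azimuth is flagged non-analysable within 0.1° of the poles, and the
straight-overhead target is scored in elevation only (its azimuth is
physically meaningless).  The great-circle error between two directions is
computed via the atan2 form, which keeps full precision near zero.

Because the original target names and coordinates are not published, the
default roster is a systematic geometric stand-in: 15 named targets placed
on azimuth rays from −90° to +90° (7 left, 7 right, one straight up) and
elevations from −20° to +90°, at ranges that put every target inside the
room.  Positions are stored and the true directions re-derived from them,
so the roster is self-consistent; it is fully user-configurable.

## Circular statistics

For angles θᵢ with optional weights wᵢ: C = Σwᵢcosθᵢ, S = Σwᵢsinθᵢ, the
circular mean is atan2(S, C) and the mean resultant length R =
√(C² + S²)/Σwᵢ.  The circular SD is √(−2 ln R) (the "std" convention of
the common circular-statistics toolboxes); the angular deviation
√(2(1 − R)) is also exposed but nothing defaults to it.  R < 1e−12 flags
the mean undefined with infinite SD.

Uniformity is tested with the Rayleigh statistic z = nR² and the classic
small-sample-corrected p-value
p = exp(√(1 + 4n + 4(n² − n²R²)) − (1 + 2n)); Watson's U² is available as
an omnibus alternative.  The test suite verifies the type-I error rate is
within [0.03, 0.07] at nominal 0.05 for n = 20.

The von Mises concentration κ is estimated by inverting A(κ) =
I₁(κ)/I₀(κ) = R with the Best–Fisher piecewise approximation, with
Fisher's small-sample bias correction for n ≤ 15.  Samples with R
numerically 1 saturate at κ = 10⁶ with a `saturated` flag.

**Two-component von Mises mixture.**  MR azimuth errors are bimodal (a
main mode plus systematic 90/180° flips), so moments are extracted from a
2-component mixture fitted by EM: log-density arithmetic throughout
(scaled Bessel functions, logsumexp), convergence when the log-likelihood
gain falls below 1e−8 or after 500 iterations, best of 5 seeded restarts.
The first restart starts at the single von Mises fit, so the mixture
log-likelihood never falls below the k = 1 fit.  Degenerate fits — a
component weight below 1/n, or component means within 20° of each other
(EM on unimodal data routinely splits the mode into two overlapping
components) — collapse to the single-component fallback with a flag.  The
mixture exists to find well-separated flip modes, so the 20° merge
threshold is far below the 90° separation of interest.

## Scoring against the EO baseline

There is no instrumented ground truth for target positions inside a room,
so each participant's pooled EO trials define a per-target baseline: the
circular mean azimuth and arithmetic mean elevation (elevation cannot
wrap, so it is treated as linear; a fully circular treatment of elevation
is available via the raw circular primitives).  Every trial is then scored
as

- azimuth error: signed circular distance from the expected azimuth
  (positive = right of expected),
- elevation error: signed difference (positive = above),
- total error: great-circle angle to the expected direction.

**Expected directions per condition.**  EO, EC and RR use the baseline
unchanged — a physical rotation does not move the target's world
direction, and azimuth is referenced to the original facing.  For MR the
imagined rotation is part of the task: by default the expected azimuth is
shifted by −90° for an imagined rightward rotation (+90° leftward), so MR
errors measure updating accuracy.  An unshifted mode
(`mr_transform=False`) scores MR against the raw baseline, in which a
perfect mental rotator shows ±90° "errors"; this is the mode in which the
bimodal structure is most visible and is kept for comparability.  Which
frame the original analysis used is not stated; both are provided and
neither is asserted as canonical.

**Sensor flips.**  The phone compass can flip 180° for strongly downward
pointing.  Trials with elevation below −15° and azimuth error within 20°
of ±180° are flagged as suspected sensor flips and excluded from summaries
by default (policy switchable).

## Dispersion estimation

Per-target SDs are the primary reliability-of-measurement quantity.  The
plain circular SD estimator √(−2 ln R̂) is biased low at small n: for
concentrated data −2 ln R̂ ≈ (n−1)/n · σ², so at the 6–8 repetitions used
per target the bias is about −σ/16 (≈ −0.5° at σ = 8°).  Analysis
summaries therefore apply a Bessel-style √(n/(n−1)) factor to the circular
SD and use ddof = 1 for linear elevation SDs.  The raw (uncorrected)
convention remains available in the circular-statistics layer.  With this
estimator, a simulated 20-participant cohort recovers the configured EO
dispersions to within 0.2° (azimuth) and 0.1° (elevation) on average.

## Reliability

Two-way intraclass correlations in the McGraw–Wong taxonomy are computed
from the subjects × items mean-square decomposition; ICC(C,k) equals
Cronbach's α, and the suite verifies the identity to 1e−10 against the
independent item-variance formula.  Confidence intervals use the exact F
interval for the consistency forms and the Satterthwaite approximation for
absolute agreement (cross-checked against pingouin).  Internal consistency
of the pointing test uses participants as rows and targets as items, on
per-target mean angles.  Azimuth angles are unwrapped about the pooled
circular mean before the linear decomposition — a necessity for circular
data, documented as a deviation from the plain linear ICC.  Test–retest
(EO day 1 vs day 2, days as items over participant × target units)
defaults to ICC(C,1), the conventional single-measure coefficient; an
average-measure (α-type) form is selectable.

## Condition effects and correlations

Per-participant mean |azimuth error| per condition feeds a one-way
repeated-measures ANOVA (participant as blocking factor) with
(c−1, (c−1)(s−1)) degrees of freedom, reported alongside a
within-participant label-permutation test (seeded, resolution
1/(n_perm+1)).  The F computation is vectorised so the permutation null is
exact re-computation, not an approximation; the suite verifies F equals
the paired t² for two conditions, agreement with statsmodels' AnovaRM, and
uniform null p-values.  Pearson correlations between pointing metrics and
questionnaire scores (SBSOD, Perspective Taking, Wayfinding Strategy,
Spatial Anxiety) are reported with raw two-sided p-values plus
Benjamini–Hochberg FDR across the requested pairs.

## The synthetic cohort

The generator emulates the study conditions: 20 participants, two days,
fixed pseudo-randomised schedules with left/right alternation (8 EO
repetitions day 1, then 6 EC; 6 EO + 6 RR + 6 MR day 2 — 120 and 90-trial
blocks), balanced rotation-side assignment, and ~10% left-hand pointers.

Noise model per trial: azimuth ~ von Mises centred on the expected
direction plus a per-participant bias (SD 2°), with κ = 1/σ²;
elevation ~ normal truncated to [−90, 90].  Baseline dispersions are
anchored to the observed cohort values, σ_az = 7.93° and σ_el = 3.83°;
the EC/RR/MR multipliers (1.5, 2.0, 2.5) are free parameters chosen to
reproduce the qualitative difficulty ordering EO < EC < RR < MR — no
per-condition dispersion values are published, and nothing here claims to
match them.  MR trials flip by −90°, +90° or 180° with probability 0.2;
targets at |azimuth| ≥ 75° contralateral to the pointing hand get their
azimuth SD doubled; an optional compass-flip artifact adds 180° to
azimuth for targets below −15° elevation.  Every draw comes from a named
random stream derived from (seed, participant); enabling one artifact
never perturbs the other draws, and sessions are byte-reproducible.

What it does **not** emulate: learning/order effects across repetitions,
auditory-landmark cues from the experimenter's voice, target-specific
difficulty beyond the laterality effect, and any real sensor noise
spectrum.  Passing recovery tests therefore show the pipeline's
estimators are calibrated under the assumed noise model, not that the
model captures every feature of real sessions.

## Problem sizes and test design

The suite runs at desk scale: calibration uses 2000 uniform samples
(Rayleigh) and 1000 null cohorts of 10 × 4 (ANOVA, 199 permutations
each); recovery uses the full 20-participant cohort at the default
repetition counts; the MR flip-mode recovery property pools MR errors
across a 4-participant cohort per seed (50 seeds) because the secondary
mode's ML uncertainty at one participant's ~18 flipped trials (~5° SE)
is comparable to the 10° criterion, and the bimodality is a cohort-level
phenomenon.  The flip-recovery scenario uses the single 180° artifact
angle; a 2-component mixture cannot represent three flip modes at once.

## Known limitations

- Azimuth and elevation are modelled in separate planes; no joint
  spherical (Kent/Fisher–Bingham) model is provided.
- Reliability on circular data relies on unwrapping about the pooled
  mean, which is only safe when the spread is well below 180°.
- The default roster is a geometric stand-in, not the original room's
  targets; absolute per-target values are not comparable to the original
  cohort, only the structure of the analysis is.
- The rm-ANOVA assumes complete condition cells; participants with
  missing conditions must be imputed or excluded by the caller.
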