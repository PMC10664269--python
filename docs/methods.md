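# Methods

This note documents the models, numerical choices and limitations behind
kinegen: what the synthetic trials emulate, how the kinematic chain is
computed, what the outcome formulas mean, and how the statistical layer is
calibrated.

## Synthetic jump trials

Each trial is built from a closed-form vertical trajectory of the pelvis
(hip centre) and a planar two-link leg chain hung off it, then converted to
marker positions and a vertical ground-reaction force.

**Trajectory segments.** Quiet standing; an eccentric descent along a raised
cosine (starts and ends at zero velocity); a propulsion segment with a cubic
velocity profile constrained to rise the countermovement depth, reach the
takeoff velocity `v = sqrt(2 g h)` for the configured flight height `h`,
and end with acceleration exactly −g, so the ground-reaction force fades
smoothly to zero at takeoff (and, as in real force traces, the centre of
mass reaches peak velocity slightly *before* takeoff — the ground truth
records both `v_takeoff` and `v_peak`); ballistic flight; and a landing
brake whose force grows smoothly from zero at touchdown. Squat jumps start
from a held 90° squat with no eccentric phase; drop jumps start standing on
a box (default 0.20 m), fall ballistically, and split their ground contact
into an eccentric brake and the propulsion rise whose durations are solved
(Brent's method on the dip depth) so the total equals the configured contact
time exactly.

Configurations that would require a negative ground-reaction force (an
eccentric descent faster than free fall) or fold the two-link chain past a
45° knee angle are rejected as config errors rather than silently clipped.

**Leg chain and markers.** The foot is fixed during ground contact, the hip
stays directly above the ankle, and the knee position follows from two-link
inverse kinematics on the pelvis height (shank and thigh 0.40 m by default).
Left/right markers are mirrored at a fixed pelvic half-width of 0.12 m;
airborne frames translate the takeoff pose rigidly. Marker noise is
isotropic Gaussian with configurable sd (0 by default; 2 mm is treated as
the upper end of optical-capture jitter). The eleven-marker set and the
sagittal-only linkage match what the angle computations consume; no
three-dimensional joint rotations, arm swing, soft-tissue artefact or
marker occlusion are simulated, so passing tests demonstrate correctness of
the processing chain, not robustness to every artefact of real captures.

**Force synthesis.** `fz = m (g + z̈_com)` during contact and exactly zero
in the air, with the sacrum/pelvis trajectory standing in for the centre of
mass. Marker data default to 200 Hz and the force channel to 1000 Hz,
matching common camera/plate rates. Impulse–momentum consistency
(`∫(fz − mg) dt = m v_takeoff` over propulsion) therefore holds by
construction and is verified numerically by a trapezoid-rule oracle.

**Sprints** translate the standing chain forward with constant acceleration
(plus a small sinusoidal vertical bob); the sacrum marker itself is the
reference the virtual timing gates watch, and its exact plane-crossing
times are recorded as ground truth. Leg articulation during running is not
modelled — only gate timing is consumed downstream.

**Cohorts.** Genotypes at two loci are drawn from Hardy–Weinberg
proportions (p², 2pq, q²; effect-allele frequency 0.5 by default). The
target outcome is `baseline + effect · code(genotype) + N(0, sd)` under an
additive or complete-dominance code; alternatively a Cohen's f can be
given, from which the homozygote shift is derived using the Hardy–Weinberg
genotype weights. The realised allele frequencies and shifts are returned
as a truth record. Covariates (height ~ N(1.58, 0.05) m, BMI ~ N(23, 2),
age uniform 18–45, all female) are plausible for a moderately trained
Southeast Asian female cohort but are defaults, not fitted to any dataset.

## Kinematics

Joint angles are inner angles at the vertex marker, in degrees (standing
knee ≈ 180°, parallel squat ≈ 90°, matching goniometer convention): hip at
the trochanter from (ASIS, trochanter, condyle), knee at the condyle from
(trochanter, condyle, malleolus). One published figure caption lists the
knee triplet as (B, C, E); the accompanying text's (B, C, D) is
implemented, and the `triplet` argument lets a user override either way.
Angles and positions are conditioned with a zero-phase (forward–backward)
Butterworth low-pass — "4th order" in the conventional effective sense, so
the underlying design order is halved — at a default 10 Hz cutoff before
central-difference differentiation. All angular quantities stay in degrees
end to end (deg, deg/s, deg/s²) because the torque formula below consumes
them that way.

## Event detection

- **Flight**: maximal runs of `fz` below 10 N lasting ≥ 50 ms, with
  crossing times linearly interpolated at the threshold. The *longest*
  airborne run is taken as the jump flight: a vigorous countermovement can
  unweight the plate below threshold briefly without takeoff. Runs touching
  the record edges are kept (a drop jump starts off-plate).
- **Movement onset** (SJ/CMJ): first sustained deviation of `fz` from
  quiet-standing body weight exceeding max(5 × quiet SD, 10 N) — the
  conventional body-weight-deviation rule, used because marker-velocity
  thresholds are noise-limited at the millimetre level.
- **Drop-jump step-off**: the pelvis markers (sacrum, both trochanters,
  both ASIS) are averaged after removing their constant offsets — a
  rigid-body composite that suppresses jitter by √5 — and the onset of
  downward velocity is located by fitting a line to the velocity ramp
  between 20% and 60% of its peak and extrapolating to zero.
- **Eccentric/concentric split**: the upward zero-crossing of the composite
  pelvis velocity, again located by back-extrapolating the concentric rise;
  the minimum of the height curve itself is locally flat and therefore
  noise-dominated.
- The drop-jump "landing" label L1 between fall and eccentric phase is a
  zero-length boundary at touchdown: the contact interval is split
  exhaustively into E and C.
- Phase intervals are half-open frame ranges and must be ordered
  D ≺ F1 ≺ L1 ≺ E ≺ C ≺ F2 ≺ L2.

On 200 simulated trials (mixed types, flight heights 0.15–0.35 m, noise up
to 2 mm) every detected phase boundary lies within 2 frames of ground truth
at 200 Hz, and both jump-height methods are within 5% of truth (within 2%
of each other on noise-free trials).

## Outcome formulas and units

Relative torque is implemented literally as printed in the study-design
table: `RT = segmental mass (kg) × angular acceleration (deg s⁻²) / total
body mass (kg)`. Because the angular acceleration stays in degrees, RT is
*not* a newton-metre quantity despite the table's "(Nm)" annotation; it is
a mass-normalised angular-acceleration measure, comparable within and
between participants as long as everyone uses the same convention. No
silent deg→rad conversion is applied; the tension is documented here
instead. Likewise the table prints the same formula for "Power" and "Peak
Power"; the peak is taken as the within-phase maximum of the same series.
"Ground count time" is read as ground contact time.

Segmental masses come from a fraction-of-body-mass table (adult female
averages: thigh 14.78%, shank 4.81%, foot 1.29%, trunk 42.57%), shipped as
an editable `AnthropometryConfig`. The hip outcome uses the whole extensor
chain distal to the joint (thigh + shank + foot, one side), the knee
outcome shank + foot; the source table was not pinned by the study design,
so the config keeps the choice explicit and swappable.

Jump height by the marker method needs a standing reference for the sacrum
apex: mean over quiet standing (L1) for CMJ, mean over on-box standing (D)
minus the box height for DJ, and the height at the takeoff instant for SJ,
which starts in a held squat and has no standing phase. Aggregation across
a participant's repeated trials is `mean` or `best` (maximum, except
minimum for sprint and ground-contact times); RSI and IReaF are recomputed
from the aggregated heights and contact time so the stored indices always
satisfy their defining ratios.

## Statistical layer

η² is SS_between/SS_total, defined as 0 for globally constant data. The
percent-of-ANOVA-variance statistic for a genetic model is
`100 · r² / η²`, where r² is the squared Pearson correlation between the
coded genotype and the outcome; ties for the best model break toward the
additive code. For the ACTN3 R577X locus the ACE coding scheme is mirrored
with X as the loss-of-function allele. The carrier-group comparison uses
Welch's t by default (pooled-variance t by flag) since group variances are
not assumed equal; normality is screened with a one-sample
Kolmogorov–Smirnov test against each group's fitted normal — with estimated
parameters this screen is conservative, and it gates nothing. The
likelihood-ratio test compares nested Gaussian OLS fits by maximum
likelihood (equivalently `n·log(RSS_null/RSS_full)`) against χ² with the
number of dropped columns as degrees of freedom. No multiple-testing
adjustment is applied by default; p-values are reported raw.

Monte-Carlo ANOVA power spaces equally separated group means so that their
allocation-weighted standard deviation equals `f` exactly at unit
within-group sd (noncentrality `f²N`), and simulates with a seeded
generator; estimates agree with the noncentral-F closed form within
Monte-Carlo error. At the planned design (k = 3, N = 269, f = 0.25,
α = 0.05) the estimated power is ≈ 0.96, comfortably above the 0.80 design
bound; the published figure of 269 itself presumably reflects additional
design factors that were not specified, so only the bound is checked.
Attrition inflation is `ceil(n · (1 + rate))`: 269 → 283 at 5%.

Calibration (2000 null replicates each, fixed seeds): Hardy–Weinberg χ²,
Welch t and the LRT all reject at rates within [0.03, 0.07] at α = 0.05. A
D-dominant architecture with a 0.5 SD homozygote shift at n = 1000 is
identified as the best model in ≥ 90% of 200 replicates (98% observed);
0.5 SD is a moderate candidate-gene effect chosen as the reference
detectable architecture.

## Pipeline and file formats

Marker and force data travel in pinned tab-separated dialects (header keys
`FREQUENCY`, `MARKER_NAMES`, `UNITS` m/mm, `GAP_ZERO`; one frame per row)
so round trips are bit-exact; an all-zero coordinate triple is read as a
lost marker under the usual optical-capture convention, and gaps are
linearly interpolated up to 10 consecutive frames, beyond which the trial
is rejected. Genotypes and covariates are an ordinary headed CSV. Binary
capture formats are out of scope; the TSV dialect is the single ingestion
path.

`run_pipeline` is deterministic given config and seed: per-trial outcomes,
per-participant aggregates, Hardy–Weinberg per locus, and the association
battery per outcome × locus, with failed trials logged and excluded rather
than aborting the run. Questionnaire-based exclusions are applied as
boolean flags (`parq_positive`, `power_sport`), and the analysis is
stratified by the `sex` field (single-sex by default) rather than pooling.

## Problem sizes used in the checks

The shipped verification uses 200 simulated trials for ground-truth
recovery, 2000 null replicates per calibration check, 200 replicates for
architecture identification at n = 1000, and 1000 replicates for the power
bound at N = 269 — sizes at which the Monte-Carlo error is far smaller than
the tolerances being checked.

## Known limitations

- The simulator's centre of mass is the pelvis; trunk/arm segments do not
  move relative to it, so whole-body COM subtleties (arm swing
  contribution, heel-raise at takeoff) are absent.
- Landing mechanics are a smooth brake, not an impact with ringing;
  flight-detection debouncing is therefore exercised only by synthetic
  dropouts in tests.
- The degree-based torque/power outcomes are internally consistent but not
  SI joint moments; treat them as relative measures.
- The sprint model is rigid translation: adequate for gate timing, not for
  running kinematics.
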