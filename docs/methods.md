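# Methods

## Lifting equation

The RNLE module implements the metric Applications-Manual multiplier
definitions behind `RWL = LC·HM·VM·DM·AM·FM·CM` (LC = 23 kg):
HM = 25/H with H clamped to [25, 63] cm, VM = 1 − 0.003|V − 75| for
V ∈ [0, 175] cm, DM = 0.82 + 4.5/D with D clamped to [25, 175] cm,
AM = 1 − 0.0032·A for A ∈ [0, 135]°, and FM/CM from the published lookup
tables (shipped as `data/fm_table.csv` and `data/cm_table.csv`; frequency
is rounded up to the next tabulated row, and frequencies below
0.2 lifts/min use the 0.2 row). A variable beyond its admissible range
zeroes its multiplier and flags the task as not recommended. Risk bands
for reporting are low ≤ 1 < medium ≤ 2 < high ≤ 3 < very high, matching
the three designed study conditions; a 1e-9 tolerance keeps indices
designed to sit exactly on a boundary inside their intended band.

Inverse design (`design_task_for_li`) moves the free geometry variables
(subset of H, V, D) along a single severity coordinate from their neutral
values (multiplier = 1) to the worst admissible values and root-solves
`LI(s) = target` by bisection; RWL is monotone along this path, so the
root is unique when it exists. Reachable targets are bounded by the 23 kg
load constant above and by the worst admissible geometry
(≈ 5.98 kg × FM·AM·CM of the template) below; outside that window the
designer raises an infeasibility error by intent.

## Signal conditioning

Kinematic and force channels: 4th-order zero-phase Butterworth low-pass at
6 Hz (reflective padding of 3× the filter order against edge transients).
Lift cycles are segmented on the vertical box velocity: start at the first
sample above 0.025 m/s, end at the first sample after the global
displacement maximum where the velocity falls back below +0.025 m/s. The
end rule deliberately uses the threshold magnitude rather than a sign
reversal, so it captures both settling-to-rest and small negative
overshoot; this is a documented reading of an ambiguous convention, not an
asserted equivalence.

EMG: 20–400 Hz 4th-order band-pass, full-wave rectification, 5 Hz
4th-order low-pass (all zero-phase), amplitude normalisation to the mean
of the three iMVC peaks per channel, and, where a fixed-length cycle
representation is needed, shape-preserving piecewise-cubic (PCHIP)
resampling to 201 samples on the normalised time axis. PCHIP was chosen
for the unspecified "polynomial" reduction because it is endpoint-exact
and does not overshoot non-negative envelopes.

## Trunk model

A planar sagittal reduction replaces the full 238-MTU lifting model: one
rigid trunk segment (lumped arms + head) on the pelvis at L5-S1, a
hand-held load at the knuckle lever, six active lumped MTU groups mapped
to the six bilateral EMG channels, and one passive pool for the
unmeasured deep muscles (constant 0.01 excitation plus passive
force-length only — how unmeasured muscles are driven is not prescribed,
so the minimal choice is used). The published channel→MTU mapping is
retained as metadata (`data/emg_mtu_mapping.csv`, 11 rows totalling 238
units) and distributed over the lumped groups.

Conventions: lumbosacral angle θ is flexion-positive, moments
extension-positive. Moment-arm magnitudes r(θ) are low-order polynomials;
MTU length integrates the arm, `l_mt(θ) = l_ref + role·∫r dθ` with
role = +1 for extensors (which lengthen with flexion) and −1 for flexors,
so role·r = dl/dθ exactly (equivalently r = −dl/dθ in the extension-angle
coordinate). The model range is θ ∈ [−0.2, 1.6] rad.

Hill curves (rigid tendon, zero pennation; constants in
`trunk_model.py`): Gaussian active force-length
`f_l = exp(−((l̃−1)/0.45)²)`; hyperbolic force-velocity with f_v(0) = 1,
zero at normalized shortening velocity −1, eccentric plateau 1.4;
exponential passive curve `f_p = (e^{10(l̃−1)} − 1)/(e^5 − 1)` for l̃ > 1,
capped at 1; maximal shortening velocity 10 optimal lengths/s. The
activation nonlinearity is `a(u) = (e^{Au} − 1)/(e^A − 1)` with shape
factor A ∈ [−3, 0), linear in the A → 0 limit. The rigid tendon avoids an
inner equilibrium solve; calibration absorbs the systematic offset this
introduces relative to elastic-tendon formulations.

Inverse dynamics: `M = I·θ̈ + (m_t d_t + m_ah d_ah) g sinθ + F_load·d_load·sinθ`,
with θ̈ by central differences on the 6 Hz-filtered angle (one-sided at
the endpoints) and F_load the vertical hand force including the box's
inertial contribution. Joint reaction: Newton–Euler balance of the trunk
free body with all muscle lines of action parallel to the trunk axis, so
muscle tension loads the joint in pure compression; compression is the
joint-force component along the trunk longitudinal axis at the current
flexion angle (a proxy for the sacral endplate normal, which the planar
model cannot orient), shear the anteroposterior component, with
centripetal/tangential trunk inertia included. Moments are normalized by
body mass (N·m/kg) and forces by body weight (dimensionless), matching
the units in which such results are conventionally reported; compression
is additionally flagged against the 3.4 kN guideline limit.

## Calibration

Objective: mean over calibration trials of the RMSE between EMG-driven
and inverse-dynamics moments, each normalized by that trial's peak |M_id|
so low- and high-risk trials weigh equally despite different magnitudes.
Left/right homologous groups share parameters (symmetric lifting). The
default adjustable set is 7-dimensional — an f_max scale (bounds
[0.5, 2.5]) and a shape factor A (bounds [−3, −0.001]) per group type,
plus one shared optimal-length scale ([0.5, 1.5]) — optimised by bounded
Powell search from the neutral point plus seeded uniform restarts
(default 5), deterministic per seed. Calibration uses the LI1 and LI3
trials; LI2 is held out for validation. Parameter-recovery experiments
use the strength scales alone as the adjustable set, since those are the
only parameters the generator varies between subjects; with the full set
the strength/shape trade-off leaves a shallow objective ridge and
recovery is correspondingly looser.

## Synthetic data generator

The generator emulates the study conditions so the pipeline is testable
without recordings: 7 subjects × 3 conditions (designed to LI = 1, 2, 3
with 21/21/20 kg; identical AM, FM, CM) × 3 repetitions; motion at
340 Hz, EMG at 1000 Hz. Subjects draw body mass ~ N(75, 8) kg truncated
to [55, 100] and BMI ~ N(24.70, 1.80) (stature derived); segment
parameters use fixed fractions (trunk 43% of body mass, trunk length 30%
of stature, COM at 45% and hands at 100% of trunk length, arms + head 15%
of body mass at 55%). Box motion is minimum-jerk from V to V+D over 2 s
with a 0.5 s lead-in and 0.7 s settling tail (velocity noise 0.004 m/s,
safely below the segmentation threshold). Trunk flexion is a sin² arc
peaking at 45/65/85° (± 3° subject jitter) for the three risk levels, so
range of motion rises strictly with risk.

EMG is synthesised by pipeline inversion: the inverse-dynamics moment is
distributed over the extensor groups as a(t) = c(t)·w_g(θ) — the
iliocostalis weight rises with flexion (w = 0.7 + 0.3θ), which keeps the
two extensor groups' activation profiles distinguishable — with
antagonist co-activation 0.05 + 0.03·level (making compression grow
faster than moment across levels, the structure the cluster analysis
exploits); activations are inverted to excitations and multiplied onto
band-limited (20–400 Hz) Gaussian carriers scaled so the processed
envelope reproduces the excitation in iMVC units. Per-trial ground truth
(excitations, moments, loads, strength scales ~ U(0.8, 1.2) per group
type) is stored for recovery tests.

What the generator does **not** emulate: soft-tissue artefact,
electrode-placement and crosstalk effects, marker occlusion, fatigue,
inter-repetition strategy changes, or any 3D/asymmetric component.
Passing tests therefore demonstrate internal consistency of the method
chain under the stated noise model, not field validity on real
recordings, and the paper's subject-level numbers (which depend on
unavailable raw data) are not reproduction targets — only the procedures
and the directional structure are.

## Statistics and clustering

Normality per metric and risk level by Shapiro-Wilk (3 ≤ n ≤ 5000).
Between-level comparisons use the Wilcoxon signed-rank test with trials
paired by (subject, repetition) — n = 21 pairs at full scale — with
Bonferroni correction over the three level pairs; z is reported from the
normal approximation of the W statistic with the sign convention that the
lower level's smaller values give negative z. Cluster analysis:
(peak moment, peak compression) standardized to zero mean/unit variance,
k-means with 10 seeded initialisations, default k = 6 with a silhouette
scan over k ∈ [2, 8] reported alongside (the choice of 6 is an adopted
outcome, not derived); clusters are relabelled by ascending compression
centroid, pairwise separation is tested with Welch's t (negative when the
lower-labelled cluster has the lower mean), and the cluster-vs-LI
cross-tabulation is computed with marginals preserved. Peak extraction is
peak-then-average across left/right homologous channels; whether
averaging should precede peak extraction is ambiguous, and the
implemented order is the documented choice.

## Problem sizes and runtimes

The analysis scripts run the full study-sized dataset (63 trials) with
calibration at 3 restarts × 1500 objective evaluations per subject
(~100 s total on one core). The test suite uses 2-subject datasets for
per-trial machinery and a single study-sized pipeline run with a reduced
optimiser budget (2 restarts × 600 evaluations) — sufficient because the
objective reaches its floor (~0.02 normalized RMSE, limited by envelope
extraction noise rather than the optimiser) well before the full budget.
Known limitations beyond those above: no ligaments or intra-abdominal
pressure in the joint balance, no elastic tendon, lumped rather than
distributed musculature, and a planar (sagittal, symmetric) world.
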