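# Methods

This note documents the models, conventions, and numerical choices the
package implements, what the synthetic generator does and does not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions and data model

All kinematics live in a right-handed global frame, Z up, meters,
seconds. Quaternions are stored (w, x, y, z) and rotate tracker-local
axes into the global frame; the ankle tracker's local x-axis points
along the foot, the navel tracker's x-axis points upward. A session is
three streams (left ankle, right ankle, navel) nominally at 90 Hz with
a shared clock starting at the first sample.

Tracking dropouts are represented as half-open `[t_start, t_end)`
intervals. A gap is declared wherever an inter-sample interval exceeds
`max_gap_factor` (default 3) nominal periods. Strides that overlap any
gap of any stream are excluded from every downstream summary — a
per-stride analogue of discarding whole sessions with tracking loss,
chosen because it preserves the rest of an otherwise usable session.
Events are detected on native timestamps; nothing is resampled, to
avoid interpolation artifacts near the extrema that define events.

## Maze model

Mazes are rows × cols grids (default 7 × 8 = 56 blocks of 0.56 m) whose
open passages are carved as a randomized-DFS spanning tree from a
seed-chosen corner entry. Because passages form a tree, the simple path
between entry and any exit is unique by construction; tests verify this
independently by exhaustive path enumeration. The exit is a seed-chosen
perimeter cell among those whose path from the entry spans at least
max(rows, cols) cells — a minimal complexity control that keeps
generated mazes comparable and guarantees grid-spanning solution paths.

Completion time is defined as the time from the first navel sample
inside the entry cell to the first subsequent navel sample inside the
exit cell. This timer definition is this package's own convention (the
endpoints of the classic completion-time measure are not standardized);
anyone comparing against other instruments should check endpoint
conventions first.

## Gait events

The shank angle per sample is α = arccos(clamp((R(q)·x̂)·Ẑ)) in
degrees. Detection:

1. moving-average smoothing over `smooth_window_s` (default 0.1 s);
2. extrema via peak finding with prominence ≥ `min_prominence_deg`
   (default 5°) and same-kind spacing ≥ `min_interval_s` (default
   0.3 s); boundary samples are never events;
3. alternation enforcement: within a run of same-kind extrema only the
   most prominent survives, so minima (heel strikes) and maxima
   (toe-offs) strictly alternate;
4. localization refinement. The smoothed-peak index is biased wherever
   the waveform is asymmetric about the extremum (stance and swing have
   different durations). When the raw waveform is effectively noiseless
   at sample scale (robust residual estimate vs the smoothed waveform
   < 0.3°), the event snaps to the best raw local extremum within the
   smoothing window — exact for clean data; plateau ties resolve to the
   plateau center. Otherwise a quadratic vertex fit on the smoothed
   waveform over ± one window supplies the refined index, which is far
   less jitter-prone under angle noise than chasing raw extrema.
5. events falling inside dropout gaps are suppressed.

The defaults are engineering choices (the extremum definition itself
fixes only what an event is, not how to find it in noise) and are all
exposed as parameters.

## Strides and classification

A stride is (heel strike, toe-off, next ipsilateral heel strike).
Parameters: length = horizontal distance between the ipsilateral ankle
positions at the two heel strikes; time = elapsed time; velocity =
length/time (an exact identity by construction); stance percentage =
100·(toe-off − initial HS)/time; width = perpendicular horizontal
distance from the contralateral ankle position at its intervening heel
strike to the line joining the two ipsilateral heel-strike positions.
The width construction is a standard one, adopted because ankle
trackers admit no more direct definition. "Consecutive heel strikes"
is read as consecutive *ipsilateral* strikes, since all five parameters
are stride-level.

A stride is straight iff the absolute wrapped heading deviation between
its two heel strikes is strictly below the threshold (default 25°, the
midpoint of the accepted 20–30° range). Headings come from the
horizontal projection of the rotated x-axis at the heel-strike samples;
a vertical x-axis leaves the heading undefined and excludes the stride.
Threshold calibration formalizes "determined from straight-line
walking": strides whose heel strikes project onto a corner-free run of
the maze solution path (with a 0.10 m guard band, because projecting a
laterally offset tracker onto the path is only centimeter-accurate) are
calibration strides; the threshold is their maximum deviation + 5°,
clamped to [20°, 30°]; fewer than 5 calibration strides falls back to
25° with a warning. The navel, not the foot, is projected onto the
path: adjacent corridors are one block apart and a laterally offset
foot can project onto the wrong corridor.

Summaries use straight strides only (turning steps are counted but
excluded; their biomechanics are out of scope). CoV = sample SD (n−1) /
mean — the n−1 convention matters at per-session stride counts of
~10–20. Fewer than two straight strides flags the session insufficient.

## Balance

CoM position is the navel tracker's horizontal position; CoM velocity
is central finite differences smoothed by a zero-phase 4th-order
Butterworth low-pass at 6 Hz (defaults; the differentiation scheme is a
package choice). Leg length is the per-session median vertical
navel-minus-ankle separation — the median is robust to the ankle's
swing excursions. XCoM = u + u̇/ω₀ with ω₀ = √(g/l), g = 9.8 m/s²
(configurable).

The base of support at a heel strike is the minimal rectangle, aligned
with the step frame (AP axis from the cycle's initial to terminal heel
strike, ML axis perpendicular), containing both foot footprints —
nominal 0.25 × 0.10 m rectangles centered on the ankle trackers and
oriented by their headings, since trackers alone cannot bound the feet.
MoS_ml is the signed ML distance from the XCoM to the nearer ML border:
**positive = XCoM inside the ML extent (stable), negative = outside**.
This sign convention is fixed here and documented because no universal
convention exists. By default both feet form the BoS at every heel
strike (`single_foot_bos=True` switches to the leading foot only).

Per cycle, the direction of progression runs from the CoM at the
initial to the CoM at the terminal heel strike; CoM_ml is the maximum
absolute perpendicular deviation of the CoM from that line. Cycles with
near-zero CoM displacement (< 1 µm) are flagged and skipped. Session
balance summaries average straight-stride cycles only, consistent with
the stride-level exclusion.

## Synthetic walker

The walker lays alternating heel strikes along the maze solution path:
per-step lengths and durations are Gaussian draws at half the stride
mean/SD, lateral offsets alternate ± half the stride width about the
centerline. Steps crossing a path corner are turn steps: their duration
is multiplied by `turn_slowdown_factor`, they land just past the corner
(a pivot step), and the next step stops short of any further corner —
so no stride ever spans two corners. Without that rule, a stride
spanning an S-shaped double corner has zero net heading change (the
heading-deviation classifier cannot reject it, by definition) while
carrying a large lateral CoM excursion; real walkers shorten steps
through zigzags in just this way. The path is extended one stride past
the exit so terminal strides are not clipped at the boundary.

Ankle orientation encodes a raised-cosine shank-angle waveform: 90°
standing, dipping to 75° at each heel strike and peaking at 105° at
each toe-off, with a 0.3 s lead-in/out so the first and last heel
strikes are genuine local minima. Only the extremum locations matter
downstream; the arc shape is free. Ankle positions hold during stance
and follow a smoothstep swing with a sinusoidal 8 cm lift. The navel
advances by interpolating arclength through the step times and sways
laterally with a per-step cosine toward the stance foot. The profile's
`com_sway_amp` is defined as the ground-truth per-cycle CoM_ml (the
deviation of the opposite-side sway peak from the DoP line, which runs
through same-side heel-strike CoM positions); internally the
oscillation amplitude is therefore `com_sway_amp/2`. Near corners the
lateral-offset direction is blended over ±0.10 m so the CoM path stays
continuous.

Sensor imperfections: white Gaussian noise on positions
(`noise_sd_pos`, default 3 mm) and on the heading/shank angles
(`noise_sd_angle`, default 1°), and Poisson-distributed dropout events
(`dropout_rate` per minute, default 0) removing 0.2–0.6 s blocks from a
random stream.

Default profiles encode the qualitative condition contrast: under
walls, strides are shorter (0.92 vs 1.10 m), slower (stride time 1.22
vs 1.06 s), relatively more variable, narrower (0.095 vs 0.12 m), with
higher stance fraction (0.66 vs 0.62) and less sway (32 vs 45 mm).
The magnitudes are this package's choices of realistic older-adult
values; no quantitative per-parameter condition effects are published
in text form to pin them to.

What the simulator does **not** emulate: path-search behavior (getting
lost), soft-tissue artifact, foot-ground compliance, double-support
kinetics, spin steps, or drift/bias noise. Passing recovery tests
therefore demonstrates the pipeline's correctness on its stated
kinematic model, not robustness to everything real trackers do.

## Cohorts and studies

Cognitive scores and demographics are truncated normals with the study
population's means and SDs as parent parameters and instrument bounds
as truncation limits (e.g. Porteus Maze 0–17; for such tightly bounded
instruments the realized moments shift slightly from the parent
values). Sex is Bernoulli with the study's male fraction (16/65).

Planted gait–cognition effects enter through the data-generating
process: a slope β on (outcome, test) perturbs each subject's gait
profile linearly in (score − population mean) — stride length/time/
velocity/sway/stance map onto profile parameters; other outcomes are
shifted at the summary level. Effects may be condition-specific.

`simulate_study` gives every subject 2 conditions × 2 visits, the same
maze across visits within a condition and different mazes across
conditions. Subject-level random effects (SDs: 0.06 m length, 0.045 s
time, 7 mm sway, …) are shared across a subject's four sessions and
become the mixed model's random intercept. The delayed visit adds a
learning effect of +0.04 m stride length and −0.03 s stride time —
*additive and identical in both conditions*, so the default study has
an exactly null condition × visit interaction on stride length. A
condition × visit interaction can be planted explicitly (e.g. an
MoS_ml decrease confined to the no-wall delayed cell).

Two modes exist. `kinematic` simulates full 90 Hz sessions for the
pipeline to analyze. `summary` draws per-stride values from the
profile distributions and summarizes them exactly as the pipeline
would (mean, sample-SD CoV), with completion time modeled as pure
walking time times a condition/visit wandering multiplier with
lognormal noise; the multipliers were fixed once to reproduce published
completion-time group means (≈28/26 s no-wall, ≈64/50 s wall) as study
conditions. Monte-Carlo work (type-I error, power) uses summary mode —
at 100 replicates × 40 subjects × 4 sessions, full kinematics would
dominate runtime without adding validity, since the kinematic chain's
fidelity to the profile truth is established separately by the
zero-noise and default-noise recovery tests. Problem sizes used by the
validation suite: 10 sessions for recovery, 1000 null cohorts of
n=100 for type-I error, n=500 for slope recovery, 100 replicate
studies of n=40 for power and interaction patterns.

## Statistical stage

Outcomes are screened per analysis sample with Shapiro–Wilk at α=0.05;
non-normal, strictly positive samples are natural-log transformed
(base-e is a package choice); non-normal samples containing
non-positive values are left untransformed with a warning — no
shift-based transform is invented. Associations are one OLS per
(outcome, cognitive test) pair — matching report layouts that tabulate
one coefficient per test — adjusted for age, sex, education, height,
weight, complete-case, with a configurable minimum of 15 complete
cases; no correction is applied across table cells (each cell is
tested at α=0.05), mirroring the analysis this replicates; a
family-wise correction can be layered on by the caller.

The condition × visit model is `outcome ~ condition + visit +
condition:visit` with a subject random intercept, fitted by REML
(statsmodels MixedLM); fixed-effect p-values are Wald z-tests, which
for borderline p-values may differ from software using
Satterthwaite/Kenward-Roger denominator degrees of freedom. A
significant interaction (p < 0.05) triggers the four simple-effect
contrasts — visit within each condition, condition within each visit —
as Wald tests on linear combinations of the fixed effects with
Bonferroni ×4 (`p_adj = min(1, 4p)` exactly). Singular random-effect
fits are retried with a derivative-free optimizer and flagged
unconverged.

## Known limitations

- Event detection assumes a roughly periodic shank-angle waveform;
  shuffling, freezing, or backward steps violate the alternation model
  and are only partially handled by prominence/spacing gates.
- The BoS uses nominal foot dimensions; subject-specific foot size
  directly scales MoS_ml.
- The completion-time endpoints, MoS sign convention, stride-width
  construction, and ipsilateral reading of "consecutive heel strikes"
  are documented package conventions; comparisons across
  implementations must align them first.
- Summary-mode completion time models wandering as a lognormal
  multiplier, not as an explicit path-search process.
- Turn strides are detected and counted but never analyzed.
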