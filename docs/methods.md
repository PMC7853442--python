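# Methods

## Scope and data model

The package analyses 2-D floor positions of a small group (typically 11–13
individuals) in a bounded arena (default 1000 cm × 850 cm), digitized at a
coarse cadence (0.2 s) and interpolated to a uniform 0.05 s frame grid.
Everything downstream consumes a `TrajectorySet`: an `(N, T, 2)` position
array in centimetres plus per-frame velocities.

## Ingestion choices

**Calibration.** Overhead video introduces perspective distortion; a
projective (homography) transform fitted to four pixel/floor point
correspondences maps image coordinates to floor centimetres. The fit must
reproduce the four correspondences to 1e-6 cm and be invertible; collinear
triples are rejected.

**Resampling.** Raw samples are interpolated per individual with a cubic
spline evaluated on the 0.05 s grid. The default boundary condition is
not-a-knot: unlike natural end conditions it reproduces low-degree
polynomial motion (constant velocity, constant acceleration) exactly,
which is the behaviour a position interpolant should have near session
edges. Natural splines remain available via `bc_type=`. Individuals with
fewer than 4 valid samples cannot support a cubic and are excluded with a
logged warning; individuals missing more than 10% of samples are dropped
from the session (short gaps are bridged by the spline). The 10% rule is a
package choice — absences and occlusions occur in real recordings but no
standard gap rule exists for this kind of data.

**Velocity.** Backward difference, `v(t) = (c(t) - c(t-1)) / dt`, declared
in `VELOCITY_SCHEME`; the first frame has no velocity and is masked.
Central differencing is available as a config alternative. Backward
difference matches the convention that the velocity at time t describes the
motion arriving at the current position.

## Indices

* Pairwise distance: Euclidean, symmetric, all unordered pairs.
* Heading angle: `arccos` of the cosine between velocity and line of sight,
  with the argument clipped to [-1, 1] before conversion to degrees
  (floating-point guard). Frames with zero speed or coincident positions
  are masked invalid rather than given a value — both unit vectors are
  undefined there.
* Angular momentum: `m_i = |u_a x u_v|` about the *static* group centre,
  the time-mean over the session of the per-frame centroid. Masked when
  speed is zero or the individual sits exactly at the centre.
* Group angular momentum is reported as the per-frame mean of valid `m_i`.
  This is an interpretation (a group-level summary could also be defined
  from the centroid's own motion); the per-individual means are the primary
  quantity.

## Approach events and the approaching angle

Onset = first frame with distance < 50 cm where the previous frame was
>= 50 cm. No hysteresis or refractory rule is applied: successive crossings
are separate events, since no debouncing convention exists for this
threshold. Each crossing produces two directed candidates (i→j and j→i);
directionality then emerges per individual, because only frames where the
*approacher's* heading angle is defined and the pair distance lies in
[100, 200) cm contribute θ′ samples. Windows are half-open in seconds
before onset — "0–1 s" means frames in [t0 − 1 s, t0) — and the onset frame
itself is excluded. θ′ is sampled per frame (not summarized per event); the
directed-pair matrix is row-normalized by the approacher's total θ′ samples.
Both conventions are configurable, since no canonical convention exists for
this step (per-event summaries and other matrix normalizations are equally
defensible).

Children contributing zero θ′ samples are excluded from the θ′ histogram
comparison, which reduces the degrees of freedom for that index exactly as
observed in sparse sessions.

## Histograms and statistics

Bins are left-open/right-closed, labeled by their upper edge, with the
first bin closed below so 0° / 0 cm samples are counted. Families: 18 × 10°
for angles, 10 × 0.1 for momentum, 50 cm bins from 0 to 1350 cm for
distance (covering the arena diagonal of ~1312 cm; the extent is
configurable). Distance samples beyond the last edge — impossible in the
arena but possible in synthetic data — fall into an overflow bin that
participates in normalization but is never tested.

Per-child histograms are the unit of analysis: each child's bin counts are
divided by that child's total samples. For pairwise indices, child i's
sample set is `{value(i, j, t) : all j != i}`, so every unordered distance
sample appears in two children's histograms.

The per-bin test is a pooled-variance two-sample Student t
(`df = n_A + n_B − 2`), Bonferroni-corrected by the number of regular bins
in the family. Effect size is Hedges' g *without* the small-sample J
correction: `g = (mean_A − mean_B)/s_pooled`, which satisfies
`|g| = |t|·sqrt(1/n_A + 1/n_B)` exactly — this identity is what ties the
implementation to the published t/g pairs and is asserted for every emitted
comparison. Zero pooled variance yields t = 0 for equal means and a flagged
signed infinity otherwise. The sign convention puts class A (the younger
class) first, so negative t means the older class's frequency is higher.

## The synthetic generator

Agents are discrete-time kinematic particles (heading + speed) on the
0.05 s grid with specular wall reflection — the analysis consumes only
positions, so heading dynamics map directly onto the indices, and
reflection keeps agents in the hall without absorbing boundaries that would
distort the group centre.

Defaults emulate the recorded sessions: 11–13 agents, 40 s (sessions of
37–100 s were recorded), speeds drawn per agent from N(220, 40) cm/s —
a moderate running pace for five-to-six-year-olds; the true speed
distribution of running children is not established, so this is a config
parameter, not a claim.

**Rotation regime.** Agents orbit the hall centre on a loose ring
(preferred radius N(280, 25) cm) with a common sense of rotation, steering
each step along the ring tangent plus (a) a weak radial restoring pull,
(b) a midpoint-tangent correction (aim half a step ahead along the circle)
so the discrete chord stays tangential to second order, and (c) Gaussian
heading jitter (default 0.12 rad/step). Runners *follow* each other: an
agent within 120 cm of another agent ahead of it on the ring slows
proportionally, which is what keeps real rotating groups from running
through each other and keeps close (< 50 cm) passes rare, as in the
younger-class recordings.

**Tag regime.** One chaser relaxes its heading toward the line of sight to
its target (rate 0.5/step) at 1.2× base speed; the target flees when the
chaser is within 200 cm; on contact (< 50 cm) the tagged agent becomes the
chaser, a new target is drawn, and chasing pauses for a 1 s refractory so
the pair separates — without the pause a tag degenerates into a permanent
clinch, which is not how the game is played. Uninvolved agents wander with
heading noise.

**Mixed regime.** Each agent is independently a pursuit participant with
probability `p_social`; non-participants orbit. The random stream is
consumed in a fixed order regardless of the flags, so `p_social = 0` is
bit-identical to rotation and `p_social = 1` to tag at the same seed.

What the generator does *not* emulate: cognitive anticipation, music
phrasing, social preference structure between specific children, stopping/
standing bouts, or measurement noise of manual digitization. Passing tests
on synthetic data therefore demonstrates that the pipeline detects the
intended kinematic signatures (close contact, pursuit headings, broken
rotation) at realistic group sizes and durations — not that any particular
developmental claim holds in real classrooms.

## Problem sizes used in validation

Oracle-equivalence checks run 100 random 5-agent × 100-frame sets against
double-loop references at 1e-9. Parameter recovery uses 50 replicate pairs
of full-size sessions (rotation 11 agents vs tag 12 agents, 40 s),
requiring Bonferroni-significant differences in the hypothesized directions
in ≥ 80% of replicates. The null calibration runs 1000 replicates in the
test suite (400 by default in the acceptance script), each simulating one
pooled 23-agent, 20 s rotation session and splitting its children at random
into pseudo-classes of 11 and 12. The split-of-one-generator design makes
children exchangeable under the null, which is the assumption the per-child
t-test actually relies on; comparing two independently simulated sessions
would instead measure session-level clustering, a real phenomenon of
single-session-per-class designs but not a property of the testing
machinery. These sizes keep the complete validation under a few minutes on
one CPU.

## Known limitations

* With one session per class, children within a class share the group
  configuration; the per-child t-test does not model that clustering (this
  mirrors the original single-session design and is why the null
  calibration uses exchangeable splits).
* A class in which fewer than two children contribute θ′ samples (e.g. a
  pure-rotation group with no approach events) yields an empty
  approach-angle comparison table rather than a test.
* Approach directionality cannot distinguish one-sided from reciprocal or
  accidental approaches; positions alone do not carry intent.
* The arena is assumed rectangular and empty; obstacles and furniture are
  not modelled.
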