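# Methods

This note documents the models, parameters and numerical choices behind
`ethotrack`, what the synthetic data do and do not emulate, and the design
decisions taken where more than one reading was defensible. All lengths are
in cm, times in s, angles in rad, image intensities in 8-bit gray levels,
transfer entropy in bits.

## Arena and trial structure

The arena is a disc of diameter 42 cm partitioned into seven concentric
rings of 3-cm radial width. Rings are half-open, `[3k, 3k+3)` cm, with the
outermost ring closed at the wall; rings 0-4 form the central region
(0-15 cm radius) and rings 5-6 the external region (15-21 cm). A sample
exactly at r = 15 cm therefore counts as central — the half-open convention
is stated so occupancy tests can be bit-exact. The stated ring increments
are radial; seven 3-cm rings exactly span the 21-cm radius, which is the
only arithmetic-consistent reading of the layout.

Trials default to 3600 s at 20 frames/s (72,000 frames). The simulation
time step equals the frame interval (1/fps), so simulation and tracking
share one clock.

## Agent model

Mosquitofish follow a correlated random walk with shoaling terms; the
heading update combines persistence (weight 1.2), alignment with the group
mean heading (0.8), cohesion toward the group centroid (0.5), a zone of
repulsion below 2.5 cm (inverse-square push, weight 2.0), and white heading
noise (1.6 rad/√s). Speed follows an Ornstein-Uhlenbeck process around
6 cm/s (sd 2 cm/s, relaxation 1/s). Within 10 cm of the robot the fish are
repelled (weight 3.0) and cohere more strongly; both effects scale with
`fish_fear_gain`. Tadpoles are slower (2.5 cm/s) pure correlated random
walkers with heading noise 1.2 rad/√s and no social terms, reflecting their
short perception range. The wall is reflective: an agent stepping outside
the disc is mirrored back across the boundary and its radial heading
component flipped, so no position ever leaves the arena and no absorbing
state exists. These parameter values were chosen once to produce plausible
group statistics (fish AIID ≈ 4-5 cm, tadpoles dispersed over the arena)
and are not fitted to data.

### Directed coupling (ground truth for the information-flow stage)

The cross-species interaction is a modulation of heading-noise amplitude:
the responder's turning noise in one half-second window scales with the
driver group's mean *stochastic* heading activity (the erratic component,
excluding deterministic steering) from an earlier window,

    sigma_tad(window k) = sigma_0 · [1 + g · (a_fish(k - 2) - 1)],

clipped below at 0.2·sigma_0, where `a` is the window activity normalised
by its analytic baseline (mean |N(0, σ√dt)| = σ√(dt·2/π)) and
`g = tadpole_from_fish_gain` (symmetrically `fish_from_tadpole_gain` for
the reverse direction). Two deliberate choices make the induced information
flow clean at the half-second symbol scale:

- **One extra window of latency** (the responder reacts to the driver's
  activity from two windows back, a 0.5-1.0-s behavioural reaction time).
  Because the driver's stochastic window activities are independent across
  windows, the increase/no-increase symbol chain of an independent-window
  signal has conditional memory only at lag one; an echo delayed to lag two
  is conditionally silent. The responder's series therefore carries
  forward information (via the shared window between its echo and the
  driver's symbol) but adds no backward-predictive information, so
  `(g, 0)` yields a ground-truth coupling that is unidirectional *in the
  transfer-entropy sense*, not merely by construction of the forces. With
  a one-window latency the responder echoes the same window the driver's
  current symbol straddles, and a genuine (if ~20x smaller)
  reverse-direction flow appears — measurable and reproducible, which is
  why the latency is part of the model.
- **Noise-only activity** as the driver: deterministic steering
  (shoaling, fear) is autocorrelated across windows through the slowly
  changing group configuration; driving the responder with it would leak
  information across windows and reopen the reverse channel.

The default gains are `fish_fear_gain = 1`, `tadpole_from_fish_gain = 1`,
`fish_from_tadpole_gain = 0`: a unidirectional fish→tadpole interaction of
a strength that yields a forward transfer entropy of ~0.005 bits above the
estimator floor on 300-s trials — comfortably detectable by the permutation
test at 12 trials yet far from saturating. Zero gains give fully
independent groups, used for null calibration. A higher-order residual of
the mechanism remains: the fish's deterministic steering (autocorrelated
through the slowly changing shoal configuration) enters the *measured*
fish signal and carries a faint imprint of past noise, so on much longer
series (where the estimator floor keeps dropping) a weak reverse-direction
flow eventually becomes detectable; the recovery experiment is therefore
specified at the 300-s design point, where the ground truth is
unidirectional at detection scale.

## Robotic predator

The robot patrols a stored closed curve — a Lissajous figure (2:3, phase
π/2, so the two coordinates never reach their extremes simultaneously and
the curve has no cusp) scaled to stay inside the central region — resampled
to uniform arc length and traversed at 6 cm/s with linear interpolation
between samples. Attacks are scheduled, then executed by a five-phase
controller (`idle-patrol`, `orient`, `pursue`, `hold`, `return`):

- **Scheduling.** Trigger times are drawn uniformly inside consecutive
  bins whose period is the nominal interval (60 s at one attack per
  minute) plus a reserved busy time of 7.5 s — an upper bound on a
  complete attack (braking from patrol, a full-arena pursuit out and back,
  and the 1-s hold). This guarantees non-overlapping attacks, completion
  before the trial ends, and strictly fewer than 60 attacks per
  unstandardized hour. With `standardize_to = n`, n bins of width
  duration/n are used instead (error if infeasible).
- **Tiers.** At trigger time the target is the mosquitofish whose distance
  to its nearest tadpole is smallest (the fish currently most dangerous to
  the tadpole most at risk). The trigger distance fixes the tier: below
  1 cm the robot only turns toward the fish, holds 1 s, and restores its
  heading; from 1-10 cm (inspection) and beyond 10 cm (pursuit) it
  accelerates at 20 cm/s² (capped at 20 cm/s) toward the fish's position
  at trigger time — a feed-forward lunge, which bounds attack duration and
  matches a gantry executing a planned move — stops at the 1-cm standoff,
  holds 1 s, and returns to its pre-attack pose.
- **Kinematics.** The speed ramp is limited to ±20 cm/s² at every step and
  the position advances with the midpoint speed, under which the discrete
  braking ramp from v = √(2as) covers exactly s: each leg lands on its
  stop point with zero residual speed and the acceleration bound holds at
  every simulated step (an instantaneous stop would violate it at any
  finite time step). A 30-cm pursuit accelerates for exactly 1 s, cruises
  at exactly 20 cm/s and brakes to the standoff. The patrol speed itself
  ramps up and down within the same limit, decelerating along the curve
  before an attack so the robot re-enters patrol exactly where it left.

Attack log entries record trigger time, target, trigger distance, tier and
completion time; the tier stored is the one implied by the trigger
distance. A trigger arriving while an attack is in progress (possible only
if a pursuit overruns its budget) is deferred to the next idle frame.

## Rendering and tracking

Frames are 480×480 at 0.1 cm/px. Species are drawn as uniform disks with
distinct areas (fish 80 px², tadpole 40 px², robot 220 px²) and gray levels
(130, 210, 70 on a background of 10), plus additive Gaussian noise
(sd 3). `miss_rate` drops an agent from a frame with fixed probability.
The renderer returns the frame-by-frame blob ground truth for evaluation.

Thresholds are fitted once per trial from the first three frames: the
background level and spread are estimated robustly (median and 1.4826×MAD —
the blob pixels are far too few for Otsu on the full histogram), the lowest
threshold is set six noise deviations above background, and multi-Otsu on
the foreground pixels places the remaining levels between the blob
intensity modes. Detection then labels connected components above each
threshold from the highest level down, merging by centroid proximity
(3 px), so an animal standing out above a dimmer neighbour (the robot's
band lies below the fish's) separates cleanly even when silhouettes touch.
A component whose area and mean intensity fit no species whole, but fit
twice one species' area band, is split into two blobs along its
intensity-ellipse major axis — the touching-pair case. Components outside
every band are noise and are dropped; the robot is recognised by its own
intensity band, which is how its image is kept out of the animal analysis.

Assignment runs per species (labels fixed first) through the Hungarian
algorithm on Euclidean distance with a 5-cm gate — far above any plausible
per-frame displacement at 20 fps; matched pairs beyond the gate are
unmatched. Each track carries a constant-velocity Kalman filter
(white-acceleration process noise 200 cm²/s³, measurement variance
0.001 cm², calibrated once against the simulator so filtering tracks
maneuvers without over-smoothing); a frame without an assigned detection
appends the prediction, flagged `predicted`. When two same-species animals
fuse into a single blob, the unassigned track additionally receives a
high-variance ("merged measurement") update toward the fused centroid —
its sample stays flagged `predicted` because no detection was assigned.
Tracks are seeded on the first frames with the known group sizes (6+6+1,
closed population); a track first observed later is backfilled with its
first observation so all tracks share one time base. Identity swaps after
occlusions are not corrected retrospectively; all downstream measures are
group-level and swap-tolerant. Pixel coordinates (origin top-left, y down)
are converted to arena-centred cm (y up) only at the TrackSet boundary.

## Group measures

All metrics are computed frame-wise and then averaged over the trial (the
only reading under which a per-trial average is well defined for moving
animals), per species, with `predicted` samples included — a real-time
tracker has no way to exclude them. AFND averages each individual's
distance to its furthest group-mate; AIID averages all C(n,2) pairwise
distances; both need ≥ 2 individuals. Distance swam sums successive
displacements per individual. Turning rate uses the unsigned angle between
successive displacement vectors (headings are undefined at rest) divided by
the frame interval, skipping steps whose displacement falls below a 0.1-cm
motion floor so tracker noise at rest cannot masquerade as turning.
Occupancy counts samples per ring divided by fps. Fulton's condition
factor is K = weight[g] · length[mm]⁻³ · 10⁴.

## Symbolic transfer entropy

Group signals are sampled at 0.5-s ticks: the turning magnitude is the
within-window mean of the group's mean |turning angle|/frame-interval
(a rate, so it is averaged), while the central count is the number of the
species' individuals inside 15 cm at the tick instant (a state, so it is
sampled). A 60-min trial gives 7,200 signal values and 7,199 symbols.
Symbolization writes "+" for a strict increase between consecutive ticks
and "-" otherwise (ties are "-"). Transfer entropy uses single-step
histories on both sides, as in the defining equation; the joint mass of the
eight (T(t+1), T(t), M(t)) outcomes is estimated by relative frequency
(plug-in), zero-probability terms contribute nothing, and the result is a
conditional mutual information, hence ≥ 0 (clipped at 0 against rounding).

Significance: the observed statistic is the mean TE over trials with source
and target from the same trial (trials are pooled by mean, not by
concatenation, because the tested quantity is the mean). Each null draw
applies a uniformly random permutation to the source group identities
across trials and recomputes the mean; the identity assignment is excluded
(probability ~1/n! of being drawn anyway). The interaction is significant
when the observed mean exceeds the null's 95th percentile (one-sided
upper — the only direction in which "information transfer" is evidence).
Permutations over the full symmetric group make the null exchangeable with
the observed statistic; the measured false-positive rate on independent
series is 5.0% (800 runs), whereas restricting draws to
"donor-from-another-trial" schemes measured 6.5-9% and was therefore
rejected. Implementation note: TE is precomputed for all ordered
(source-trial, target-trial) pairs once, so each of the 20,000 default
permutations is a table lookup; cross-trial pairs of unequal length are
truncated to the shorter series. Series with fully missing ticks are not
accepted — symbolization is undefined on gaps (tracker output has none:
misses are filled by prediction).

## Problem sizes in the test suite

The suite runs the real study geometry throughout but scales simulation
lengths to what the checks need: a single full 60-min trial verifies the
7,000-point symbol contract; tracker accuracy uses a 300-frame rendered
clip (13 agents, noise on, no misses); coupling recovery uses 20 replicates
of 12 × 300-s trials with 2,000 permutations; null calibration uses 1,000
repetitions of 12 trials drawn from a pool of 400 pre-simulated 60-s
zero-coupling trials at 500 permutations (each repetition is an
exact-condition test; the pool only correlates repetitions slightly).
Because the significance rule is an exact-level 5% test, the
per-replicate probability that the reverse direction fires is ~5% even
under perfectly unidirectional ground truth; the recovery check
(≥ 18 of 20 joint successes) therefore carries an irreducible few-percent
failure probability by construction.

## Known limitations

- The agent model is a minimal correlated-random-walk/shoaling caricature:
  no hydrodynamics, no body posture, no learning or habituation across
  trials, and the fear response is a fixed repulsion rather than an
  adaptive strategy. Passing tests demonstrate that the pipeline recovers
  what this model encodes, not that real fish behave like the model.
- Rendered blobs are uniform disks; real animals are elongated, change
  apparent size with depth, and cast shadows. The tracker's
  area/intensity criteria would need re-fitting on real footage, and the
  touching-pair splitter assumes blob-scale convexity.
- The robot's live patrol trajectory is a stand-in curve satisfying the
  controller contract (the original is not published); the attack lunge is
  feed-forward to the trigger-time target position rather than closed-loop
  pursuit of a fleeing fish.
- The permutation test assumes trials are exchangeable units; systematic
  trial-order effects (e.g., habituation) would violate the null.
- Central-count signals from small groups are heavily tied (long runs of
  "-"), which lowers TE magnitudes for the space-use variable relative to
  the turning variable; the estimator remains valid but less sensitive.
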