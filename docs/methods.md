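# Methods

## Chart geometry

Charts are grids of digit characters (1–9) on a plane fixed 0.50 m in
front of the eyes, in a head-fixed frame: the chart follows head and body
movements, so head pose never enters the measurement and the plane origin
can sit at the chart center (x right, y up, meters). Every character
carries an axis-aligned square collider of side 0.04 m; adjacent colliders
are separated 0.06 m edge to edge, giving a 0.10 m center pitch. The
stored `scale_factor` (12) records the enlargement relative to the printed
booklet and is metadata only.

Grid shapes are configuration, not physics: the vertical reading is 20
rows × 4 columns (Test A in columns 1–2, Test B in columns 3–4, each read
top to bottom, column by column), the horizontal test 16 rows × 5 columns
read row by row, the pretest a single line of the digits 1–9. These shapes
reproduce the standard 40/40/80 character counts; the booklet's exact grid
is not published. Commercial digit sequences are proprietary, so default
charts draw digits uniformly from 1–9 under a seed, and explicit digit
lists can be supplied to reproduce a known chart.

One reading of "the distance between any two colliders is 0.06 m" had to
be fixed: it is taken edge to edge (center to center would leave 0.02 m
between collider edges and read oddly against the 0.04 m collider side).

## Gaze geometry and calibration

Streams begin at the gaze-ray level (a single cyclopean origin+direction
per sample); pupil imaging and binocular fusion are out of scope. The gaze
point is the crossing of the ray with the chart plane. Calibration is an
affine least-squares map (6 coefficients) fitted to point pairs; the
six-point protocol overdetermines the map, and the residual RMS reports
leftover tracker error. The functional form is a choice — the protocol
fixes only the number of points — and affine is the simplest family a
6-point redundant fit supports. Default calibration targets sit on a 3×2
grid spanning the chart extent, also a choice. Samples with non-finite
coordinates model tracker dropout (blinks) and count as "outside every
collider" downstream, which conservatively ends a running dwell.

## Event engine

Collisions are evaluated at sample times only, mirroring a 60 Hz tracker,
so all durations are quantized at the sample period (16.7 ms). Event
times take the first sample of the new state (enter-biased); consecutive
samples in different colliders emit exit-then-enter at the same timestamp.
Collider membership is boundary-inclusive.

Rest time = exit − enter for a visit; transfer time = next enter − exit.
The timers alternate and never overlap, so per subtest the measured
records telescope exactly: Σ(rest+transfer) = last enter − first enter.
Any collision — including with an already-visited character — closes the
running transfer and opens a rest, so records follow event order;
reconciliation with chart reading order is a separate step
(`align_log_to_chart`) that takes the longest strictly increasing
subsequence of visited ordinals as the best sequential reading, counting
unmatched chart characters as omissions and surplus records as additions.

The last-read character of each subtest gets a placeholder row (`-` in the
printed dialect) rather than a record: its rest ends the recording and it
has no successor. Hence 78 records for the vertical test (subtests A and
B of 40, two terminal rows at serials 40 and 80) and 79 for the horizontal
test. The vertical visit sequence splits at the first collision beyond
ordinal 40; gaze between the subtests belongs to no timer. A recording
normally ends while the gaze still rests on the final character, so its
unpaired enter is closed at the stream's last sample time and flagged
`incomplete`.

Measured time is not defined by a voice recording here, so the endpoint
rule is explicit and configurable: by default each subtest's clock runs
from its first collision to the end of its last character's observed dwell
(`first_entry_to_last_exit`); `stream_start_to_last_exit` instead starts
the first subtest at display onset. Every output embeds the conventions
used. Error counts o and a default to examiner-supplied values, with the
gaze-derived counts as a labeled opt-in substitute.

## Scanpath simulator

The simulator replaces the headset: it plans a fixation–saccade scanpath
over a chart and renders it to a sampled, noisy gaze stream, returning the
ground-truth schedule for parameter-recovery testing.

Parameters (defaults):

- `sample_rate` 60 Hz — tracker frame rate.
- `dwell_mean_v` 0.19 s, `dwell_mean_h` 0.12 s — mean per-character dwell
  for vertical/horizontal reading, matching the group-average rest times
  observed for the two chart orientations in VR administration.
- `dwell_shape` 8 — gamma shape; fixation durations are positive and
  right-skewed, and shape 8 gives a realistic ~35% coefficient of
  variation. `None` makes dwells deterministic (useful in tests).
- `saccade_intercept` 0.021 s, `saccade_slope` 0.0022 s/deg — the standard
  main-sequence linear amplitude–duration rule; amplitude is the true
  angular separation of the two characters as seen from the eye.
- `noise_sigma` 0.002 m — isotropic tracker noise on the plane, ≈0.25°
  RMS at 0.5 m, typical consumer-VR eye-tracker precision; one tenth of
  the collider half-side, so jitter cannot break a dwell.
- `p_omit`, `p_revisit` (0) — per-character reading-error rates. A revisit
  inserts one glance back at a uniformly chosen earlier character, so each
  event contributes exactly one "addition".

The planned dwell is defined as the **full in-collider time**. Rendering
honors that: during a fixation the gaze sits at the character center (plus
noise); between fixations it traverses only the out-of-collider portion of
the path, clipped 0.01 m (5σ of default noise) outside the source and
destination colliders, with a minimum-jerk speed profile. Enter/exit
events therefore coincide with the schedule's t_on/t_off up to sampling
quantization, which is what makes the schedule a usable ground truth:
mean measured rest recovers the configured dwell mean to within one
sample period, and each transfer equals its planned saccade duration to
within one sample period.

Saccade paths between grid-adjacent characters are straight. Return
sweeps and other long jumps are routed through the blank corridors
between collider rows/columns (an axis-aligned detour staying 0.03 m from
every collider center line): a straight 1.9 m return sweep would graze
colliders near its slow endpoints and register spurious collisions that
an attentive reader does not produce, breaking the fixed 78/79 record
counts of a complete reading. Real return sweeps are curved; the corridor
polyline is the simplest collision-faithful stand-in.

What the simulator does **not** emulate: digit-naming (voice onset)
latency, so simulated transfers are pure traversal times (~0.02–0.05 s)
rather than the 0.2–0.4 s search-plus-naming gaps of human readers;
within-fixation drift and microsaccades; blink episodes (dropout is
supported in the engine but not injected by default); head motion (the
chart frame is head-fixed); anisotropic or calibration-residual tracker
error. Passing tests therefore validate the *measurement machinery* —
geometry, event bookkeeping, conservation, error accounting — not the
human realism of absolute transfer magnitudes.

## Statistics

Paired comparisons use the paired *t*-test (two-sided, df = n−1);
identical pairs are the no-evidence case (t = 0, p = 1), while constant
non-zero differences have no finite statistic and raise. Pearson *r*
carries a two-sided p and an intensity label on the conventional
seven-level scale. Bin boundaries are closed on the side nearer zero and
open on the side nearer ±1 (so r = 0.3 is already "distinctly", r = 0.7
already "strongly"; ±1 included in the outermost bins) — a declared
convention, as the scale itself does not state boundary membership. A
Wilcoxon signed-rank alternative is available behind a flag for
non-normal data; it is an option, not the default.

## Numerical conventions

- Durations print to 2 decimals in the log-CSV dialect, but statistics
  must use the full-precision values kept in results JSON; the printed
  dialect loses ~5 ms per entry.
- Conservation and round-trip checks use 1e-9 s tolerances; duration
  quantization checks allow one sample period.
- All randomness flows through a single integer seed; the rendering noise
  stream is derived from the same seed via a fixed offset so planning and
  rendering draws are independent but jointly reproducible.

## Problem sizes

Test-suite simulations use full-size charts (80 characters, ~1100 samples
at 60 Hz, ~18 s of gaze data per run). Monte-Carlo suites use 100 runs
for engine/oracle equivalence, 200 runs for dwell recovery, 1000 plans
for dwell-distribution calibration and 10⁴ replicates for the paired-t
type-I-error check — sizes at which the binomial/standard-error bounds in
the tests are informative.

## Known limitations

- The fixed 78/79 record counts hold for complete sequential readings;
  real (or error-injected) readings produce fewer or more records, which
  the log reports via warnings and flags rather than force-filling.
- The longest-increasing-subsequence error accounting attributes
  ambiguous visit patterns (e.g. a skip followed by a backtrack) in a
  single canonical way; examiner counts remain the default for scoring.
- Calibration is affine; pincushion-like distortions of a real optical
  stack are outside its family and would surface in the residual RMS.
- The collider-based rest time is an analogue of, not a synonym for, a
  fixation duration: a slow drifting pass through a collider also counts
  as rest.
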