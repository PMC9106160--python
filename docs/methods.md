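# Methods

## Shank kinematics

The shank's sagittal orientation is the four-quadrant angle of the
distal→proximal tibia-marker vector projected onto the (forward, vertical)
plane, unwrapped along the series; a plain arctangent would be ambiguous
across quadrants.  Velocity is the central-difference derivative (one-sided
at the ends), filtered forward–backward with a Butterworth low-pass so the
passband is delayed by zero samples.  Defaults: cutoff 4 Hz, design order 4
(effective attenuation order 8).  The 4 Hz cutoff keeps the gait band —
stride fundamentals of 0.7–1.7 Hz and their first few harmonics — while
suppressing soft-tissue artifact, the dominant noise in 200 Hz optical
marker data.  Differentiation before filtering is equivalent to the reverse
order for these linear zero-phase operations (verified as a test property to
1% RMS on band-limited signals).

Internal units are radians and rad/s.  When `auto_orient` is on, the sign of
the velocity is chosen so midswing is a positive peak: the signal is negated
when the 0.1th percentile of the signal core exceeds the 99.9th percentile
in magnitude.  The quantile form, evaluated away from the trial edges, makes
the decision robust to the filter's edge transients, which on noisy trials
can exceed the midswing peak for a few samples.

## Event detection

Midswing (MS) candidates are positive local maxima of the filtered velocity.
The height criterion is relative — a candidate qualifies when its height is
at least `peak_frac` (default 0.5) of the median height of the *dominant
class*, the positive maxima reaching at least half the tallest peak.  Taking
the median over the dominant class rather than over all positive maxima
matters: any realistically filtered signal carries small positive stance
ripples, roughly one per cycle, and a median over everything collapses to the
ripple height, qualifying every ripple.  The dominant-class median keeps the
criterion scale-invariant (detection is unchanged under any positive scaling
of ω) while ignoring ripples.  Qualifying peaks closer together than
`min_cycle_s` (default 0.4 s ≙ max cadence 150 strides/min) are thinned,
keeping the taller.

For each MS peak, toe-off is the nearest negative-valued local minimum
before it (searched back to the previous MS) and heel strike the nearest
after it (up to the next MS).  A local minimum with ω ≥ 0 is not an event.
Boundary MS peaks missing a flank yield no event for that flank; a single
negative minimum shared between two MS peaks is assigned as heel strike of
the earlier cycle *and* toe-off of the later one, with a warning.  Ties on
plateau extrema resolve to the earliest sample.  MS/TO/HS times are reported
at sample resolution — the natural granularity of peak picking; only the
zero crossing is interpolated between its bracketing samples.

Reference events threshold the vertical GRF at `grf_threshold_n` (default
20 N, the common treadmill convention): upward crossing = heel strike,
downward = toe-off, crossing times interpolated between force samples,
contact/swing intervals shorter than `debounce_s` (50 ms) merged, and
alternation (HS, TO, HS, …) enforced.

## Temporal parameters

A complete gait cycle is a pair of consecutive same-side heel strikes with
exactly one toe-off strictly between them; leading/trailing half-cycles are
discarded, and HS pairs with zero or multiple TOs are rejected with a log
message.  Stride = HS→HS, stance = HS→TO, step = HS→first contralateral HS
in the half-open interval (hs_start, hs_end].  Swing is computed as
stride − stance rather than hs_end − to: the two are equal in exact
arithmetic, but only the former makes stance + swing = stride hold
bit-exactly in floating point, which downstream consistency checks rely on.
Events of different sources (kinematic vs force) are never mixed within one
cycle.

## Validation statistics

Signed timing error e = (t_reference − t_predicted)·1000 ms, so an early
prediction gives a positive error.  Matching is greedy one-to-one
nearest-neighbour within half the local reference stride (the local stride
around a reference event is half the span of its two neighbours); on
well-separated events this reproduces the optimal assignment, which a test
verifies against `linear_sum_assignment`.  Summaries report mean signed
error, mean absolute error and sample SD (n−1 denominator; unavailable for
n = 1).  Stride-normalised errors are 100·|e|/stride.  Bland–Altman
agreement uses differences method − reference: bias = mean difference,
RPC = 1.96·SD, limits of agreement = bias ± RPC, and CV = 100·SD over the
grand mean of the pairwise means (the CV convention is not standardised;
this definition is the one implemented and tested).

## The synthetic gait generator

The generator emulates bilateral treadmill gait of a unilateral amputee:
four tibia markers on rigid 0.4 m shank segments rotating about gently
oscillating ankle points, per-side vertical GRF, and force-defined truth
events.  Defaults describe moderate-speed amputee walking — cadence 55
strides/min, stance fractions 0.62 (sound) / 0.60 (prosthetic), midswing
peak 6 rad/s, marker noise 2 mm (i.i.d. Gaussian per coordinate, a
soft-tissue-artifact stand-in), markers at 200 Hz, force at 1000 Hz.  The
toe-off minimum leads true toe-off by 80 ms (sound) / 35 ms (prosthetic)
and the heel-strike minimum lags by 5 / 13 ms by default, so the default
conditions exercise the early-TO/late-HS asymmetry the dual-minima rule
shows on real amputee data.  These leads are configuration, not
biomechanical claims.

### Waveform construction

Per stride the designed velocity is a small positive baseline (0.07·amp)
plus three cosine-squared bumps — a negative dip at (TO − lead), the
midswing peak, a negative dip at (next HS + lag) — smoothed with a
zero-phase Butterworth low-pass whose cutoff is 3.8 cycles per stride
(≈3.5 Hz at the default cadence), making the waveform shape cadence-
invariant.  Because smoothing moves and rescales overlapping bumps, the
bump centres and amplitudes are solved by a quasi-Newton root find so the
*smoothed* waveform's three extrema sit exactly on the landmark times with
the configured values (MS = `ms_peak_amp`, dips = −0.55·amp); tighter
layouts fall back to gap-capped and shrunk bump widths, and a layout too
tight to resolve raises a configuration error.  The result has exactly one
dominant positive peak and two negative minima per cycle; the smoothed dip
shoulders supply the small stance-phase undulation.

A waveform with this morphology (±6 / −3.3 rad/s extrema 0.2–0.3 s apart)
necessarily carries energy in the 2.5–4.5 Hz band, which the detection
stage's 4 Hz zero-phase filter attenuates differentially, shifting dip
minima by ~4–5 ms outward.  To keep the ground truth meaningful through the
standard measurement chain, the marker angles integrate a *pre-compensated*
velocity: a damped fixed-point iteration solves
chain(ω_pre) = ω_designed, where the chain is trapezoid integration →
central difference → 4 Hz zero-phase filter.  The pre-compensation sharpens
the waveform by a few percent — analogous to raw versus filtered velocity
of real marker data — and is self-regularising (bands the chain suppresses
are left at designed amplitude, never amplified).  With it, the pipeline
recovers the designed landmarks to < 0.1 ms before sampling granularity.
The compensation targets the package's default measurement chain; detecting
with a different cutoff recovers that filter's view of the designed
waveform instead.

The GRF is a smoothstep-edged trapezoid per stance (ramp 80 ms), shifted so
the force crosses the 20 N threshold exactly at the true heel-strike and
toe-off instants, plus a trailing partial stance after the final heel
strike so the reference stream contains all n + 1 heel strikes.  All
randomness derives from a single seed; identical seeds give bit-identical
trials.

### What the simulator does and does not emulate

It reproduces the signal *structure* the detector assumes — one MS peak
flanked by negative minima per cycle, stance-phase force support, side
asymmetry, sensor-like marker noise — with exact, force-defined truth.  It
does not model pathological waveform variability (vaulting, circumduction,
intra-subject cycle-to-cycle morphology changes), correlated soft-tissue
artifact, marker occlusion, handrail use, or double-support force sharing
on a single belt.  Passing tests therefore demonstrate correctness of the
algorithmic chain under the stated morphology and noise, not clinical
accuracy on any real population.

## Numerical choices and degenerate inputs

Coincident markers raise a degenerate-geometry error; series shorter than
three samples cannot be differentiated; a cutoff at or above Nyquist is
rejected; filtering pads reflectively.  Marker gaps ≤ 10 samples are
linearly interpolated with a warning, longer gaps stay NaN and the
kinematics layer refuses them.  Empty event lists propagate as empty
results, not errors.  Bland–Altman needs at least two pairs.  Seeds below
2³¹ everywhere.

## Problem sizes

The default test and acceptance workloads use 4–20 cycles per trial and up
to 100 seeded trials per property — sizes at which every statistic the
package reports is stable to well under its assertion tolerance while the
full suite runs in seconds.
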