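# Methods

This note documents the models, conventions, parameter choices, and known
limitations of `placeseq`. Units: angles in radians wrapped to [0, 2π)
with the rest-box exit at 0 and the running direction positive; times in
seconds; rates in Hz; all intervals half-open `[start, end)`.

## Encoding model and decoder

Position tuning `f_i(x)` is estimated on a uniform circular partition of
90 bins (bin width 2π/90 ≈ 0.0698 rad — the nearest uniform partition to
the nominal 0.07-rad bin, which does not divide 2π; the effective width is
recorded in the rate-map object). Spike counts and occupancy are
restricted to samples moving faster than 5 cm/s, masked within half a
site spacing (0.0995 rad) of the rest box, smoothed separately with a
wrap-around Gaussian kernel (SD 0.14 rad), and divided; smoothing counts
and occupancy separately is robust in low-occupancy bins (smoothing the
raw ratio instead is available as a switch). Occupancy uses the same
kernel as counts. Bins with zero smoothed occupancy carry NaN rates and
are excluded from the decoding support.

Speed is the central difference of the unwrapped angle times the track
radius, one-sided at the ends. Unit selection excludes putative
fast-spiking interneurons (session mean rate > 5 Hz) and randomly
(seeded) downsamples goal-active units (peak rate > 0.5 Hz within half a
site spacing of the goal — the goal window is a package choice) to match
the count of units active elsewhere, so goal over-representation cannot
bias decoding.

The decoder assumes conditionally independent Poisson spiking given
position. It works in log space; rates are floored at ε = 0.01 Hz before
the logarithm (the floor handles silent units without changing argmax
behavior for active ones). The prior is flat and absorbed by row
normalization. Windows with zero spikes still yield a posterior (the
zero-count likelihood); sequence detection separately requires occupied
windows. Argmax ties break toward the lowest bin index. Cross-validation
decodes the pre-running laps with maps trained on everything after
pre-running; decoding error is the circular distance between the
maximum-likelihood bin center and the interpolated true angle.

## Circular-linear fits

The trajectory line `θ = a·t + φ₀` maximizes the weighted mean resultant
length `R(a) = |Σ w·e^{i(θ−a·t)}| / Σw` over a 101-point grid on the
slope range (±20 rad/s for run-period sequences, ±60 rad/s for replay,
±π per cycle for gamma fits), refined by bounded scalar minimization
within one grid step; `φ₀` is the argument of the resultant at the
optimum. Fit quality r² is the squared *weighted circular-linear
correlation* between the angles and the linear variable (the standard
estimator from the paired correlations of the linear variable with cosθ
and sinθ); note this measures the strength of circular-linear
association, is nonnegative by construction, and does not depend on the
fitted slope itself. Whether prior replay literature used exactly this r²
definition is not settled; the definition here is stated prominently for
that reason.

Candidates for sequence qualification are maximal runs of occupied
windows; a run failing any criterion is discarded whole (no sub-run
search). The x-span is computed from the fitted line (|slope| × t-span,
with t-span measured between the outer window edges, so the 6-window
minimum equals 90 ms), not from raw argmax endpoints. The relative
x-span divides by the circular distance from the animal's position at the
sequence midpoint to the stop location — one reasonable normalization
among several; it is a package definition, not an established one.
Sequences are analyzed only during the approach to the stop on
sample/test/post-test trials, never during pre-running.

## LFP conventions

Bands: theta 6–10, slow gamma 25–55, fast gamma 60–100, ripple
150–250 Hz. Filtering is a 4th-order Butterworth bandpass applied forward
and backward (zero net phase); envelope and phase come from the analytic
signal, with phase 0 at the oscillation peak and wrapped to [0, 2π).
Band power is the squared envelope z-scored over the movement mask
(≥5 cm/s outside the rest box) — the z-score is this package's choice of
normalization; min–max is available by config. The theta channel is the
eligible channel with the highest mean raw theta power over the mask,
ties broken by channel id. Theta cycles are cut at the center of the
minimum-count 30° phase bin of all run-period spikes.

## SWR and replay

Per channel, the smoothed (Gaussian SD 25 ms) ripple envelope is
z-scored over the rest mask; events are supra-5-SD stretches ≥50 ms,
widened to the first crossings of the mean, then merged across channels
by interval union (the multi-channel combination rule is a package
choice). Replay decoding reuses the 40/10-ms windows of run decoding;
finer bins can be configured. The end (start) location of an event is the
argmax of its last (first) occupied window's posterior snapped to the
nearest reward-site center.

### Termination/initiation bias null

Each event's terminal posterior row is aggregated to the site grid
(nearest-site assignment of each decoding bin) and the profile is summed
across events after rotating the goal to location 0. The null rotates
each event's profile by an independent uniform number of *site steps*
rather than by a continuous angle: on the site-aligned location grid this
makes the permutation distribution exactly exchangeable with
location-unbiased replay (a continuous rotation is not, because the 19
sites do not tile the circle — the arc at the rest box belongs to no
site window — and 90 decoding bins do not divide evenly into site
wedges), and it conserves each event's mass exactly. Significance is
upper-tail at the 97.5th percentile per location, uncorrected across
locations. No correction for multiple locations is applied.

## Synthetic sessions

The generator emulates the task: a 100-cm-diameter track with 19 sites
spaced 0.199 rad, the 10 sites farthest from the rest box eligible as
goals; sessions of 4–6 pre-running laps, 8 sample–test pairs (30-s
within-pair rests, ~1-min inter-trial rests), and 4–6 post-test trials.
Inter-stage rests default to 60 s to keep simulated sessions compact.
Sample trials stop at the (cued) goal; test/post-test trials stop at the
goal with probability `p_correct` (default 0.75) or at a neighboring
candidate site with one-site errors most likely, matching the dominance
of ±1 errors in this task; sample trials inherit their pair's test
outcome.

Trajectories integrate lap kinematics at 30 Hz: speed is drawn around
40 cm/s with AR(1)-smoothed noise (SD 4 cm/s, 0.5-s correlation time),
ramps down over the last 15 cm to the stop, dwells ~1.5 s, and completes
the lap; rest periods pin the angle at the rest box.

Run-period spiking is inhomogeneous Poisson with intensity

```
λ_i(t) = f_i(x(t)) · [(1−m) + m·vM(θ(t) − ψ_i(t); κ_φ)] · [1 + g·cos(θ(t) − π)] + baseline
```

where `f_i` is a von Mises place field (κ = 40, ≈30-cm fields, peak
15 Hz), θ(t) the theta phase (8 Hz), and ψ_i the preferred phase, which
*precesses* (moves earlier) at `precession_slope` k radians of phase per
radian of distance into the field (default 6.3 ≈ one theta cycle per
field traversal). The phase kernel is a mean-preserving mixture of an
unmodulated floor and a von Mises bump (κ_φ = 4, mixing weight m = 0.7):
a kernel this concentrated is required for 40-ms decoding windows (~2 rad
of theta phase) to resolve the within-cycle position sweep at all. The
population gate (depth 0.8, maximal at the mid-sweep phase) silences the
ensemble near the opposite phase; the resulting spike-free windows are
what segment continuous decoding into discrete cycle-scale sequence
candidates. The flat baseline (0.1 Hz) is suppressed five-fold when the
animal is still, reflecting the near-silence of CA1 pyramidal cells in
quiet rest outside SWRs (and keeping stray spikes from contaminating
replay clips).

Under this model the decoded within-cycle sweep speed is approximately
`v + 2π·f_θ/k`: a *smaller* precession slope produces *steeper* (more
compressed) decodable sequences. The steep/shallow condition pair used
for compression comparisons is k = 3 vs k = 12. Fitted slopes are
substantially diluted relative to the idealized sweep (window overlap,
posterior spread, and multi-cycle candidates all pull fits toward the
running speed), so the planted ordering — not the absolute sweep speed —
is the verifiable quantity.

Replay: ripples (200-Hz Hann-windowed packets, 80 ms, amplitude 8× the
channel's background ripple-band envelope SD) are planted in rest
windows; inside each, units fire in field-center order along a
constant-speed path (25 rad/s; reversed for reverse events) that ends at
the goal with probability `replay_end_bias` and otherwise at a uniformly
drawn site. The path dwells ~30 ms at its start and end sites with a
short spike-free margin adjacent to each dwell, so that the causal
decoding windows at the event edges represent the intended start/end
sites rather than a mixture lagged by half a window.

## What the generator does and does not emulate

It reproduces the statistical structure the pipeline's detectors consume:
unimodal circular tuning, phase precession with controllable compression,
theta-gated population firing, ripple-band transients, and ordered replay
with controllable goal bias. It does not model biophysics, spike
waveforms (sorting is upstream), learning dynamics within a session,
multi-field or directional cells, theta asymmetry/harmonics, realistic
1/f LFP backgrounds beyond a slow noise component, or inter-area
interactions. Passing tests therefore demonstrate the pipeline's
correctness and calibration on data with known structure — not that real
recordings satisfy the generator's assumptions.

## Numerical choices and degenerate inputs

Rate floor 0.01 Hz; posterior rows normalized by log-sum-exp; argmax ties
toward the lowest bin; empty decoding epochs yield valid empty matrices;
all-zero fit weights, zero total occupancy, empty rest masks, a zero
replay speed, and a goal at the track start are rejected with explicit
errors; degenerate MCC marginals yield NaN (flagged, never silently 0).
Bootstrap CIs are percentile (matching the common default; BCa is not
implemented) with n = 5000 resamples; the bias null uses 5,000 shuffles
in production and 1,000 in the test suite and acceptance script, which
changes only the percentile estimate's precision. Problem sizes in tests
(3–8 trial pairs per session, 2–3 sessions per condition, 20–40
calibration runs) were chosen so the full suite completes in a few
minutes on one CPU while leaving clear margins on every threshold.

## Known limitations

- The r² definition for replay quality follows the weighted
  circular-linear correlation; other definitions exist in the replay
  literature.
- The termination-bias null is site-granular (see above); with goals
  always at site centers this is the exchangeable choice, but it cannot
  detect sub-site biases.
- The Fig.-2-style regional posterior sums aggregate per lap by the
  per-window mean by default (a per-lap sum scales with lap duration;
  both are available) — the aggregation convention is a package choice.
- The continuous-mode detector discards a failing maximal run whole;
  sub-run search might recover more sequences.
- Statistical tests on real-data tables (ANOVAs, mixed models, circular
  two-factor tests) are out of scope: the pipeline emits the per-event
  tables those tests consume.
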