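# Methods

This note documents the models, rules and numerical choices behind
`gaitevents`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Preprocessing

Pipeline order is fixed: gap-filling → low-pass filtering →
differentiation → frame construction/decomposition.

* **Gap filling.** Interior occlusion runs strictly shorter than 0.5 s
  are cubic-spline interpolated per coordinate and re-validated; longer
  runs and leading/trailing runs stay invalid.  Downstream code operates
  per contiguous valid segment, so a long occlusion splits the analysis
  rather than contaminating it.
* **Filtering.** Zero-lag (forward–backward) 4th-order Butterworth,
  cutoff 7 Hz — above the frequency content of voluntary foot motion,
  below marker noise.  The effective magnitude response is the squared
  single-pass response, so the gain at the cutoff is 1/2 (asserted in
  tests).  Segments shorter than ~30 samples cannot be edge-padded and
  are left unfiltered with a warning.
* **Differentiation.** Central differences in segment interiors,
  one-sided at edges (exact for quadratics in the interior).  Repeated
  application yields acceleration and jerk.
* **Pelvis frame.** ML = unit(P1 − P0) (to the subject's right),
  AP = unit normal of the P0-P1-P3 plane, V = ML × AP.  The AP sign
  ("forward") is resolved by projecting the candidate normal on the
  smoothed pelvis-origin velocity, with a 0.05 m/s hysteresis so the
  sign is carried over from neighbouring moving frames rather than
  re-decided when the subject is nearly stationary; a fully stationary
  trial falls back to choosing the sign that makes V point away from the
  feet (cranially).  Frames with occluded or collinear cluster markers
  are invalid.
* **Decomposition.** Positions are expressed relative to the pelvis
  origin; velocity/acceleration/jerk components are the dot product of
  the *global* derivative with the instantaneous frame axis.
  Differentiating the decomposed scalar instead would add spurious
  frame-rotation terms during turns.
* **World vertical.** Estimated as the mean pelvis V axis; without a
  pelvis, as the least-variance direction of the heel trajectories with
  the sign chosen so the height distribution is bottom-heavy.  Step
  height is a world quantity, so step negotiation uses this vertical,
  not the (posture-tilted) pelvis V.
* **Quantiles** everywhere use linear interpolation between order
  statistics (the numpy default).

## Detectors

Threshold-crossing semantics are shared: an event fires at the first
sample satisfying the inequality after at least `min_event_separation`
(default 0.2 s — shorter than any physiological half-cycle) of
non-satisfaction; a run touching the start of a valid segment counts as
armed.  This debounces chatter near thresholds.  Peak-based detectors
use the same separation as a peak distance plus a prominence floor (1%
of the signal range for M1; 10% of the robust range for M8/M9).

Design points where the underlying method descriptions are silent:

* **M1/M2 horizontal-plane projection.**  The heel/toe position
  relative to the pelvis is projected on the horizontal plane before
  taking its AP component.  The progression direction is horizontal by
  definition, and this prevents cluster-axis wobble under marker noise
  from coupling the large (~0.9 m) vertical heel–pelvis offset into the
  AP signal, which otherwise creates spurious peaks during quiet
  standing.  For noise-free, level pelvis axes the two definitions
  coincide.
* **M2** high-passes the relative-AP signals at 0.5 Hz (config) and
  pairs heel/toe extrema within ±0.3 s, taking the earlier maximum (IC)
  and later minimum (FC) of each pair.
* **M3** rejects IC candidates whose mid-foot clearance exceeds
  1.3× the stance-phase baseline (10th percentile of clearance, floored
  at one marker height) — the height gate applies to ICs only — and
  both event types must reach 25% of the 95th-percentile vertical-speed
  amplitude ("timing constraints": contact-phase extrema are large,
  mid-swing ripples are not).
* **M5/M7 candidate grouping.** IC candidates are grouped by the swing
  interval they terminate, delimited by consecutive toe-speed upward
  crossings of the FC threshold.
* **M5/M7 FC refinement.** The heel-speed local peak sought within the
  100 ms window must clear a prominence of 5% of the heel-speed range;
  otherwise micrometre-scale plateau ripple would qualify as a "peak".
  The contact is the sample *after* the peak — the discrete analogue of
  the zero-acceleration instant at 10 ms resolution; the continuous
  zero crossing is not interpolated.
* **M8 "null jerk"** is operationalised as a jerk sign change across
  the acceleration peak (or |jerk| below 5% of the trial's jerk RMS):
  at a genuine smooth extremum the jerk crosses zero there.
* **M10 fusion.** Each M1 event takes the time and foot-strike label of
  the nearest unmatched same-side/same-type M7 event within 0.25 s
  (half the validation tolerance window; no fusion window is prescribed
  by the method family).  Unmatched M1 events are retained with an
  unknown strike (M1 is the base estimate); unmatched M7 events are
  discarded — M1's role is precisely to suppress such false positives —
  except inside pelvis-occlusion intervals, where M7 events pass
  through directly.  If no walking-speed estimate is available the
  refinement uses M5's fixed thresholds, with a warning.
* **Walking speed** is the mean stride speed over both sides, strides
  delimited by M5 ICs, displacement measured on the heel marker in the
  horizontal plane.

## Conditions, strides, bouts

* CW cores (|yaw rate| ≥ 15°/s) are widened until the rate falls below
  5°/s so the segment spans the whole manoeuvre, merged across gaps
  < 0.2 s, then accepted on net rotation ≥ 45°, duration 0.5–10 s
  (applied to the extended segment) and peak rate.  Yaw is the unwrapped
  horizontal heading of the AP axis; its rate is smoothed with the same
  7 Hz filter.
* SN uses a strict inequality (> 0.15 m) on the heel-height difference
  between consecutive same-side ICs, as a physical threshold; all
  events within the segment span are labeled SN.
* Label precedence is SN over CW (a step negotiated mid-turn is the
  rarer, more specific stratum); everything else is SW.  A stride is SN
  if either bounding IC is SN, else CW if either is CW, else SW.
* Stride length is the **horizontal-plane** heel displacement between
  bounding ICs (a config flag enables full-3D displacement), so step
  negotiation does not inflate length; the heel anchors length/speed
  because it also defines the IC.  Walking bouts are maximal stepping
  episodes with inter-IC gaps < 3 s containing ≥ 2 strides per side.

## Validation metrics

* **Matching** is greedy nearest-neighbour in reference-time order,
  one-to-one, inside ±TW/2 (TW = 0.5 s).  In the gait regime — events of
  one type spaced by more than TW — each detection is feasible for at
  most one reference and greedy matching is provably optimal; tests
  compare it against an exhaustive maximum-bipartite-matching oracle and
  document the adversarial dense configurations where greedy can
  sacrifice one pair.  Reference events rendered undetectable by marker
  occlusion can be excluded before matching.
* Timing errors are detected − reference (negative = anticipation).
  ME/IQRE/MAE estimate bias/precision/accuracy.  When more than 5% of
  the expected events of a method are missing, each FN is assigned the
  method's largest observed error (maximum magnitude, keeping its
  sign — the conservative reading of "highest error"); otherwise the
  mean observed error.  FPs never enter the error statistics.
* Stride errors are computed only for reference strides whose bounding
  ICs are both true positives matched to the ICs of one detected
  stride; the rest count as missing.  Resolution fractions report
  |error| within one sample period (temporal), 2 mm (spatial) and
  0.01 m/s (speed).
* **ICC(2,1)** (absolute agreement, two-way model, single measure) is
  computed from the ANOVA mean squares with the standard F-based 95%
  CI; an independent implementation (pingouin) serves as a 1e-10 oracle
  in the tests.  Bland–Altman coordinates are exported rather than
  plotted.
* Omnibus hypothesis tests (Friedman/Wilcoxon with Holm correction) are
  deliberately not reimplemented; the tidy per-event error tables feed
  any statistics package.

## Synthetic gait generator

The generator's defining assumption is **contact = stationarity**: a
foot on the ground has motionless markers, and ground truth is the exact
frame-aligned boundary of stationarity (IC = first stationary frame of
the striking marker, FC = last stationary frame of the toe).  All phase
boundaries are snapped to the sample grid before synthesis, so ground
truth is exact by construction and never perturbed by the noise or
occlusions applied afterwards.

Defaults describe comfortable adult gait: 100 Hz sampling, stride
length 1.32 m, stride duration 1.1 s (1.2 m/s), stance fraction 0.62,
heel-off at 45% and toe-down at 8% of the cycle, 0.20 m step width,
0.15 m heel–toe marker separation, 0.95 m pelvis height, 0.12 m heel
clearance and a two-hump toe-clearance profile (5 cm early, 4 cm late).
The corpus varies speed from 0.8 to 1.6 m/s by scaling length and
duration together.  Swing displacement follows a cosine-ramped velocity
profile with a 30 ms onset ramp and a 60 ms landing ramp: swing
initiation (push-off) is ballistic while terminal swing decelerates
under control, which reproduces the near-zero detection bias that
velocity-threshold methods show on real foot-marker data.  Footfalls
are placed by arc length along a centreline whose heading follows the
prescribed turns (raised-cosine yaw-rate), so straight-walk strides
have exactly the nominal length while turning strides become chords.
The pelvis centre is the one-stride moving average of the foot markers
(hence smooth gait initiation/termination) plus small AP/ML/V
oscillations (1.0/2.5/2.0 cm) at step/stride frequency; the rigid
cluster yaws with the heading.

What the simulator does **not** emulate: residual foot-marker motion
during real stance (micro-slippage, sole compression), soft-tissue
artifact, pelvis list/tilt dynamics, double-support force transfer, and
pathological coordination.  Impaired gait is approximated only through
slower speed, shorter strides, noise and occlusions.  Consequently,
passing the synthetic gates shows that the detectors implement their
rules exactly and are robust to measurement noise and occlusion — not
that they achieve any particular accuracy on clinical data.

One counting consequence of the stationarity model: a recording that
starts from quiet standing contains the first push-off of each foot, so
a trial with n strides per side carries n+1 ICs **and n+1 FCs** per
side (the initial toe-off has no enclosing stride but is a real,
detectable event; omitting it from the ground truth would wrongly count
every detector's correct detection of it as a false positive).

## Known limitations

* The M2 high-pass cutoff and the M3 height/amplitude constraints are
  config-exposed interpretations; the method family's sources do not
  state values.
* The greedy matcher can differ from the exhaustive optimum by one pair
  when events crowd inside one tolerance window (documented in tests);
  this cannot occur for same-type gait events at physiological rates.
* C3D support covers the mainstream subset (Intel byte order, float or
  scaled-integer point data, residual-based occlusion flags); analog
  channels, force platforms and EMG are ignored.
* With all pelvis markers absent, M1/M2/M4/M6/M8/M9 return empty sets
  with a warning; only the 3D-magnitude methods (M5/M7, and M10 via its
  fallback) and M3 remain available.
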