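# Methods

## Problem and scope

Stride-specific temporal gait parameters (stride, stance, swing time) are
delimited by two gait events per foot: initial contact (IC), when the foot
strikes the ground, and final contact (FC), when it leaves the ground.
This package detects both events from one 6-channel IMU worn anywhere on
the lower leg (left/right ankle or shank, arbitrary mounting orientation)
by sequence labeling with a temporal convolutional network (TCN), and
quantifies the result against marker-based reference annotations.  Only
straight-line, short-bout walking is modeled; spatial parameters (stride
length), turning, and real-time streaming are out of scope.

## Marker-based reference annotation

Heel and toe trajectories (200 Hz, meters) are processed per foot:

1. **Gap filling.** Missing samples (NaN) are restored by cubic-spline
   interpolation per coordinate.  Preconditions: ≤ 20% missing, no gap
   touching a trial boundary, no gap longer than 0.5 s (each violation
   raises a specific error).  Correlation-based reconstruction from other
   markers is deliberately not implemented.
2. **Filtering.** 6th-order Butterworth low-pass, 20 Hz cut-off, applied
   forward-backward (`scipy.signal.filtfilt`), which squares the magnitude
   response and cancels phase lag so event timing is not shifted.  Unit DC
   gain holds to 1e-9.
3. **Differentiation.** Central differences (one-sided at the ends);
   exact for polynomials up to degree 2.
4. **Event extraction.** IC at local minima of heel vertical velocity
   (the heel decelerates downward into contact), FC at local maxima of toe
   vertical velocity (the toe accelerates upward at push-off).  The
   assignment of event type to marker/extremum is configurable; this
   default follows the velocity-extremum annotation convention in the
   optical motion-capture literature.  Peaks must clear a prominence of
   10% of the velocity range and be separated by ≥ 0.3 s — explicit,
   configurable gates that stand in for the manual inspection step a
   laboratory workflow would use.  A flat (standing) trajectory yields no
   events, not an error.

The vertical axis is fixed as the third marker coordinate.

## Synthetic gait generator

The generator emulates the study conditions the pipeline assumes: cohorts
of healthy and neurological walkers (groups YA, OA, PD, MS, stroke, cLBP,
other, with sampling weights proportional to a 157-participant reference
cohort), each walking ~8 strides per trial at slow / preferred / fast
speed (cadence × 0.7 / 1.0 / 1.3), recorded at 200 Hz by heel/toe markers
and four lower-leg IMUs on one common clock.  Group profiles draw cadence
(e.g., YA 1.00 ± 0.07 strides/s, stroke 0.80 ± 0.08), stance fraction
(≈ 0.60–0.63), left-right asymmetry (up to 0.10 of a stride for stroke),
and a sensor-noise level (5–6% of per-channel signal SD).

The waveform model keeps ground truth in closed form:

* **Markers.** Vertical marker *velocities* are sums of well-separated
  Gaussian bumps; positions are their analytic integrals (Gaussian-CDF
  smooth steps), giving smooth periodic heel-lift/toe-lift curves that are
  non-negative.  The heel's downward-velocity peak is placed exactly at
  each IC and the toe's upward-velocity peak exactly at each FC, with all
  bump centers snapped to the sample grid.  Bump separations are ≥ ~5
  widths at every supported cadence, so neighboring bumps shift an
  extremum by far less than one sample: the velocity-extremum annotator
  recovers the generating schedule to the sample, which is asserted in
  tests (the generator/annotator loop closure).
* **IMU.** In the sensor's canonical frame, the medio-lateral angular
  velocity follows the canonical lower-leg template — a dominant positive
  mid-swing peak (250–320 deg/s) flanked by negative deflections at IC and
  FC — and the accelerometer carries gravity, a sharp narrow impact
  transient at IC (25 m/s², 20 ms width) and smoother braking/propulsion
  lobes.  IC and FC signatures differ in width and channel mix, so they
  remain separable from rotation-invariant structure.  Each stream is then
  rotated by an independent uniformly random 3-D rotation (the unknown
  mounting orientation) and white Gaussian noise is added per channel.
  Marker noise is a small proportional fraction of the subject's sensor
  noise level (0 for noise-free subjects).

Events per foot alternate IC, FC, …, IC by construction (n ICs, n−1 FCs);
the right foot is offset by half a stride plus the asymmetry fraction.
All randomness flows through explicit integer seeds; identical arguments
give bit-identical trials.

What the generator does **not** model: ground-reaction-force dynamics,
soft-tissue artifact, double-support micro-structure, turning, stops,
sensor drift/bias, or inter-stride waveform variability beyond additive
noise.  Passing the end-to-end tests therefore demonstrates that the
implementation is correct and that the architecture can learn
orientation-invariant event signatures — not that the trained weights
transfer to human recordings.

## Preprocessing

* **Normalization** is per trial and per channel (zero mean, unit SD);
  a constant channel raises an error.  Per-trial statistics are the only
  statistics available when a single deployment trial arrives alone, so
  they are used at training time too.
* **Targets.** y[n] = max over events e of exp(−(n−e)²/(2σ²)), σ = 5
  samples (25 ms), value exactly 1 at the event sample.  Widened targets
  keep MSE regression from collapsing onto the all-zero solution that
  near-empty binary impulse targets would invite; σ is configurable.
* **Windows.** Training/validation streams are cut into 400-sample
  windows with 50% overlap (hop 200); M = ⌊(N−window)/hop⌋ + 1.  Trailing
  samples beyond the last full window are dropped for training only —
  inference always consumes complete trials.  A too-short trial produces
  an empty set plus a warning.
* **Split.** Subject-level (never trial-level) random assignment to
  train/validation/test, stratified by group × gender with
  largest-remainder rounding per stratum; strata smaller than three
  subjects are assigned randomly with a warning.  Disjointness is asserted
  in tests (leakage guard).

## Network and training

Residual blocks with dilations 1, 2, 4 (reference configuration:
16 filters, kernel 5) of two [dilated conv → batch norm → ReLU → dropout]
sequences and an additive shortcut (1×1 conv for the 6→16 channel change,
identity elsewhere); two time-distributed single-unit sigmoid heads.  All
convolutions are centered "same" convolutions; the receptive field is
1 + 2·Σ_layers (k−1)/2·d = 57 samples (285 ms) for the reference
configuration, which tests confirm by perturbation probing of the built
network.  Parameter count of the reference configuration: 7314.

Training: mean of the two heads' per-sample MSE, Adam (lr 1e-3, β =
0.9/0.999), batch 32, early stopping on validation loss (patience 10 by
default), best-validation weights restored.  Dropout 0.1.  Weight init is
He fan-in, fully seeded.  Arithmetic is single precision by default;
double precision is available and used for the finite-difference gradient
check (worst relative error ~1e-7).  Bit-reproducibility across BLAS
builds is not promised; tests assert statistics and exact structural
properties (locality, determinism at fixed weights), not bit patterns.

Hyperparameter search: uniform random sampling from
{8, 16, 32, 64, 128} filters × {3, 5, 7} kernel × {[1,2], [1,2,4],
[1,2,4,8]} dilations, scored by validation loss; the winner is retrained
on train+validation by default (disable with a flag).

## Detection scoring

Likelihood traces are converted to events by keeping local maxima above a
threshold (default 0.3) greedily in descending height under a minimum
separation (default 0.25–0.3 s).  Reference and predicted events are
paired by an order-preserving dynamic program that first maximizes the
number of pairs with |t_ref − t_pred| ≤ tolerance and then minimizes the
summed |Δt|; the matching tolerance is a mandatory explicit parameter on
the CLI (0.25 s — half a typical step time — in the library pipeline), and
the DP is verified against an exhaustive matching oracle.  Time errors
follow the sign convention t_ref − t_pred.  Metrics: recall, precision,
F1 (reported raw and as half-up-rounded integer percent), median and IQR
of the time errors with linear-interpolation quantiles (stated because at
4-sample granularity the IQR is convention-sensitive).

Stride parameters are extracted per consecutive IC_i, FC_i, IC_{i+1}
triplet: stride = IC_{i+1} − IC_i, stance = FC_i − IC_i, swing =
IC_{i+1} − FC_i (so stance + swing = stride identically; swing defined
this way is the only reading consistent with that identity).  Only
"valid" trials — every event detected, no false positives, for both event
types — contribute strides; with a complete one-to-one matching the
reference and predicted stride sequences align by order.  Agreement is
Bland–Altman with the classical 1.96 multiplier and the sample (n−1) SD.

## Problem sizes and the end-to-end check

The package's own end-to-end validation simulates 60 subjects × 3 speeds,
splits subjects into thirds, trains the reference architecture for at most
30 epochs (patience 6) on windows from two sensor locations (left ankle +
right shank — both sides and both attachment sites, each stream plus one
extra randomly rotated copy), and evaluates complete trials of all four
locations on the held-out test subjects.  These sizes keep a full run in
the few-minutes range on one CPU while leaving hundreds of test events
per event type.  Under the default noise levels this run reaches recall
and precision ≥ 0.90 for both IC and FC at 0.25 s tolerance, median
|time error| ≤ 0.02 s, and stride-time limits of agreement within a few
milliseconds — the published human-data values themselves are not
re-derivable without the original recordings, so this property-based
surrogate stands in.

## Known limitations

* The published benchmark's exact pairing rule and matching tolerance are
  unreported, so its confusion counts are reproducible in structure (and
  its printed metrics recompute exactly from the counts) but not
  re-derivable from raw data.
* Batch-norm inference statistics come from training windows; a trial
  whose normalized distribution differs grossly from training would shift
  calibration of the likelihood traces.
* The peak-picking threshold is a free parameter; no calibration procedure
  (e.g., PR-curve selection on validation data) is built in.
* The synthetic generator's waveform realism bounds what the end-to-end
  result can claim about human data (see above).
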