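# gaitevents

Detection of gait events — initial contact (IC, heel strike) and final
contact (FC, toe off) — from a **single shank- or ankle-worn IMU**, using a
temporal convolutional network (TCN), together with the marker-based
reference annotation, evaluation metrics, and stride-parameter agreement
analysis needed to validate it.

The package targets movement scientists and digital-biomarker engineers who
want event-level gait timing (stride, stance, swing time) from one wearable
sensor, without knowing the sensor's exact placement or orientation, across
healthy and neurological gait (older adults, Parkinson's disease, multiple
sclerosis, stroke, chronic low back pain).

## The method

A trial is a matrix **X** ∈ ℝ^(N×D) of D = 6 channels (3-axis
accelerometer, 3-axis gyroscope, 200 Hz), standardized per channel.  Two
per-sample likelihood targets y_IC[n], y_FC[n] ∈ [0, 1] encode the events as
Gaussian bumps (σ = 5 samples = 25 ms).  The network is a stack of residual
blocks with exponentially increasing dilation d = 1, 2, 4; each block is
two sequences of dilated convolution → batch norm → ReLU → dropout with an
additive shortcut (1×1 convolution where the channel count changes).  All
convolutions are centered, zero-padded "same" convolutions, so

  ŷ_i[n] = f(…, x[n−1], x[n], x[n+1], …),  i ∈ {IC, FC},

the receptive field is 1 + 2·Σ (k−1)/2·d over all conv layers (57 samples
for kernel 5, dilations 1, 2, 4), and a complete trial of any length can be
fed at test time.  Two time-distributed single-unit sigmoid heads emit the
IC and FC traces; training minimizes the mean of the two heads' MSE with
Adam.  The whole network — forward, backward, Adam — is implemented on
NumPy arrays and verified against finite-difference gradients and an
input-perturbation receptive-field probe.

Reference events come from heel/toe marker trajectories: gap filling,
zero-phase 6th-order Butterworth low-pass at 20 Hz (applied
forward-backward), differentiation, then IC at local minima of heel
vertical velocity and FC at local maxima of toe vertical velocity.
Predicted peaks are matched one-to-one to reference events (order-preserving
minimal-|Δt| matching within a tolerance); recall = TP/(TP+FN), precision =
TP/(TP+FP), F1 = their harmonic mean; timing agreement is the median and
IQR of t_ref − t_pred; stride parameters are compared via Bland–Altman mean
difference and 95% limits of agreement (mean ± 1.96·SD).

Because the human recordings behind the published validation are not
redistributable, a synthetic-gait module generates cohorts of walking
trials (marker + 4 IMU streams + exact ground-truth events, with random
sensor orientations and configurable noise) on which the complete pipeline
is exercised end to end.

## Worked example

```python
import numpy as np
import gaitevents as ge

subject = ge.SubjectSpec(subject_id="S001", group="PD", gender="M",
                         cadence_hz=0.9, stance_fraction=0.62,
                         asymmetry=0.04, noise_sd=0.05)
trial = ge.simulate_trial(subject, speed="preferred", fs=200.0, seed=7)

ref = ge.detect_reference_events(trial.markers)   # marker-based annotation
left = ref["left"]
print("left-foot ICs (s):", np.round(left.ic_times, 3))

strides = ge.compute_stride_params(left)
print(f"mean stride {np.mean([s.stride_time_s for s in strides]):.3f} s, "
      f"stance {np.mean([s.stance_time_s for s in strides]):.3f} s, "
      f"swing {np.mean([s.swing_time_s for s in strides]):.3f} s")

# score a detector (here: the reference shifted 5 ms late) at 0.25 s tolerance
m = ge.match_events(left.ic_times, left.ic_times + 0.005, tolerance_s=0.25)
met = ge.detection_metrics(m)
print(f"TP={m.tp} FN={m.fn} FP={m.fp} -> recall {met.recall_pct}% "
      f"precision {met.precision_pct}% F1 {met.f1_pct}%")
med, iqr = ge.time_error_stats(m.time_errors)
print(f"median time error {med:+.3f} s, IQR {iqr:.3f} s")
```

prints

```
left-foot ICs (s): [0.665 1.78  2.895 4.    5.11  6.22  7.33  8.445]
mean stride 1.111 s, stance 0.686 s, swing 0.426 s
TP=8 FN=0 FP=0 -> recall 100% precision 100% F1 100%
median time error -0.005 s, IQR 0.000 s
```

The slow Parkinsonian walker strides every ≈1.11 s (cadence 0.9 strides/s);
all eight annotated heel strikes are matched, and a uniform 5 ms-late
detector shows up as a −0.005 s median time error (one sample period) with
zero spread.

The same pipeline is available from the shell:

```bash
gait simulate   --config cohort.yaml --outdir data/ --seed 1
gait annotate   --data-dir data/
gait preprocess --data-dir data/ --outdir prep/ --seed 1
gait train      --data-dir prep/ --outdir model/ --seed 1
gait evaluate   --checkpoint model/checkpoint.npz --data-dir data/ \
                --split-json prep/split.json --tolerance-s 0.25 --outdir eval/
```

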