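# Methods

This note documents the models, numerical choices, and deliberate gaps of the
`spf` toolkit: a software re-implementation of the sensing and gait-event
pipeline of a prosthetic foot instrumented with optoelectronic pressure
transducers (tactels) and a foot-mounted IMU.

## Tactel calibration

Each tactel maps an applied normal force to a photodiode voltage; pressing a
tactel drives the voltage negative. The bench characterization is a 4th-degree
polynomial

    F(v) = p1 v^4 + p2 v^3 + p3 v^2 + p4 v + p5   [N, v in V]

with defaults p = (186.1, 224.5, 64.76, −18.59, 0). Evaluation uses Horner's
nested form. Because `p4 < 0`, the raw polynomial is slightly negative for
small positive voltages; per-tactel forces are clamped to ≥ 0 N, since
physical contact forces are nonnegative.

The polynomial is inverted on its *negative branch* `[-2, 0]` V, on which it
is strictly monotone (checked numerically at configuration time; the image is
0 to ≈ 1478 N, ample for a ≤ 90 kg wearer). The scalar inverse uses Brent's
bracketing root-finder (|F(v*) − f| well below 1e−6 N); the vectorized inverse
used by the simulator interpolates a 4097-point grid and polishes with two
Newton steps, giving ≈ 1e−9 V accuracy. The tactels' true operating voltage
span is not published; the branch interval is a declared assumption of this
package and is configurable.

## vGRF and CoPy

With per-tactel voltages `V_i`, coordinates `y_i` (cm from the heel) and CoP
weights `w_i`:

    vGRF = Σ_i F(V_i) · [V_i ≤ VT]                    (gated sum, N)
    CoPy = Σ_i F_i w_i y_i / Σ_i F_i w_i   if vGRF ≥ vGRFT, else NaN (cm)

* `VT` (default −0.05 V) gates out zero-mean noise on unloaded channels. Its
  experimental value is unpublished; the default rejects > 5σ of the default
  0.01 V sensor noise.
* `vGRFT` (default 15 N) is the minimum load for the foot to count as in
  contact; the plausible tuning range is 10–20 N.
* The CoPy validity condition is implemented as *defined while loaded*
  (vGRF ≥ vGRFT). The opposite orientation appears in print but contradicts
  both the physics and the threshold detector; we treat it as typographical.
* `w_i` defaults to 1 for every tactel: `y_i` already carries the lever arm,
  and CoPy is invariant to a global positive rescaling of the weights (a
  tested property). Distinct weights remain available in the layout file.
* Per-tactel coordinates are not individually published, only the 0–22.8 cm
  span and the 5-heel/11-forefoot split. The bundled default layout places the
  5 heel tactels uniformly on [0, 6] cm and the 11 forefoot tactels uniformly
  on [12, 22.8] cm; it lives in `spf/data/default_config.json`, not in code.

## Gait-event detectors

**Pressure (PS) detector.** Stance ⇔ vGRF ≥ vGRFT; heel strike (HS) is
stamped on the first stance sample of each swing→stance transition, toe off
(TO) on the first swing sample. Comparisons are inclusive and crossings are
assigned to whole samples (no sub-sample interpolation) since errors are
reported at 10 ms resolution. The phase already in progress at the first
sample emits no event. The two cascaded thresholds (VT, vGRFT) necessarily
detect HS late and TO early relative to true contact/lift-off, so stance
duration is underestimated — a tested invariant.

**IMU finite-state machine.** Inputs: accelerations ax, ay, az (raw, gravity
included) and sagittal angular velocity ωx (deg/s, positive during the swing
rotation). Phases: `WAIT_MSW → SEARCH_HS → IDLE → SEARCH_TO → WAIT_MSW`, with
a timeout edge `SEARCH_HS → WAIT_MSW`.

1. Mid-swing (MSw): confirmed local maximum of ωx ≥ 75 deg/s.
2. HS: confirmed local maximum of az such that within the 30 ms window before
   the peak (window samples in `(t_peak − 0.030, t_peak]`; 3–4 samples at
   100 Hz) at least one acceleration channel spans a peak-to-peak range
   > 7 m/s². If no HS within 0.75 s of MSw, re-arm.
3. After HS, idle 0.4 s (timer starts at the HS *timestamp*, not its
   confirmation time, reproducing the offline-equivalent behavior).
4. TO: confirmed local minimum of ωx ≤ −65 deg/s; back to `WAIT_MSW`.

"Local extremum" is made streaming-safe by a confirmation lag (default 30 ms,
i.e. 3 samples at 100 Hz): sample *i* is a confirmed maximum once strictly
greater than its `lag` predecessors and at least as great as its `lag`
successors (plateaus resolve to their first sample). The event keeps timestamp
`t[i]`; it becomes known at `t[i+lag]`, keeping detection latency far below
the 0.100 s budget. Rates that place fewer than one sample in the 30 ms
window are rejected. By construction the FSM emits strictly alternating
HS/TO with at most one HS per mid-swing.

**Force-plate reference.** The same threshold rule applied to plate fz with
the threshold fixed at 20 N — the reference detectors are benchmarked against.

## Synthetic gait generator

The generator produces the study conditions used throughout the tests: stride
period 1.6 s, duty factor 0.62 (stance 0.992 s), body mass 70 kg, 100 Hz
sensor channels, 200 Hz force plate, and per-channel Gaussian noise (voltage
0.01 V; accelerometer 0.2 m/s²; gyro 2 deg/s; plate 1 N — typical MEMS/plate
noise floors; the source study publishes no noise model). One integer seed
drives a single `numpy` generator, so trials are bitwise reproducible.

* **vGRF**: two raised-cosine lobes (centers 0.3/0.7 of stance, half-width
  0.3), zero at contact and lift-off, peak 10.4 N/kg × mass — the typical
  force-plate peak for level walking. The quadratic onset means the 20 N
  reference crossing trails true contact by ≈ 30 ms, and the 15 N PS crossing
  by slightly less; these offsets, not added noise, dominate the benchmark
  errors.
* **CoP**: smoothstep ramp from 1 cm (heel region) to 22 cm (forefoot) over
  stance — monotone, emulating the heel→toe progression.
* **Tactel loading**: the instantaneous total force is spread with a Gaussian
  kernel (σ = 2 cm, truncated at 3σ) centered on the target CoP, then the
  kernel weights are tilted linearly (1-D root-find) so the layout-weighted
  centroid equals the target to 1e−6 cm with nonnegative forces summing
  exactly to the total. One-sided kernel support (near the span edges and in
  the heel/forefoot gap) falls back to an exact two-tactel split. Voltages
  follow from the calibration inverse on the negative branch. Tactels loaded
  below ≈ 1 N emit voltages above VT and are gated off — reproducing the
  threshold-cascade timing bias of the real device.
* **IMU**: ωx carries one +150 deg/s raised-cosine peak per swing (centered
  at mid-swing, half-width 0.15 s) and one −120 deg/s trough centered at each
  true TO (half-width 0.10 s); az carries gravity (9.81 m/s²) plus a decaying
  25 Hz oscillation (amplitude 12 m/s², τ = 30 ms) starting at each true HS,
  whose first peak lands 10 ms after contact with a pre-peak excursion ≈ 8.6
  m/s² > the 7 m/s² threshold.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: tactel viscoelasticity, hysteresis and shear
sensitivity; the strong vGRF amplitude underestimation of a partially
sensorized sole (the simulator feeds the full load through the tactels, so
simulated PS peaks match the plate instead of reading ≈ 8× low); soft-tissue
and footwear dynamics; inter-subject variability beyond parameter presets;
broken channels (no dead-channel mask). One visible consequence: the
simulated IMU flags HS ≈ 20 ms *before* the 20 N plate reference, whereas the
human cohort showed it late — the sub-0.100 s error budget holds either way,
but the sign of the IMU HS bias is not a prediction of this simulator.

## Benchmarking

Reference events come from the plate at 20 N. Detected events are paired
one-to-one per event type with the nearest reference event within half the
reference stride period, solved as a rectangular assignment minimizing total
absolute error among maximal pairings (so no detection is claimed twice);
unmatched events are counted as misses / false alarms. Signed error =
detected − reference. Per trial: MAE = median |error|, IQR = Q3 − Q1 of
|error| (linear-interpolation quantiles — no convention is published, this is
the common default), late fraction, MAE as % of stride, and stance-duration
error on fully matched strides. Grouping takes the median across trials of
the per-trial medians, each simulated trial standing in for one subject.

Waveform agreement: tactel voltages are low-pass filtered (2nd-order
Butterworth, 25 Hz cutoff, applied forward–backward for zero phase — an
offline analysis; the causal detectors never see this filter), vGRF/CoPy are
recomputed, each reference stance is linearly resampled onto 1000 points, and
Pearson r (vGRF, CoPy) plus RMSE (CoPy) and the body-mass-normalized vGRF
peak are computed per stride and summarized by medians. CoPy samples outside
the validity window (NaN) are dropped before interpolation, with edge
clamping. Cohort-level Friedman/Lilliefors testing of shoes-vs-no-shoes
conditions is a human-cohort analysis and is out of scope here.

## Problem sizes

The default evaluation cohort is 10 trials × 20 strides (200 strides,
≈ 33.6 s of signal per trial), which the package simulates and scores in a
few seconds; unit-test fixtures use 3–5 strides. These sizes were chosen so
grouped medians are stable at the 10 ms error resolution of interest.

## Known limitations

* Only the longitudinal CoP coordinate is modeled (no medio-lateral CoP).
* No sensor fusion of the two detectors; they are evaluated independently.
* The simulator is a signal-morphology emulator, not a biomechanical model;
  absolute agreement statistics on it (e.g. CoPy RMSE ≈ 0.04 cm) reflect its
  internal consistency, not field performance.
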