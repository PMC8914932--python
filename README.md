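# spf — sensorized prosthetic foot toolkit

`spf` re-implements the sensory-processing stack of a prosthetic foot
instrumented with a matrix of optoelectronic pressure transducers ("tactels")
and a foot-mounted IMU, for people working on gait-event detection and
control of lower-limb prostheses:

* **Calibration** — each tactel's voltage→force map is a 4th-degree
  polynomial `F(v) = p1 v⁴ + p2 v³ + p3 v² + p4 v + p5` (pressed tactels read
  negative voltages), invertible on its monotone negative branch.
* **Biomechanical estimates** — the vertical ground reaction force
  `vGRF = Σᵢ F(Vᵢ)·[Vᵢ ≤ VT]` (the gate `VT` suppresses noise on unloaded
  channels) and the longitudinal center of pressure
  `CoPy = Σ Fᵢwᵢyᵢ / Σ Fᵢwᵢ`, defined while the foot is loaded
  (`vGRF ≥ vGRFT`), over a 16-tactel sole (5 heel + 11 forefoot, 0–22.8 cm).
* **Two independent gait-event detectors** for heel strike (HS) and toe off
  (TO): a pressure-threshold rule (stance ⇔ `vGRF ≥ vGRFT`, `vGRFT` tuned in
  10–20 N) and a causal IMU finite-state machine (mid-swing gyro peak
  ≥ 75 deg/s arms an HS search; HS = az peak with a > 7 m/s² excursion in the
  preceding 30 ms, within 0.75 s; 0.4 s idle; TO = gyro trough ≤ −65 deg/s).
* **A synthetic gait simulator** producing tactel voltages, IMU channels and
  force-plate data with known ground-truth events (double-bump stance vGRF,
  monotone heel→toe CoP, mid-swing/pre-toe-off gyro features, heel-strike
  impact bursts, seeded Gaussian noise).
* **A benchmarking procedure**: events are scored against the 20 N
  force-plate reference by the median absolute error (MAE) and IQR of the
  timing errors, grouped as median-of-trial-medians; waveforms are compared
  after zero-phase 25 Hz Butterworth filtering and 1000-sample stance
  normalization via Pearson r and RMSE.

See `docs/methods.md` for the full model description and numerical choices.

## Worked example

Simulate one 20-stride trial, run both detectors, and benchmark them against
the force-plate reference:

```python
import spf

trial = spf.simulate_trial(spf.GaitProfileParams(n_strides=20, seed=1))
report = spf.evaluate_trial(trial)
for det in ("PS", "IMU"):
    for kind in ("HS", "TO"):
        s = report["detectors"][det][kind]
        print(f"{det:3s} {kind}: MAE {s['mae_s']*1000:.0f} ms "
              f"(IQR {s['iqr_s']*1000:.0f} ms, {s['mae_pct_stride']:.2f}% of "
              f"stride, late {100*s['pct_late']:.0f}%)")
print(f"CoPy: r = {report['copy']['pearson_r']:.3f}, "
      f"RMSE = {report['copy']['rmse_cm']:.2f} cm")
```

prints

```
PS  HS: MAE 5 ms (IQR 0 ms, 0.31% of stride, late 0%)
PS  TO: MAE 8 ms (IQR 5 ms, 0.47% of stride, late 100%)
IMU HS: MAE 25 ms (IQR 0 ms, 1.56% of stride, late 0%)
IMU TO: MAE 30 ms (IQR 5 ms, 1.87% of stride, late 100%)
CoPy: r = 1.000, RMSE = 0.04 cm
```

Every error is far below the 0.100 s budget required for prosthesis control.
The PS errors come from the cascaded `VT`/`vGRFT` thresholds (HS detected
after true contact, TO before true lift-off, so stance duration is
underestimated); the IMU errors reflect the offset between the impact/trough
features and the 20 N reference crossings. The near-perfect CoPy agreement is
against the simulator's own force-plate CoP and demonstrates pipeline
consistency, not field accuracy.

The same workflow is available from the shell:

```sh
spf simulate --out trial1 --seed 1 --n-strides 20
spf segment --detector imu --trial trial1 --out imu_events.csv
spf benchmark --trial trial1 --out report.json
```

All file formats are plain CSV/JSON (documented in `spf/io.py`); a single
JSON config (see `src/spf/data/default_config.json`) governs calibration
coefficients, tactel layout, thresholds, and simulator parameters.

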