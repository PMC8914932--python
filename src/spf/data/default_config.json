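{
  "schema_version": 1,
  "calibration": {
    "p1": 186.1,
    "p2": 224.5,
    "p3": 64.76,
    "p4": -18.59,
    "p5": 0.0,
    "branch_v": [-2.0, 0.0]
  },
  "layout": {
    "y_cm": [0.0, 1.5, 3.0, 4.5, 6.0,
             12.0, 13.08, 14.16, 15.24, 16.32, 17.4, 18.48, 19.56, 20.64, 21.72, 22.8],
    "region": ["heel", "heel", "heel", "heel", "heel",
               "forefoot", "forefoot", "forefoot", "forefoot", "forefoot", "forefoot",
               "forefoot", "forefoot", "forefoot", "forefoot", "forefoot"],
    "weights": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
  },
  "thresholds": {
    "voltage_gate_v": -0.05,
    "vgrf_min_n": 15.0
  },
  "imu": {
    "midswing_gyro_min_dps": 75.0,
    "toeoff_gyro_max_dps": -65.0,
    "accel_pp_min_ms2": 7.0,
    "hs_search_window_s": 0.75,
    "idle_after_hs_s": 0.4,
    "pre_peak_window_s": 0.03,
    "confirm_lag_s": 0.03
  },
  "simulator": {
    "stride_period_s": 1.6,
    "duty_factor": 0.62,
    "body_mass_kg": 70.0,
    "n_strides": 20,
    "fs_sensors_hz": 100.0,
    "fs_forceplate_hz": 200.0,
    "noise_sd_voltage_v": 0.01,
    "noise_sd_accel_ms2": 0.2,
    "noise_sd_gyro_dps": 2.0,
    "noise_sd_force_n": 1.0,
    "seed": 0
  }
}
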