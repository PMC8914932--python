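"""Typed configuration: one JSON document governs calibration, layout,
thresholds, and simulator parameters. CLI flags override individual fields."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, Field

from .segmentation import ImuThresholds
from .sensing import (CalibrationPolynomial, SensingThresholds, TactelLayout,
                      _default_config)
from .synthetic import GaitProfileParams


class CalibrationConfig(BaseModel):
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    branch_v: tuple[float, float] = (-2.0, 0.0)

    def build(self) -> CalibrationPolynomial:
        return CalibrationPolynomial(self.p1, self.p2, self.p3, self.p4,
                                     self.p5, tuple(self.branch_v))


class LayoutConfig(BaseModel):
    y_cm: list[float]
    region: list[str]
    weights: list[float]

    def build(self) -> TactelLayout:
        return TactelLayout(self.y_cm, tuple(self.region), self.weights)


class ThresholdConfig(BaseModel):
    voltage_gate_v: float = -0.05
    vgrf_min_n: float = 15.0

    def build(self) -> SensingThresholds:
        return SensingThresholds(self.voltage_gate_v, self.vgrf_min_n)


class ImuConfig(BaseModel):
    midswing_gyro_min_dps: float = 75.0
    toeoff_gyro_max_dps: float = -65.0
    accel_pp_min_ms2: float = 7.0
    hs_search_window_s: float = 0.75
    idle_after_hs_s: float = 0.4
    pre_peak_window_s: float = 0.03
    confirm_lag_s: float = 0.03

    def build(self) -> ImuThresholds:
        return ImuThresholds(self.midswing_gyro_min_dps, self.toeoff_gyro_max_dps,
                             self.accel_pp_min_ms2, self.hs_search_window_s,
                             self.idle_after_hs_s, self.pre_peak_window_s,
                             self.confirm_lag_s)


class SimulatorConfig(BaseModel):
    stride_period_s: float = 1.6
    duty_factor: float = 0.62
    body_mass_kg: float = 70.0
    n_strides: int = 20
    fs_sensors_hz: float = 100.0
    fs_forceplate_hz: float = 200.0
    noise_sd_voltage_v: float = 0.01
    noise_sd_accel_ms2: float = 0.2
    noise_sd_gyro_dps: float = 2.0
    noise_sd_force_n: float = 1.0
    seed: int = 0

    def build(self, seed: int | None = None) -> GaitProfileParams:
        return GaitProfileParams(
            stride_period=self.stride_period_s, duty_factor=self.duty_factor,
            body_mass=self.body_mass_kg, n_strides=self.n_strides,
            fs_sensors=self.fs_sensors_hz, fs_forceplate=self.fs_forceplate_hz,
            noise_sd_voltage=self.noise_sd_voltage_v,
            noise_sd_accel=self.noise_sd_accel_ms2,
            noise_sd_gyro=self.noise_sd_gyro_dps,
            noise_sd_force=self.noise_sd_force_n,
            seed=self.seed if seed is None else seed)


class SpfConfig(BaseModel):
    """Root configuration document (see ``spf/data/default_config.json``)."""

    schema_version: int = 1
    calibration: CalibrationConfig
    layout: LayoutConfig
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    imu: ImuConfig = Field(default_factory=ImuConfig)
    simulator: SimulatorConfig = Field(default_factory=SimulatorConfig)

    def sha256(self) -> str:
        """Stable content hash used for reproducibility logging."""
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def default_config() -> SpfConfig:
    return SpfConfig.model_validate(_default_config())


def load_config(path: str | Path | None) -> SpfConfig:
    if path is None:
        return default_config()
    return SpfConfig.model_validate(json.loads(Path(path).read_text()))
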