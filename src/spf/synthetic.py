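"""Seeded synthetic gait trials with known ground-truth events.

The generator emulates the signal morphology that the detectors assume for
level walking at self-selected speed:

* a double-bump stance vGRF (weight-acceptance and push-off peaks with a
  mid-stance valley), peak scaled to ≈ 10.4 N/kg of body mass;
* a monotone heel→toe CoP progression during stance, distributed over the
  tactel layout and converted to voltages through the inverse calibration;
* a sagittal angular-velocity trace with a positive mid-swing peak and a
  negative pre-toe-off trough, and an acceleration impact burst at each heel
  strike (gravity offset on the vertical channel);
* independent additive Gaussian noise per channel.

Everything is reproducible from a single integer seed. The true heel-strike
and toe-off times are returned alongside the signals so detectors can be
benchmarked against ground truth rather than against each other.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError
from .segmentation import GaitEvents, ImuSeries
from .sensing import CalibrationPolynomial, TactelLayout, voltages_from_forces
from .trial import SensorTrial

__all__ = [
    "GaitProfileParams",
    "SyntheticTrial",
    "synth_vgrf_profile",
    "synth_cop_trajectory",
    "distribute_to_tactels",
    "synth_imu_trace",
    "simulate_trial",
]

#: Per-body-mass vGRF peak (N/kg) of the synthetic stance profile, matching
#: typical force-plate peaks for level walking.
VGRF_PEAK_PER_KG = 10.4

# Raised-cosine lobe centers / half-widths (stance-phase units) of the two
# vGRF bumps: weight acceptance and push-off.
_LOBES = ((0.3, 0.3), (0.7, 0.3))

# Mid-swing gyro peak and pre-toe-off trough of the synthetic wx trace (deg/s),
# chosen to clear the detector thresholds (+75 / -65) with margin.
_MSW_PEAK_DPS = 150.0
_MSW_HALFWIDTH_S = 0.15
_TO_TROUGH_DPS = -120.0
_TO_HALFWIDTH_S = 0.10

# Heel-strike impact burst on az: decaying 25 Hz oscillation whose first peak
# (~+8.6 m/s2, 10 ms after contact) gives a pre-peak excursion above the 7 m/s2
# detector threshold.
_BURST_AMPL_MS2 = 12.0
_BURST_TAU_S = 0.03
_BURST_FREQ_HZ = 25.0
_BURST_SPAN_S = 0.12

_GRAVITY = 9.81


@dataclass(frozen=True)
class GaitProfileParams:
    """Study conditions of one synthetic walking trial.

    Defaults describe slow level walking of a 70 kg wearer (stride period
    1.6 s, duty factor 0.62), with tactel/IMU channels at 100 Hz and the force
    plate at 200 Hz. Noise levels are per-sample Gaussian standard deviations.
    """

    stride_period: float = 1.6
    duty_factor: float = 0.62
    body_mass: float = 70.0
    n_strides: int = 20
    fs_sensors: float = 100.0
    fs_forceplate: float = 200.0
    noise_sd_voltage: float = 0.01
    noise_sd_accel: float = 0.2
    noise_sd_gyro: float = 2.0
    noise_sd_force: float = 1.0
    seed: int = 0
    lead_in: float = 1.0
    lead_out: float = 0.6
    cop_kernel_width: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ConfigurationError("duty_factor must lie in (0, 1)")
        for name in ("stride_period", "body_mass", "fs_sensors", "fs_forceplate",
                     "lead_in", "lead_out"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_strides < 0:
            raise ConfigurationError("n_strides must be nonnegative")
        if self.lead_in <= self.swing_duration / 2:
            raise ConfigurationError("lead_in must cover at least half a swing")

    @property
    def stance_duration(self) -> float:
        return self.duty_factor * self.stride_period

    @property
    def swing_duration(self) -> float:
        return (1.0 - self.duty_factor) * self.stride_period

    @property
    def duration(self) -> float:
        return self.lead_in + self.n_strides * self.stride_period + self.lead_out

    def truth_events(self) -> GaitEvents:
        hs = self.lead_in + np.arange(self.n_strides) * self.stride_period
        return GaitEvents(hs, hs + self.stance_duration)


#: Alias: a simulated trial is an ordinary :class:`~spf.trial.SensorTrial`
#: whose ``truth`` and ``params`` fields are populated.
SyntheticTrial = SensorTrial


def _lobe(x: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump: cos^2 taper, support ``|x - center| < halfwidth``."""
    u = (x - center) / halfwidth
    return np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)


def synth_vgrf_profile(phase, body_mass: float = 70.0):
    """Stance vGRF (N) as a function of stance phase in [0, 1].

    Sum of two raised-cosine lobes; zero at contact and lift-off, two local
    maxima of ``10.4 N/kg x body_mass`` with a mid-stance valley.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any((phase < 0.0) | (phase > 1.0)):
        raise DomainError("stance phase must lie in [0, 1]")
    amp = VGRF_PEAK_PER_KG * body_mass
    out = sum(amp * _lobe(phase, c, hw) for c, hw in _LOBES)
    return float(out) if out.ndim == 0 else out


def synth_cop_trajectory(phase, y_start: float = 1.0, y_end: float = 22.0):
    """Longitudinal CoP (cm) vs stance phase: smooth monotone heel→toe ramp."""
    phase = np.asarray(phase, dtype=float)
    if np.any((phase < 0.0) | (phase > 1.0)):
        raise DomainError("stance phase must lie in [0, 1]")
    s = phase * phase * (3.0 - 2.0 * phase)  # smoothstep: C1, monotone
    out = y_start + (y_end - y_start) * s
    return float(out) if out.ndim == 0 else out


def _two_point_split(total: float, cop_y: float, layout: TactelLayout) -> np.ndarray:
    """Exact CoP placement on the two tactels bracketing ``cop_y``."""
    y, w = layout.y_cm, layout.weights
    forces = np.zeros(layout.count)
    order = np.argsort(y)
    pos = np.searchsorted(y[order], cop_y)
    if pos < order.size and np.isclose(y[order][min(pos, order.size - 1)], cop_y):
        forces[order[pos]] = total
        return forces
    j, k = order[pos - 1], order[pos]
    # Solve a*wj*yj + b*wk*yk = cop*(a*wj + b*wk) with a + b = total.
    denom = layout.weights[j] * (y[j] - cop_y) - w[k] * (y[k] - cop_y)
    a = total * (-w[k] * (y[k] - cop_y)) / denom
    forces[j] = a
    forces[k] = total - a
    return forces


def distribute_to_tactels(total_force: float, cop_y: float, layout: TactelLayout,
                          kernel_width: float = 2.0) -> np.ndarray:
    """Split a total vertical force over the tactels around a target CoP.

    Loads a Gaussian kernel (std ``kernel_width`` cm, truncated at 3 sigma)
    centered on ``cop_y``, then tilts the kernel weights linearly so that the
    layout-weighted centroid matches ``cop_y`` to 1e-6 cm while every force
    stays nonnegative and the forces sum to ``total_force`` exactly.
    ``kernel_width <= 0`` degenerates to loading the (at most two) tactels
    bracketing ``cop_y``.
    """
    lo, hi = layout.span
    if not lo <= cop_y <= hi:
        raise DomainError(f"cop_y={cop_y} cm outside the layout span [{lo}, {hi}] cm")
    if total_force < 0:
        raise DomainError("total_force must be nonnegative")
    if total_force == 0.0:
        return np.zeros(layout.count)
    if kernel_width <= 0.0:
        return _two_point_split(total_force, cop_y, layout)

    y, w = layout.y_cm, layout.weights
    r = y - cop_y
    q = np.exp(-0.5 * (r / kernel_width) ** 2)
    q[np.abs(r) > 3.0 * kernel_width] = 0.0
    support_r = r[q > 0]
    # the tilt can only balance the centroid if the kernel support straddles
    # (or touches) the target; a one-sided support happens near span edges and
    # in the heel/forefoot gap
    if support_r.size == 0 or np.all(support_r > 1e-12) or np.all(support_r < -1e-12):
        return _two_point_split(total_force, cop_y, layout)

    def centroid_offset(lam: float) -> float:
        f = q * np.clip(1.0 + lam * r, 0.0, None)
        return float(np.sum(f * w * r))

    lam = 0.0
    if abs(centroid_offset(0.0)) > 0.0:
        b = 1.0 / max(np.max(np.abs(r[q > 0])), 1e-12)
        for _ in range(60):  # expand until the root is bracketed
            if centroid_offset(-b) <= 0.0 <= centroid_offset(b):
                break
            b *= 2.0
        else:
            return _two_point_split(total_force, cop_y, layout)
        lam = brentq(centroid_offset, -b, b, xtol=1e-14)
    f = q * np.clip(1.0 + lam * r, 0.0, None)
    if f.sum() <= 0.0:
        return _two_point_split(total_force, cop_y, layout)
    return total_force * f / f.sum()


def synth_imu_trace(truth: GaitEvents, params: GaitProfileParams,
                    duration: float | None = None,
                    rng: np.random.Generator | None = None) -> ImuSeries:
    """Foot IMU channels consistent with the given ground-truth events.

    wx carries one positive mid-swing lobe per swing (including the lead-in
    swing before the first heel strike) and one negative trough centered at
    each true toe-off; az carries gravity plus a decaying impact oscillation
    starting at each true heel strike. Channel noise uses ``params`` standard
    deviations (``rng`` defaults to a generator seeded from ``params.seed``).
    """
    hs, to = truth.hs_times, truth.to_times
    if hs.size != to.size or (hs.size and np.any(to <= hs)):
        raise DomainError("truth events must pair each HS with a later TO")
    truth.check_interleaved()
    if duration is None:
        last = max(hs[-1], to[-1]) if hs.size else 0.0
        duration = last + params.lead_out
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n = int(round(duration * params.fs_sensors))
    t = np.arange(n) / params.fs_sensors
    wx = np.zeros(n)
    az = np.full(n, _GRAVITY)
    for h in hs:  # mid-swing peak precedes every heel strike
        wx += _MSW_PEAK_DPS * _lobe(t, h - params.swing_duration / 2.0,
                                    _MSW_HALFWIDTH_S)
    for tto in to:
        wx += _TO_TROUGH_DPS * _lobe(t, tto, _TO_HALFWIDTH_S)
    for h in hs:
        dt = t - h
        m = (dt >= 0.0) & (dt <= _BURST_SPAN_S)
        az[m] += (_BURST_AMPL_MS2 * np.exp(-dt[m] / _BURST_TAU_S)
                  * np.sin(2.0 * np.pi * _BURST_FREQ_HZ * dt[m]))

    ax = rng.normal(0.0, params.noise_sd_accel, n) if params.noise_sd_accel else np.zeros(n)
    ay = rng.normal(0.0, params.noise_sd_accel, n) if params.noise_sd_accel else np.zeros(n)
    if params.noise_sd_accel:
        az = az + rng.normal(0.0, params.noise_sd_accel, n)
    if params.noise_sd_gyro:
        wx = wx + rng.normal(0.0, params.noise_sd_gyro, n)
    return ImuSeries(t, ax, ay, az, wx)


def _stance_phase(t: np.ndarray, params: GaitProfileParams) -> tuple[np.ndarray, np.ndarray]:
    """(in_stance mask, stance phase in [0,1]) for every sample time."""
    rel = t - params.lead_in
    k = np.floor(rel / params.stride_period)
    within = rel - k * params.stride_period
    phase = within / params.stance_duration
    in_stance = (k >= 0) & (k < params.n_strides) & (phase <= 1.0)
    return in_stance, np.clip(phase, 0.0, 1.0)


def simulate_trial(params: GaitProfileParams | None = None,
                   poly: CalibrationPolynomial | None = None,
                   layout: TactelLayout | None = None) -> SensorTrial:
    """Generate one complete synthetic trial.

    Pressure voltages are obtained by distributing the stance vGRF over the
    tactel layout along the synthetic CoP trajectory and inverting the
    calibration polynomial on its negative (pressed) branch; the force plate
    records the same vGRF and CoP directly at its own rate. All noise draws
    come from one generator seeded with ``params.seed``, so identical
    parameters yield bitwise-identical trials.
    """
    params = params or GaitProfileParams()
    poly = poly or CalibrationPolynomial()
    layout = layout or TactelLayout.default()
    rng = np.random.default_rng(params.seed)
    truth = params.truth_events()

    # --- tactel pressure channels (sensor rate) ---
    n_ps = int(round(params.duration * params.fs_sensors))
    t_ps = np.arange(n_ps) / params.fs_sensors
    in_stance, phase = _stance_phase(t_ps, params)
    forces = np.zeros((n_ps, layout.count))
    total = np.where(in_stance, synth_vgrf_profile(phase, params.body_mass), 0.0)
    cop = synth_cop_trajectory(phase)
    for i in np.flatnonzero(in_stance & (total > 0.0)):
        forces[i] = distribute_to_tactels(total[i], cop[i], layout,
                                          params.cop_kernel_width)
    voltages = voltages_from_forces(forces, poly)
    if params.noise_sd_voltage:
        voltages = voltages + rng.normal(0.0, params.noise_sd_voltage,
                                         voltages.shape)

    # --- IMU channels (sensor rate, same noise stream) ---
    imu = synth_imu_trace(truth, params, duration=params.duration, rng=rng)

    # --- force plate (plate rate) ---
    n_fp = int(round(params.duration * params.fs_forceplate))
    t_fp = np.arange(n_fp) / params.fs_forceplate
    in_st_fp, phase_fp = _stance_phase(t_fp, params)
    fz = np.where(in_st_fp, synth_vgrf_profile(phase_fp, params.body_mass), 0.0)
    cop_fp = np.where(in_st_fp, synth_cop_trajectory(phase_fp), np.nan)
    if params.noise_sd_force:
        fz = fz + rng.normal(0.0, params.noise_sd_force, n_fp)

    return SensorTrial(t_pressure=t_ps, voltages=voltages, imu=imu,
                       t_fp=t_fp, fz=fz, cop_fp=cop_fp, truth=truth,
                       params=asdict(params))
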