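"""Gait-event detection: heel strike (HS) and toe off (TO).

Two independent causal detectors are provided:

* :func:`ps_segment` — pressure-based: the foot is in stance while the
  estimated vGRF is at or above a threshold ``vGRFT``; a swing→stance
  transition is an HS, a stance→swing transition a TO.
* :func:`imu_segment` — a rule-based finite-state machine on the foot IMU:
  a confirmed local maximum of the sagittal angular velocity above
  ``ωxT_MSw`` marks mid-swing and arms the HS search; HS is a confirmed local
  maximum of the vertical acceleration whose preceding 30 ms window contains a
  peak-to-peak excursion above ``aT`` on at least one acceleration channel;
  after HS an idle period elapses, then TO is a confirmed local minimum of the
  angular velocity below ``ωxT_TO``.

Both run on uniformly sampled series and emit event timestamps on the input
time base. The reference rule used for benchmarking against a force platform
is the same threshold rule with the threshold fixed at 20 N.

"Local extremum" is made precise for streaming data by a confirmation lag: a
sample is a confirmed maximum once it is strictly greater than its ``lag``
predecessors and at least as great as its ``lag`` successors (plateaus resolve
to their first sample). The event timestamp is the extremum sample itself; it
becomes *known* ``lag`` samples later.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigurationError, DomainError, EventStructureError, ShapeError

__all__ = [
    "GaitEvents",
    "ImuSeries",
    "ImuThresholds",
    "FsmPhase",
    "FsmState",
    "confirm_local_extremum",
    "offline_confirmed_extrema",
    "ps_segment",
    "imu_segment",
    "force_plate_reference_events",
]


@dataclass(frozen=True)
class GaitEvents:
    """Ordered heel-strike and toe-off timestamps (s)."""

    hs_times: np.ndarray
    to_times: np.ndarray

    def __post_init__(self) -> None:
        hs = np.asarray(self.hs_times, dtype=float)
        to = np.asarray(self.to_times, dtype=float)
        for name, arr in (("hs_times", hs), ("to_times", to)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise EventStructureError(f"{name} must be strictly increasing")
        object.__setattr__(self, "hs_times", hs)
        object.__setattr__(self, "to_times", to)

    @property
    def n_hs(self) -> int:
        return int(self.hs_times.size)

    @property
    def n_to(self) -> int:
        return int(self.to_times.size)

    def merged(self) -> tuple[np.ndarray, list[str]]:
        """All events in time order with their labels."""
        times = np.concatenate([self.hs_times, self.to_times])
        labels = ["HS"] * self.n_hs + ["TO"] * self.n_to
        order = np.argsort(times, kind="stable")
        return times[order], [labels[i] for i in order]

    def check_interleaved(self) -> None:
        """Raise unless the merged sequence alternates HS/TO."""
        _, labels = self.merged()
        for a, b in zip(labels, labels[1:]):
            if a == b:
                raise EventStructureError("events do not alternate HS/TO")


@dataclass(frozen=True)
class ImuSeries:
    """Uniformly sampled foot IMU channels.

    ``ax, ay, az`` in m/s² (raw accelerometer output, gravity included);
    ``wx`` is the sagittal-plane angular velocity in deg/s, positive during
    the forward swing rotation.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    wx: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "ax", "ay", "az", "wx"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.t.size
        if any(getattr(self, c).size != n for c in ("ax", "ay", "az", "wx")):
            raise ShapeError("all IMU channels must have the same length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DomainError("timestamps must be strictly increasing")
            span = self.t[-1] - self.t[0]
            if np.max(np.abs(dt - dt.mean())) > 1e-9 * max(span, 1.0):
                raise DomainError("timestamps must be uniformly spaced")

    @property
    def fs(self) -> float:
        if self.t.size < 2:
            raise DomainError("need at least two samples to define a rate")
        return float((self.t.size - 1) / (self.t[-1] - self.t[0]))


@dataclass(frozen=True)
class ImuThresholds:
    """Parameters of the IMU finite-state machine.

    ``msw_gyro_min`` (ωxT_MSw, deg/s): minimum mid-swing angular-velocity peak.
    ``to_gyro_max`` (ωxT_TO, deg/s): maximum (most positive) toe-off trough.
    ``accel_pp_min`` (aT, m/s²): minimum peak-to-peak excursion, on any
    acceleration channel, within ``pre_peak_window`` before the az peak for it
    to qualify as a heel-strike impact.
    ``hs_search_window`` (s): HS must follow mid-swing within this window or
    the machine re-arms. ``idle_after_hs`` (s): dead time after HS before the
    TO search opens. ``confirm_lag`` (s): streaming local-extremum
    confirmation lag.
    """

    msw_gyro_min: float = 75.0
    to_gyro_max: float = -65.0
    accel_pp_min: float = 7.0
    hs_search_window: float = 0.75
    idle_after_hs: float = 0.4
    pre_peak_window: float = 0.030
    confirm_lag: float = 0.030

    def __post_init__(self) -> None:
        if not (self.msw_gyro_min > 0 > self.to_gyro_max):
            raise ConfigurationError("require msw_gyro_min > 0 > to_gyro_max")
        for name in ("hs_search_window", "idle_after_hs", "pre_peak_window",
                     "confirm_lag"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "ImuThresholds":
        return cls(d["midswing_gyro_min_dps"], d["toeoff_gyro_max_dps"],
                   d["accel_pp_min_ms2"], d["hs_search_window_s"],
                   d["idle_after_hs_s"], d["pre_peak_window_s"],
                   d.get("confirm_lag_s", 0.03))


class FsmPhase(Enum):
    WAIT_MSW = "WAIT_MSW"
    SEARCH_HS = "SEARCH_HS"
    IDLE = "IDLE"
    SEARCH_TO = "SEARCH_TO"


@dataclass
class FsmState:
    phase: FsmPhase = FsmPhase.WAIT_MSW
    phase_entry_time: float = float("-inf")


def confirm_local_extremum(x, i: int, mode: str = "max",
                           confirm_lag: int = 1) -> tuple[bool, int]:
    """Streaming local-extremum test at sample ``i``.

    ``x[i]`` is a confirmed extremum when it is strictly more extreme than its
    ``confirm_lag`` predecessors and at least as extreme as its ``confirm_lag``
    successors (ties resolve to the first sample of a plateau). Returns
    ``(confirmed, confirmation_index)`` where ``confirmation_index = i +
    confirm_lag`` is the sample at which the decision becomes available — the
    event timestamp stays at ``i``.
    """
    x = np.asarray(x, dtype=float)
    if confirm_lag < 1:
        raise ConfigurationError("confirm_lag must be >= 1")
    if not (0 <= i < x.size):
        raise IndexError(f"index {i} out of range for series of length {x.size}")
    if i - confirm_lag < 0 or i + confirm_lag >= x.size:
        return False, i + confirm_lag
    sign = 1.0 if mode == "max" else -1.0
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    before = sign * x[i - confirm_lag:i]
    after = sign * x[i + 1:i + confirm_lag + 1]
    val = sign * x[i]
    ok = bool(np.all(val > before) and np.all(val >= after))
    return ok, i + confirm_lag


def offline_confirmed_extrema(x, mode: str = "max", confirm_lag: int = 1) -> np.ndarray:
    """Indices of every confirmed extremum of a full series (interior points)."""
    x = np.asarray(x, dtype=float)
    return np.array([i for i in range(confirm_lag, x.size - confirm_lag)
                     if confirm_local_extremum(x, i, mode, confirm_lag)[0]],
                    dtype=int)


def _threshold_events(t: np.ndarray, x: np.ndarray, threshold: float) -> GaitEvents:
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size == 0 or x.size == 0:
        raise DomainError("empty series")
    if t.size != x.size:
        raise ShapeError("time base and series must have equal length")
    stance = x >= threshold
    # Transitions only: the phase in progress at the first sample yields no
    # event (its onset was not observed), so a recording that starts mid-stance
    # emits no spurious HS at t[0].
    d = np.diff(stance.astype(np.int8))
    hs = t[1:][d == 1]
    to = t[1:][d == -1]
    return GaitEvents(hs, to)


def ps_segment(t, vgrf, vgrf_threshold: float = 15.0) -> GaitEvents:
    """Pressure-based detector: stance while ``vgrf >= vgrf_threshold`` (N).

    HS is stamped on the first stance sample of each swing→stance transition,
    TO on the first swing sample of each stance→swing transition. The
    threshold is normally tuned within [10, 20] N; values outside that range
    trigger a warning but are honored.
    """
    if not (10.0 <= vgrf_threshold <= 20.0):
        warnings.warn(
            f"vGRF threshold {vgrf_threshold} N outside the usual [10, 20] N range",
            stacklevel=2)
    return _threshold_events(t, vgrf, vgrf_threshold)


def force_plate_reference_events(t, fz) -> GaitEvents:
    """Reference gait events from force-plate vertical force at a fixed 20 N."""
    return _threshold_events(t, fz, 20.0)


def imu_segment(imu: ImuSeries, thr: ImuThresholds | None = None) -> GaitEvents:
    """IMU finite-state machine detector (causal single pass).

    Phases cycle WAIT_MSW → SEARCH_HS → IDLE → SEARCH_TO → WAIT_MSW, with a
    timeout edge SEARCH_HS → WAIT_MSW when no heel strike is confirmed within
    ``hs_search_window`` of mid-swing. Emitted events are guaranteed to
    alternate HS, TO, HS, TO, … with at most one HS per mid-swing detection.
    """
    thr = thr or ImuThresholds()
    fs = imu.fs
    lag = max(1, round(thr.confirm_lag * fs))
    if thr.pre_peak_window * fs < 1.0:
        raise ConfigurationError(
            f"sampling rate {fs:.3g} Hz cannot resolve the "
            f"{thr.pre_peak_window * 1e3:.0f} ms pre-peak window")
    t, wx, az = imu.t, imu.wx, imu.az
    accel = (imu.ax, imu.ay, imu.az)
    n = t.size
    state = FsmState()
    hs_times: list[float] = []
    to_times: list[float] = []
    t_msw = t_hs = float("-inf")

    for j in range(lag, n):
        i = j - lag  # newest sample whose extremum status is decidable
        ti = t[i]
        if state.phase is FsmPhase.SEARCH_HS and ti - t_msw > thr.hs_search_window:
            state = FsmState(FsmPhase.WAIT_MSW, ti)  # timeout: re-arm
        if state.phase is FsmPhase.WAIT_MSW:
            if wx[i] >= thr.msw_gyro_min and \
                    confirm_local_extremum(wx, i, "max", lag)[0]:
                t_msw = ti
                state = FsmState(FsmPhase.SEARCH_HS, ti)
        elif state.phase is FsmPhase.SEARCH_HS:
            if confirm_local_extremum(az, i, "max", lag)[0]:
                w0 = int(np.searchsorted(t, ti - thr.pre_peak_window, side="right"))
                window = slice(w0, i + 1)
                if any(float(np.ptp(ch[window])) > thr.accel_pp_min for ch in accel):
                    t_hs = ti
                    hs_times.append(ti)
                    state = FsmState(FsmPhase.IDLE, ti)
        if state.phase is FsmPhase.IDLE and ti >= t_hs + thr.idle_after_hs:
            state = FsmState(FsmPhase.SEARCH_TO, ti)
        if state.phase is FsmPhase.SEARCH_TO:
            if ti >= t_hs + thr.idle_after_hs and wx[i] <= thr.to_gyro_max and \
                    confirm_local_extremum(wx, i, "min", lag)[0]:
                to_times.append(ti)
                state = FsmState(FsmPhase.WAIT_MSW, ti)

    events = GaitEvents(np.array(hs_times), np.array(to_times))
    events.check_interleaved()
    return events
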