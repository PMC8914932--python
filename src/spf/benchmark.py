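"""Benchmarking gait detectors and waveforms against a force-plate reference.

The evaluation mirrors standard gait-lab practice: reference heel-strike and
toe-off events come from the force plate at a fixed 20 N threshold; detector
events are paired one-to-one with the nearest same-type reference event;
timing errors are summarized per trial by the median absolute error (MAE) and
the interquartile range (IQR) of the absolute errors, then grouped across
trials by taking the median of the per-trial summaries. Waveform agreement
(vGRF, CoPy) is assessed after zero-phase low-pass filtering (2nd-order
Butterworth, 25 Hz) and time-normalization of each stance onto 1000 samples,
via the Pearson correlation coefficient and the RMSE, plus the body-mass
normalized vGRF peak per stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, DomainError, EventStructureError
from .segmentation import (GaitEvents, force_plate_reference_events, imu_segment,
                           ps_segment)
from .sensing import (CalibrationPolynomial, SensingThresholds, TactelLayout,
                      compute_copy, compute_vgrf)
from .trial import SensorTrial

__all__ = [
    "EventErrorStats",
    "WaveformAgreement",
    "MatchResult",
    "BenchmarkReport",
    "lowpass_filter",
    "resample_stance",
    "match_times",
    "match_events",
    "event_error_stats",
    "stance_durations",
    "waveform_agreement",
    "peak_vgrf_normalized",
    "evaluate_trial",
    "evaluate_cohort",
]

_BIG = 1e9  # assignment cost for out-of-gap pairs


def lowpass_filter(x, fs: float, cutoff: float = 25.0, order: int = 2):
    """Zero-phase (forward-backward) Butterworth low-pass, same length as input.

    Used only in the offline analysis; the causal detectors never see it.
    Works on 1-D series or on matrices (filtered along axis 0).
    """
    if not fs > 2.0 * cutoff:
        raise ConfigurationError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {fs / 2} Hz")
    b, a = butter(order, cutoff, fs=fs)
    return filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def resample_stance(t, x, hs: float, to: float, n: int = 1000) -> np.ndarray:
    """Linearly interpolate one stance onto ``n`` evenly spaced points.

    Samples where ``x`` is NaN (e.g. CoP outside its validity window) are
    dropped before interpolation; values outside the remaining support clamp
    to the nearest defined sample.
    """
    if not to > hs:
        raise DomainError("stance requires to > hs")
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    m = (t >= hs) & (t <= to) & np.isfinite(x)
    if np.count_nonzero(m) < 2:
        raise DomainError("stance contains fewer than 2 defined samples")
    grid = np.linspace(hs, to, n)
    return np.interp(grid, t[m], x[m])


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of detected against reference event times."""

    ref_times: np.ndarray
    det_times: np.ndarray
    errors: np.ndarray          # detected - reference, s
    unmatched_ref: np.ndarray   # misses
    unmatched_det: np.ndarray   # false alarms

    @property
    def n_pairs(self) -> int:
        return int(self.errors.size)


def match_times(detected, reference, max_gap: float) -> MatchResult:
    """Pair each reference time with the nearest detected time within ``max_gap``.

    The pairing is one-to-one and minimizes the total absolute error over all
    maximal pairings (solved as a rectangular assignment problem), so a
    detection cannot be claimed by two reference events.
    """
    det = np.asarray(detected, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if det.size == 0 or ref.size == 0:
        return MatchResult(np.empty(0), np.empty(0), np.empty(0), ref, det)
    cost = np.abs(det[:, None] - ref[None, :])
    cost = np.where(cost <= max_gap, cost, _BIG)
    rows, cols = linear_sum_assignment(cost)
    ok = cost[rows, cols] < _BIG
    rows, cols = rows[ok], cols[ok]
    order = np.argsort(ref[cols])
    rows, cols = rows[order], cols[order]
    return MatchResult(
        ref_times=ref[cols],
        det_times=det[rows],
        errors=det[rows] - ref[cols],
        unmatched_ref=np.delete(ref, cols),
        unmatched_det=np.delete(det, rows),
    )


def _default_gap(reference: GaitEvents) -> float:
    hs = reference.hs_times
    if hs.size >= 2:
        return float(np.median(np.diff(hs)) / 2.0)
    return 0.5


def match_events(detected: GaitEvents, reference: GaitEvents,
                 max_gap: float | None = None) -> dict[str, MatchResult]:
    """Pair HS with HS and TO with TO (default gap: half the reference stride)."""
    gap = max_gap if max_gap is not None else _default_gap(reference)
    return {
        "HS": match_times(detected.hs_times, reference.hs_times, gap),
        "TO": match_times(detected.to_times, reference.to_times, gap),
    }


@dataclass(frozen=True)
class EventErrorStats:
    """Timing-error summary for one event type of one detector."""

    errors: np.ndarray
    mae: float              # median absolute error, s
    iqr: float              # Q3 - Q1 of the absolute errors, s
    pct_late: float         # fraction of detections with error > 0
    mae_pct_stride: float   # MAE as percent of the stride period

    def __post_init__(self) -> None:
        if not (self.mae >= 0 and self.iqr >= 0 and 0 <= self.pct_late <= 1):
            raise DomainError("inconsistent error statistics")


def event_error_stats(errors, stride_period: float) -> EventErrorStats:
    """MAE / IQR / late fraction of signed timing errors (detected - reference).

    Quantiles use linear interpolation between order statistics.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise DomainError("no event pairs to summarize")
    ae = np.abs(errors)
    mae = float(np.median(ae))
    q1, q3 = np.percentile(ae, [25.0, 75.0])
    return EventErrorStats(
        errors=errors,
        mae=mae,
        iqr=float(q3 - q1),
        pct_late=float(np.mean(errors > 0.0)),
        mae_pct_stride=100.0 * mae / stride_period,
    )


def stance_durations(events: GaitEvents) -> np.ndarray:
    """Per-stride stance duration: TO - HS for each HS followed by its TO."""
    events.check_interleaved()
    hs, to = events.hs_times, events.to_times
    durations = []
    for h in hs:
        later = to[to > h]
        if later.size:
            durations.append(float(later[0] - h))
    return np.asarray(durations)


@dataclass(frozen=True)
class WaveformAgreement:
    """Pearson correlation and RMSE between two stance-normalized signals."""

    pearson_r: float
    rmse: float
    n_strides: int
    per_stride_r: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    per_stride_rmse: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return float("nan")  # undefined-correlation marker
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def waveform_agreement(a, b) -> WaveformAgreement:
    """Agreement between matching ``(strides x n)`` resampled waveform matrices."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise DomainError(f"shape mismatch {a.shape} vs {b.shape}")
    r = _pearson(a.ravel(), b.ravel())
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    per_r = np.array([_pearson(ai, bi) for ai, bi in zip(a, b)])
    per_rmse = np.sqrt(np.mean((a - b) ** 2, axis=1))
    return WaveformAgreement(r, rmse, a.shape[0], per_r, per_rmse)


def peak_vgrf_normalized(vgrf_stances, body_mass: float) -> np.ndarray:
    """Per-stride vGRF peak divided by body mass (N/kg)."""
    if not body_mass > 0:
        raise DomainError("body mass must be positive")
    m = np.atleast_2d(np.asarray(vgrf_stances, dtype=float))
    return m.max(axis=1) / body_mass


# ---------------------------------------------------------------------------
# trial- and cohort-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-trial results plus grouped (median-of-medians) summaries."""

    per_trial: list[dict]
    grouped: dict
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {"schema_version": self.schema_version,
                "n_trials": len(self.per_trial),
                "grouped": self.grouped,
                "per_trial": self.per_trial}


def _stats_dict(s: EventErrorStats) -> dict:
    return {"mae_s": s.mae, "iqr_s": s.iqr, "pct_late": s.pct_late,
            "mae_pct_stride": s.mae_pct_stride, "n": int(s.errors.size)}


def evaluate_trial(trial: SensorTrial,
                   poly: CalibrationPolynomial | None = None,
                   layout: TactelLayout | None = None,
                   thr: SensingThresholds | None = None,
                   imu_thr=None,
                   max_gap: float | None = None,
                   resample_n: int = 1000) -> dict:
    """Run both detectors on one trial and benchmark them against the plate.

    Detection runs on the raw (causal) signals; waveform comparisons use the
    25 Hz zero-phase filtered pressure channels resampled over each reference
    stance. Returns a plain-dict report for one trial.
    """
    poly = poly or CalibrationPolynomial()
    layout = layout or TactelLayout.default()
    thr = thr or SensingThresholds()
    if trial.fz is None or trial.t_fp is None:
        raise DomainError("trial lacks force-plate data required as reference")

    vgrf_raw = compute_vgrf(trial.voltages, poly, layout, thr)
    ps_ev = ps_segment(trial.t_pressure, vgrf_raw, thr.vgrf_min)
    imu_ev = imu_segment(trial.imu, imu_thr)
    ref_ev = force_plate_reference_events(trial.t_fp, trial.fz)

    hs_ref = ref_ev.hs_times
    stride = float(np.median(np.diff(hs_ref))) if hs_ref.size >= 2 else float("nan")
    gap = max_gap if max_gap is not None else _default_gap(ref_ev)

    report: dict = {"stride_period_s": stride, "detectors": {}}
    ref_st = stance_durations(ref_ev)
    for name, ev in (("PS", ps_ev), ("IMU", imu_ev)):
        matches = match_events(ev, ref_ev, gap)
        det: dict = {}
        for kind in ("HS", "TO"):
            m = matches[kind]
            det[kind] = (_stats_dict(event_error_stats(m.errors, stride))
                         if m.n_pairs else None)
            det[kind + "_misses"] = int(m.unmatched_ref.size)
            det[kind + "_false_alarms"] = int(m.unmatched_det.size)
        # stance-duration error on strides whose HS and TO both matched
        st_err = _matched_stance_errors(matches, ref_ev)
        det["St"] = _stats_dict(event_error_stats(st_err, stride)) if st_err.size else None
        report["detectors"][name] = det

    # --- waveform agreement over reference stances ---
    fs_ps = trial.fs_sensors
    volt_f = lowpass_filter(trial.voltages, fs_ps)
    vgrf_f = compute_vgrf(volt_f, poly, layout, thr)
    copy_f = compute_copy(volt_f, poly, layout, thr)

    vgrf_ps_rs, vgrf_fp_rs, copy_ps_rs, copy_fp_rs = [], [], [], []
    for h, d in zip(ref_ev.hs_times, ref_st):
        to = h + d
        try:
            v_ps = resample_stance(trial.t_pressure, vgrf_f, h, to, resample_n)
            v_fp = resample_stance(trial.t_fp, trial.fz, h, to, resample_n)
            c_ps = resample_stance(trial.t_pressure, copy_f, h, to, resample_n)
        except DomainError:
            continue
        vgrf_ps_rs.append(v_ps)
        vgrf_fp_rs.append(v_fp)
        copy_ps_rs.append(c_ps)
        if trial.cop_fp is not None:
            copy_fp_rs.append(resample_stance(trial.t_fp, trial.cop_fp, h, to,
                                              resample_n))

    body_mass = float(trial.params.get("body_mass", 0.0)) or None
    if vgrf_ps_rs:
        wa_v = waveform_agreement(vgrf_ps_rs, vgrf_fp_rs)
        report["vgrf"] = {"pearson_r": wa_v.pearson_r, "n_strides": wa_v.n_strides}
        if body_mass:
            report["vgrf"]["peak_ps_n_per_kg"] = float(np.median(
                peak_vgrf_normalized(vgrf_ps_rs, body_mass)))
            report["vgrf"]["peak_fp_n_per_kg"] = float(np.median(
                peak_vgrf_normalized(vgrf_fp_rs, body_mass)))
        if copy_fp_rs:
            wa_c = waveform_agreement(copy_ps_rs, copy_fp_rs)
            report["copy"] = {"pearson_r": wa_c.pearson_r, "rmse_cm": wa_c.rmse,
                              "n_strides": wa_c.n_strides}
    return report


def _matched_stance_errors(matches: dict[str, MatchResult],
                           ref_ev: GaitEvents) -> np.ndarray:
    """Detected-minus-reference stance durations for fully matched strides."""
    mh, mt = matches["HS"], matches["TO"]
    ref_st = {}
    to = ref_ev.to_times
    for h in ref_ev.hs_times:
        later = to[to > h]
        if later.size:
            ref_st[float(h)] = float(later[0])
    errs = []
    det_to_by_ref = dict(zip(mt.ref_times.tolist(), mt.det_times.tolist()))
    for rh, dh in zip(mh.ref_times.tolist(), mh.det_times.tolist()):
        rt = ref_st.get(rh)
        if rt is None or rt not in det_to_by_ref:
            continue
        errs.append((det_to_by_ref[rt] - dh) - (rt - rh))
    return np.asarray(errs)


def _nested_median(dicts: list[dict]) -> dict:
    """Median across trials of every numeric leaf shared by all trial dicts."""
    out: dict = {}
    keys = set().union(*(d.keys() for d in dicts)) if dicts else set()
    for k in sorted(keys):
        vals = [d.get(k) for d in dicts]
        if all(isinstance(v, dict) for v in vals):
            out[k] = _nested_median(vals)
        else:
            nums = [v for v in vals if isinstance(v, (int, float)) and np.isfinite(v)]
            out[k] = float(np.median(nums)) if nums else None
    return out


def evaluate_cohort(trials: list[SensorTrial], **kwargs) -> BenchmarkReport:
    """Evaluate each trial then group by the median of the per-trial results.

    Per-trial medians stand in for per-subject medians: each simulated trial
    plays the role of one subject, and the grouped value is the median of the
    individual results.
    """
    per_trial = [evaluate_trial(tr, **kwargs) for tr in trials]
    return BenchmarkReport(per_trial=per_trial, grouped=_nested_median(per_trial))
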