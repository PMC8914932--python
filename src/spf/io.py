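"""CSV / JSON file formats for trials, events, and benchmark reports.

Dialects (UTF-8, '.' decimal separator, LF or CRLF accepted):

* pressure CSV — ``time_s,v01..vNN`` (one column per tactel, volts);
* IMU CSV — ``time_s,ax,ay,az,wx`` (m/s² and deg/s);
* force-plate CSV — ``time_s,fz_n[,cop_y_cm]``;
* events CSV — ``event_type,time_s,detector`` with event_type in {HS, TO};
* benchmark report — schema-versioned JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import BenchmarkReport
from .config import SpfConfig
from .errors import ConfigurationError, DomainError, ShapeError
from .segmentation import GaitEvents, ImuSeries
from .trial import SensorTrial

__all__ = [
    "TrialFileSet",
    "write_trial",
    "read_trial",
    "write_events",
    "read_events",
    "write_report",
    "read_report",
]

_IMU_COLS = ["time_s", "ax", "ay", "az", "wx"]


@dataclass(frozen=True)
class TrialFileSet:
    """Paths of the files that make up one trial on disk."""

    pressure: Path
    imu: Path
    forceplate: Path | None = None
    truth: Path | None = None
    params: Path | None = None

    @classmethod
    def from_dir(cls, directory: str | Path) -> "TrialFileSet":
        d = Path(directory)
        opt = lambda p: p if p.exists() else None
        return cls(pressure=d / "pressure.csv", imu=d / "imu.csv",
                   forceplate=opt(d / "forceplate.csv"),
                   truth=opt(d / "truth.csv"), params=opt(d / "params.json"))


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ShapeError(f"{path}: missing column(s) {missing}")


def _check_monotone(t: np.ndarray, path: Path) -> None:
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise DomainError(f"{path}: timestamps must be strictly increasing")


def write_trial(trial: SensorTrial, directory: str | Path) -> TrialFileSet:
    """Write a trial as CSVs plus a parameter-echo JSON into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    n_tactels = trial.voltages.shape[1]
    pcols = [f"v{i + 1:02d}" for i in range(n_tactels)]
    pd.DataFrame({"time_s": trial.t_pressure} |
                 {c: trial.voltages[:, i] for i, c in enumerate(pcols)}
                 ).to_csv(d / "pressure.csv", index=False, float_format="%.6g")
    imu = trial.imu
    pd.DataFrame({"time_s": imu.t, "ax": imu.ax, "ay": imu.ay,
                  "az": imu.az, "wx": imu.wx}
                 ).to_csv(d / "imu.csv", index=False, float_format="%.6g")
    if trial.fz is not None:
        fp = {"time_s": trial.t_fp, "fz_n": trial.fz}
        if trial.cop_fp is not None:
            fp["cop_y_cm"] = trial.cop_fp
        pd.DataFrame(fp).to_csv(d / "forceplate.csv", index=False,
                                float_format="%.6g")
    if trial.truth is not None:
        write_events(trial.truth, d / "truth.csv", detector="TRUTH")
    (d / "params.json").write_text(json.dumps(trial.params, indent=2) + "\n")
    return TrialFileSet.from_dir(d)


def read_trial(paths: TrialFileSet | str | Path,
               config: SpfConfig | None = None) -> SensorTrial:
    """Read and validate a trial; rejects channel-count and rate mismatches."""
    if not isinstance(paths, TrialFileSet):
        paths = TrialFileSet.from_dir(paths)

    press = pd.read_csv(paths.pressure)
    _require_columns(press, ["time_s"], paths.pressure)
    vcols = [c for c in press.columns if c.startswith("v")]
    t_ps = press["time_s"].to_numpy(float)
    _check_monotone(t_ps, paths.pressure)
    voltages = press[vcols].to_numpy(float)

    imu_df = pd.read_csv(paths.imu)
    _require_columns(imu_df, _IMU_COLS, paths.imu)
    imu = ImuSeries(*(imu_df[c].to_numpy(float) for c in _IMU_COLS))

    t_fp = fz = cop_fp = None
    if paths.forceplate is not None:
        fp = pd.read_csv(paths.forceplate)
        _require_columns(fp, ["time_s", "fz_n"], paths.forceplate)
        t_fp = fp["time_s"].to_numpy(float)
        _check_monotone(t_fp, paths.forceplate)
        fz = fp["fz_n"].to_numpy(float)
        if "cop_y_cm" in fp.columns:
            cop_fp = fp["cop_y_cm"].to_numpy(float)

    truth = read_events(paths.truth)[0] if paths.truth is not None else None
    params = (json.loads(Path(paths.params).read_text())
              if paths.params is not None else {})

    if config is not None:
        expect = len(config.layout.y_cm)
        if voltages.shape[1] != expect:
            raise ShapeError(
                f"{paths.pressure}: {voltages.shape[1]} tactel columns, "
                f"layout expects {expect}")
        fs_cfg = config.simulator.fs_sensors_hz
        fs_file = (t_ps.size - 1) / (t_ps[-1] - t_ps[0])
        if abs(fs_file - fs_cfg) > 1e-6 * fs_cfg:
            raise ConfigurationError(
                f"{paths.pressure}: sampling rate {fs_file:.6g} Hz does not "
                f"match configured {fs_cfg:.6g} Hz")

    return SensorTrial(t_pressure=t_ps, voltages=voltages, imu=imu,
                       t_fp=t_fp, fz=fz, cop_fp=cop_fp, truth=truth,
                       params=params)


def write_events(events: GaitEvents, path: str | Path, detector: str) -> None:
    """Events CSV: one row per event, columns event_type,time_s,detector."""
    times, labels = events.merged()
    pd.DataFrame({"event_type": labels, "time_s": times,
                  "detector": detector}).to_csv(path, index=False,
                                                float_format="%.6f")


def read_events(path: str | Path) -> tuple[GaitEvents, str | None]:
    df = pd.read_csv(path)
    _require_columns(df, ["event_type", "time_s"], Path(path))
    hs = df.loc[df["event_type"] == "HS", "time_s"].to_numpy(float)
    to = df.loc[df["event_type"] == "TO", "time_s"].to_numpy(float)
    detector = None
    if "detector" in df.columns and len(df):
        detector = str(df["detector"].iloc[0])
    return GaitEvents(np.sort(hs), np.sort(to)), detector


def write_report(report: BenchmarkReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2,
                                     allow_nan=True) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
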