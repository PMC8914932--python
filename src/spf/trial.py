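"""In-memory container for one recorded or simulated walking trial."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import GaitEvents, ImuSeries


@dataclass
class SensorTrial:
    """Time-aligned multichannel trial data.

    ``t_pressure`` / ``voltages``: tactel matrix sampled at the sensor rate
    (rows = time, columns = tactels, V). ``imu``: foot IMU channels at the
    same rate. ``t_fp`` / ``fz``: force-plate vertical force (N) at the plate
    rate; ``cop_fp`` is the plate's longitudinal CoP (cm, NaN during swing).
    ``truth`` carries ground-truth gait events when known (simulation);
    ``params`` echoes the generating/recording parameters.
    """

    t_pressure: np.ndarray
    voltages: np.ndarray
    imu: ImuSeries
    t_fp: np.ndarray | None = None
    fz: np.ndarray | None = None
    cop_fp: np.ndarray | None = None
    truth: GaitEvents | None = None
    params: dict = field(default_factory=dict)

    @property
    def fs_sensors(self) -> float:
        t = self.t_pressure
        return float((t.size - 1) / (t[-1] - t[0]))

    @property
    def fs_forceplate(self) -> float | None:
        if self.t_fp is None:
            return None
        return float((self.t_fp.size - 1) / (self.t_fp[-1] - self.t_fp[0]))
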