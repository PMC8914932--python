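"""Optoelectronic tactel sensing: calibration, vGRF and longitudinal CoP.

A tactel is a single optoelectronic pressure transducer (LED + photodiode under
a silicone pad). Pressing a tactel lowers an internal curtain that obstructs
the light path, so a *pressed tactel outputs a negative voltage*. A 4th-degree
polynomial maps the output voltage (V) to the applied normal force (N).

The foot-level quantities are

* vGRF — vertical ground reaction force, the sum of the per-tactel forces,
  where a tactel contributes only while its voltage is at or below the gate
  ``VT`` (this suppresses noise on unloaded channels), and
* CoPy — the longitudinal center of pressure, the force-weighted mean of the
  tactel coordinates ``y_i`` (cm from the heel), defined only while the foot
  is loaded (vGRF at or above ``vGRFT``).

Units are fixed throughout the package: volts, newtons, centimeters, seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, DegenerateLoadError, DomainError, ShapeError

__all__ = [
    "CalibrationPolynomial",
    "TactelLayout",
    "SensingThresholds",
    "PressureFrame",
    "force_from_voltage",
    "voltage_from_force",
    "voltages_from_forces",
    "tactel_forces",
    "compute_vgrf",
    "compute_copy",
]


def _default_config() -> dict:
    with resources.files("spf.data").joinpath("default_config.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class CalibrationPolynomial:
    """Voltage→force map ``F(v) = p1 v^4 + p2 v^3 + p3 v^2 + p4 v + p5``.

    The default coefficients are the bench characterization of the tactel
    (quasi-static normal load). With ``p5 = 0`` an unloaded tactel reads
    exactly 0 N. ``branch_v`` is the voltage interval on which the polynomial
    is strictly monotone and invertible; pressed tactels live on the negative
    branch.
    """

    p1: float = 186.1
    p2: float = 224.5
    p3: float = 64.76
    p4: float = -18.59
    p5: float = 0.0
    branch_v: tuple[float, float] = (-2.0, 0.0)

    @property
    def coeffs(self) -> np.ndarray:
        """Coefficients in descending powers, as used by :func:`numpy.polyval`."""
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5])

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationPolynomial":
        branch = tuple(d.get("branch_v", (-2.0, 0.0)))
        return cls(d["p1"], d["p2"], d["p3"], d["p4"], d["p5"], branch)

    @classmethod
    def default(cls) -> "CalibrationPolynomial":
        return cls.from_dict(_default_config()["calibration"])


@dataclass(frozen=True)
class TactelLayout:
    """Geometry of the instrumented sole.

    ``y_cm`` are the longitudinal coordinates of the tactels measured from the
    heel; the default sole spans 0–22.8 cm with 5 heel and 11 forefoot
    tactels. ``weights`` are the per-tactel CoP weights ``w_i`` (dimensionless,
    nonnegative; the default is 1 for every tactel since ``y_i`` already
    carries the lever arm).
    """

    y_cm: np.ndarray
    region: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "y_cm", np.asarray(self.y_cm, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "region", tuple(self.region))
        n = self.y_cm.size
        if len(self.region) != n or self.weights.size != n:
            raise ShapeError("y_cm, region and weights must have equal length")
        if np.any(self.weights < 0):
            raise ConfigurationError("CoP weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ConfigurationError("at least one CoP weight must be positive")
        bad = set(self.region) - {"heel", "forefoot"}
        if bad:
            raise ConfigurationError(f"unknown region labels: {sorted(bad)}")

    @property
    def count(self) -> int:
        return int(self.y_cm.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.y_cm.min()), float(self.y_cm.max())

    @classmethod
    def from_dict(cls, d: dict) -> "TactelLayout":
        return cls(np.asarray(d["y_cm"], float), tuple(d["region"]),
                   np.asarray(d["weights"], float))

    @classmethod
    def default(cls) -> "TactelLayout":
        return cls.from_dict(_default_config()["layout"])


@dataclass(frozen=True)
class SensingThresholds:
    """Noise gates of the pressure pipeline.

    ``voltage_gate`` (VT): a tactel contributes to vGRF only while its output
    voltage is at or below this (pressed tactels are negative). ``vgrf_min``
    (vGRFT): minimum vGRF, in N, for the foot to count as loaded — CoPy is
    undefined below it; the same threshold drives pressure-based gait
    segmentation and is normally tuned within 10–20 N.
    """

    voltage_gate: float = -0.05
    vgrf_min: float = 15.0

    def __post_init__(self) -> None:
        if not self.vgrf_min > 0:
            raise ConfigurationError("vgrf_min must be positive")


@dataclass(frozen=True)
class PressureFrame:
    """One time sample of the tactel matrix."""

    voltages: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "voltages", np.asarray(self.voltages, dtype=float))


def _as_voltages(frame: "PressureFrame | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(frame, PressureFrame):
        return frame.voltages
    return np.asarray(frame, dtype=float)


def force_from_voltage(v, poly: CalibrationPolynomial | None = None):
    """Evaluate the calibration polynomial at voltage ``v`` (scalar or array).

    Uses Horner's nested form for numerical stability. Note the raw polynomial
    can be slightly negative for small voltages; clamping to physical forces
    happens in :func:`tactel_forces`, not here.
    """
    poly = poly or CalibrationPolynomial()
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DomainError("voltage must be finite")
    f = (((poly.p1 * v + poly.p2) * v + poly.p3) * v + poly.p4) * v + poly.p5
    return float(f) if f.ndim == 0 else f


def _check_monotone_branch(poly: CalibrationPolynomial,
                           branch: tuple[float, float], n: int = 1025) -> np.ndarray:
    """Return a dense voltage grid on ``branch``; raise if F is not strictly monotone."""
    lo, hi = branch
    if not lo < hi:
        raise ConfigurationError("branch interval must satisfy lo < hi")
    grid = np.linspace(lo, hi, n)
    f = force_from_voltage(grid, poly)
    d = np.diff(f)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ConfigurationError(
            f"calibration polynomial is not strictly monotone on {branch}")
    return grid


def voltage_from_force(f: float, poly: CalibrationPolynomial | None = None,
                       branch: tuple[float, float] | None = None,
                       tol: float = 1e-6) -> float:
    """Invert the calibration map on a monotone branch (bracketing root-finder).

    Raises :class:`DomainError` if ``f`` is outside the image of the branch and
    :class:`ConfigurationError` if the polynomial is not monotone there.
    """
    poly = poly or CalibrationPolynomial()
    branch = branch or poly.branch_v
    _check_monotone_branch(poly, branch)
    lo, hi = branch
    f_lo, f_hi = force_from_voltage(lo, poly), force_from_voltage(hi, poly)
    f_min, f_max = min(f_lo, f_hi), max(f_lo, f_hi)
    if not (f_min <= f <= f_max):
        raise DomainError(
            f"force {f} N outside the branch image [{f_min:.3g}, {f_max:.3g}] N")
    return float(brentq(lambda v: force_from_voltage(v, poly) - f, lo, hi,
                        xtol=1e-12, rtol=8.9e-16))


def voltages_from_forces(forces, poly: CalibrationPolynomial | None = None,
                         branch: tuple[float, float] | None = None,
                         n_grid: int = 4097) -> np.ndarray:
    """Vectorized inverse of the calibration map on a monotone branch.

    Grid interpolation followed by two Newton refinements; used by the gait
    simulator to emit voltages for whole force matrices at once. Zero force
    maps to exactly 0 V when the branch contains 0 and ``p5 = 0``.
    """
    poly = poly or CalibrationPolynomial()
    branch = branch or poly.branch_v
    grid = _check_monotone_branch(poly, branch, n_grid)
    forces = np.asarray(forces, dtype=float)
    fg = force_from_voltage(grid, poly)
    order = np.argsort(fg)
    f_min, f_max = fg[order[0]], fg[order[-1]]
    if np.any(forces < f_min - 1e-9) or np.any(forces > f_max + 1e-9):
        raise DomainError("some forces lie outside the branch image")
    v = np.interp(np.clip(forces, f_min, f_max), fg[order], grid[order])
    dcoef = np.polyder(poly.coeffs)
    for _ in range(2):  # Newton polish; derivative is bounded away from 0 on the branch
        v = v - (np.polyval(poly.coeffs, v) - forces) / np.polyval(dcoef, v)
    v = np.clip(v, branch[0], branch[1])
    return v


def tactel_forces(frame, poly: CalibrationPolynomial | None = None,
                  layout: TactelLayout | None = None,
                  thr: SensingThresholds | None = None) -> np.ndarray:
    """Per-tactel forces with the VT gate and physical clamping applied.

    ``frame`` may be a :class:`PressureFrame`, a length-``count`` vector, or an
    ``(n_samples, count)`` matrix. A tactel contributes only while
    ``V_i <= VT``; negative polynomial outputs are clamped to 0 N.
    """
    poly = poly or CalibrationPolynomial()
    layout = layout or TactelLayout.default()
    thr = thr or SensingThresholds()
    v = _as_voltages(frame)
    if v.shape[-1] != layout.count:
        raise ShapeError(
            f"frame has {v.shape[-1]} channels, layout expects {layout.count}")
    active = v <= thr.voltage_gate
    f = np.clip(force_from_voltage(v, poly), 0.0, None)
    return np.where(active, f, 0.0)


def compute_vgrf(frame, poly: CalibrationPolynomial | None = None,
                 layout: TactelLayout | None = None,
                 thr: SensingThresholds | None = None):
    """Vertical ground reaction force: gated, clamped sum of tactel forces (N)."""
    f = tactel_forces(frame, poly, layout, thr)
    out = np.clip(f.sum(axis=-1), 0.0, None)
    return float(out) if out.ndim == 0 else out


def compute_copy(frame, poly: CalibrationPolynomial | None = None,
                 layout: TactelLayout | None = None,
                 thr: SensingThresholds | None = None):
    """Longitudinal center of pressure (cm from the heel).

    Defined only while the foot is loaded (vGRF >= vGRFT); returns NaN for
    unloaded samples. Raises :class:`DegenerateLoadError` if a loaded sample
    has zero total CoP weight mass (all load on zero-weight tactels).
    """
    poly = poly or CalibrationPolynomial()
    layout = layout or TactelLayout.default()
    thr = thr or SensingThresholds()
    f = tactel_forces(frame, poly, layout, thr)
    vgrf = np.clip(f.sum(axis=-1), 0.0, None)
    fw = f * layout.weights
    den = fw.sum(axis=-1)
    num = (fw * layout.y_cm).sum(axis=-1)
    loaded = vgrf >= thr.vgrf_min
    if np.any(loaded & (den == 0.0)):
        raise DegenerateLoadError("foot loaded but CoP weight mass is zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.where(loaded, num / np.where(den == 0.0, np.nan, den), np.nan)
    return float(cop) if cop.ndim == 0 else cop
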