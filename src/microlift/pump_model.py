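"""Rotary-pump calibration and pulse-volume integration.

The pump's speed is set as a fraction of its maximum angular velocity; each
setting produces a characteristic peak suction flow. The relation is smooth
but measured at only a handful of settings, so it is interpolated with a
shape-preserving monotone cubic (PCHIP) that passes exactly through the
measured knots and cannot overshoot between them. Flow pulses recorded as
Q(t) traces are integrated with the trapezoid rule to give the liquid
volume drawn into the capillary per actuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

#: smallest peak flow (μl/s) that reliably lifts a 400-μm microtissue
DEFAULT_Q_MIN_UL_S = 5.1
#: arc of the rotation (degrees) where the pump delivers its peak flow
DEFAULT_OPERATING_ARC = (180.0, 210.0)


class CalibrationError(ValueError):
    pass


@dataclass
class PumpCalibration:
    """Mapping from angular-speed setting (fraction of max ω) to peak flow.

    Carries the measured knots, a monotone interpolator, the minimum lift
    flow Q_min and the operating arc as metadata for the transfer simulator's
    timing model.
    """

    settings: np.ndarray
    angular_speeds: np.ndarray  # rad/s, may be NaN if unrecorded
    peak_flows: np.ndarray  # μl/s
    q_min_ul_s: float = DEFAULT_Q_MIN_UL_S
    operating_arc_deg: tuple[float, float] = DEFAULT_OPERATING_ARC
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.settings, dtype=float)
        q = np.asarray(self.peak_flows, dtype=float)
        if s.size < 2:
            raise CalibrationError("need at least 2 calibration points")
        if np.any(np.diff(s) <= 0) or np.any(np.diff(q) <= 0):
            raise CalibrationError(
                "calibration must be strictly increasing in setting and peak flow"
            )
        if np.any(s <= 0) or np.any(s > 1):
            raise CalibrationError("settings must lie in (0, 1]")
        arc = self.operating_arc_deg
        if not (0 <= arc[0] < arc[1] < 360):
            raise CalibrationError("operating arc must lie within [0°, 360°)")
        self._interp = PchipInterpolator(s, q, extrapolate=False)

    def peak_flow(self, setting: float) -> float:
        """Interpolated peak flow (μl/s); clamped to the knot range with a warning."""
        lo, hi = self.settings[0], self.settings[-1]
        if setting < lo or setting > hi:
            warnings.warn(
                f"setting {setting} outside calibrated range [{lo}, {hi}]; clamped",
                stacklevel=2,
            )
            setting = min(max(setting, lo), hi)
        return float(self._interp(setting))


def fit_calibration(
    points: pd.DataFrame | np.ndarray,
    q_min_ul_s: float = DEFAULT_Q_MIN_UL_S,
    operating_arc_deg: tuple[float, float] = DEFAULT_OPERATING_ARC,
) -> PumpCalibration:
    """Build a PumpCalibration from a table of (setting, [rad/s,] peak flow).

    Accepts a DataFrame with columns ``setting``, optional ``rad_per_s`` and
    ``peak_ul_per_s``, or a plain (n, 2) array of (setting, peak flow).
    """
    if isinstance(points, pd.DataFrame):
        s = points["setting"].to_numpy(dtype=float)
        q = points["peak_ul_per_s"].to_numpy(dtype=float)
        w = (
            points["rad_per_s"].to_numpy(dtype=float)
            if "rad_per_s" in points.columns
            else np.full(s.shape, np.nan)
        )
    else:
        arr = np.asarray(points, dtype=float)
        s, q = arr[:, 0], arr[:, 1]
        w = np.full(s.shape, np.nan)
    return PumpCalibration(
        settings=s,
        angular_speeds=w,
        peak_flows=q,
        q_min_ul_s=q_min_ul_s,
        operating_arc_deg=operating_arc_deg,
    )


def default_calibration() -> PumpCalibration:
    """The packaged four-knot calibration of the platform's rotary pump."""
    with resources.files("microlift.data").joinpath("pump_calibration.csv").open() as fh:
        return fit_calibration(pd.read_csv(fh))


@dataclass(frozen=True)
class FlowPulse:
    """A sampled Q(t) trace: times in s, flows in μl/s."""

    times: np.ndarray
    flows: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.flows, dtype=float)
        if t.size != q.size or t.size < 2:
            raise ValueError("pulse needs ≥2 matched samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if not np.all(np.isfinite(q)):
            raise ValueError("pulse flows must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "flows", q)

    @classmethod
    def from_csv(cls, path) -> "FlowPulse":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["q_ul_per_s"].to_numpy())


def reference_pulse() -> FlowPulse:
    """Packaged surrogate pulse: 56 μl/s peak shaped to draw 6.4 μl.

    The real waveform was recorded with an inline flow sensor; only its peak
    and integral are carried over here, the triangular shape is synthetic.
    """
    with resources.files("microlift.data").joinpath("pulse_56ulps.csv").open() as fh:
        return FlowPulse.from_csv(fh)


def pulse_volume(pulse: FlowPulse) -> float:
    """Trapezoidal integral of Q(t) → volume in μl."""
    return float(np.trapezoid(pulse.flows, pulse.times))


def lift_feasible(setting: float, calibration: PumpCalibration) -> bool:
    """True iff the setting's interpolated peak flow reaches Q_min."""
    return calibration.peak_flow(setting) >= calibration.q_min_ul_s
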