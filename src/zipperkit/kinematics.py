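"""Image-derived kinematic quantifications of fork-position time series.

Fork positions are lengths measured along the neurite from the moving
zippering/unzippering fork to a fixed landmark (the dorsal midline), so a
position series for a neighborhood is the length of neurite placed there
over developmental time.  Velocities are forward differences between
consecutive tracked timepoints, matching how time-lapse measurements are
reported; no smoothing or interpolation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PositionSeries",
    "VelocitySeries",
    "finite_difference_velocity",
    "percent_zippered",
    "acceleration_ratio",
    "window_displacement",
]

_NEIGHBORHOODS = ("anterior", "posterior")


@dataclass(frozen=True)
class PositionSeries:
    """Length of neurite placed in one neighborhood over time.

    ``times`` in minutes post fertilization, strictly increasing;
    ``positions`` in micrometers, nonnegative.
    """

    times: np.ndarray
    positions: np.ndarray
    neighborhood: str = "anterior"
    subject_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.size == 0 or t.size != p.size:
            raise ValueError("times and positions must be equal-length and nonempty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(p < 0) or not np.all(np.isfinite(p)) or not np.all(np.isfinite(t)):
            raise ValueError("positions must be finite and >= 0")
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ValueError(f"neighborhood must be one of {_NEIGHBORHOODS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)


@dataclass(frozen=True)
class VelocitySeries:
    """Forward-difference velocities over the intervals of a position series."""

    interval_start_times: np.ndarray
    velocities: np.ndarray
    method: str = "forward-difference"
    neighborhood: str = "anterior"
    subject_id: str = ""


def finite_difference_velocity(series: PositionSeries) -> VelocitySeries:
    """Forward-difference velocity v(t1) = (pos(t2) - pos(t1)) / (t2 - t1).

    For a posterior series the returned values are the positive magnitudes
    of the posterior-length decrease (unzippering velocities).
    """
    if series.times.size < 2:
        raise ValueError("need at least two points to form a velocity")
    dt = np.diff(series.times)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in position series")
    v = np.diff(series.positions) / dt
    if series.neighborhood == "posterior":
        v = -v
    return VelocitySeries(
        series.times[:-1], v, neighborhood=series.neighborhood, subject_id=series.subject_id
    )


def percent_zippered(series: PositionSeries, initial_relocating_length: float) -> np.ndarray:
    """Zippered length as a percentage of the initial relocating length.

    Values above 100% are reported as-is (measurement noise) with a
    warning rather than clipped.
    """
    if not initial_relocating_length > 0:
        raise ValueError("initial_relocating_length must be > 0")
    pct = 100.0 * series.positions / initial_relocating_length
    if np.any(pct > 100.0):
        warnings.warn(
            "percent zippered exceeds 100% at some timepoints (measurement noise?)",
            stacklevel=2,
        )
    return pct


def acceleration_ratio(
    vel: VelocitySeries,
    early_window: tuple[float, float],
    late_window: tuple[float, float],
) -> float:
    """Ratio of late-window mean velocity to early-window mean velocity.

    A ratio > 1 flags acceleration, the kinematic hallmark of a force
    imbalance (net adhesion gain) during zippering.  Windows are closed
    intervals over interval start times.
    """
    means = []
    for lo, hi in (early_window, late_window):
        mask = (vel.interval_start_times >= lo) & (vel.interval_start_times <= hi)
        if not np.any(mask):
            raise ValueError(f"window [{lo}, {hi}] contains no velocity samples")
        means.append(float(np.mean(vel.velocities[mask])))
    if means[0] == 0.0:
        raise ValueError("early-window mean velocity is zero; ratio undefined")
    return means[1] / means[0]


def window_displacement(series: PositionSeries, t_start: float, t_end: float) -> float:
    """Net length change between the samples nearest t_start and t_end (um).

    Window endpoints snap to the nearest sampled time (tracked series are
    sparse; timepoints are reported to within a few minutes).  For a
    posterior series the magnitude of the decrease is returned, so a
    balanced run has anterior gain equal to posterior loss.
    """
    if t_start >= t_end:
        raise ValueError("t_start must precede t_end")
    t = series.times
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("window endpoints fall outside the sampled time span")
    i0 = int(np.argmin(np.abs(t - t_start)))
    i1 = int(np.argmin(np.abs(t - t_end)))
    delta = float(series.positions[i1] - series.positions[i0])
    return -delta if series.neighborhood == "posterior" else delta
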