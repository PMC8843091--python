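"""Two-fork force-balance model of neurite shaft zippering.

A neurite shaft relocating between two fasciculated neighborhoods moves by
two concurrent processes: it *zippers* onto the target (anterior)
neighborhood at one fork and *unzippers* from the source (posterior)
neighborhood at the other.  At each fork two forces compete: adhesion ``S``
to the neighborhood, which favors attachment, and mechanical tension ``T``
on the free segment, which opposes it.  With friction constant ``eta`` and
approach angle ``theta`` between the neurite and the neighborhood, the fork
velocities are

    v_zip   = [S_anterior  - T_anterior  (1 - cos theta)] / eta
    v_unzip = [T_posterior (1 - cos theta) - S_posterior] / eta

so their sum obeys the combined force balance

    v_zip + v_unzip = (S_anterior - S_posterior)/eta
                      - (T_anterior - T_posterior)(1 - cos theta)/eta.

Only force-to-friction ratios are identifiable from velocities, so ``S`` and
``T`` are in arbitrary consistent units and ``S/eta``, ``T/eta`` carry
units of um/min.  If tension is uniform along the shaft (``delta T = 0``)
the summed velocity measures the differential adhesion ``delta S / eta``
directly, which is what :func:`infer_differential_adhesion` estimates from
tracked fork positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .kinematics import PositionSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ZipperParams",
    "AdhesionSchedule",
    "NeuriteState",
    "Trajectory",
    "fork_velocities",
    "combined_velocity",
    "equilibrium_residual",
    "simulate",
    "infer_differential_adhesion",
    "DifferentialAdhesionEstimate",
]


@dataclass(frozen=True)
class ZipperParams:
    """Mechanical state of the zipper model.

    Parameters
    ----------
    s_anterior, s_posterior
        Adhesion strength per unit length in the anterior (zippering) and
        posterior (unzippering) neighborhoods.  Nonnegative, arbitrary
        force units.
    t_anterior, t_posterior
        Mechanical tension on the neurite segment at each fork.
        Nonnegative, same units as ``s``.
    eta
        Friction constant (force·time/length), strictly positive.
    theta
        Approach angle of the neurite to the neighborhoods, radians in
        ``[0, pi]``.
    """

    s_anterior: float
    s_posterior: float
    t_anterior: float = 0.0
    t_posterior: float = 0.0
    eta: float = 1.0
    theta: float = math.pi / 2

    def __post_init__(self) -> None:
        vals = (
            self.s_anterior,
            self.s_posterior,
            self.t_anterior,
            self.t_posterior,
            self.eta,
            self.theta,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("zipper parameters must be finite")
        if self.eta <= 0:
            raise ValueError(f"friction constant eta must be > 0, got {self.eta}")
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError(f"approach angle theta must lie in [0, pi], got {self.theta}")
        for name in ("s_anterior", "s_posterior", "t_anterior", "t_posterior"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AdhesionSchedule:
    """Piecewise-linear time course of the anterior adhesion strength.

    Linear between breakpoints, constant outside; emulates a developmentally
    ramping adhesion (rising IgCAM expression in the target neighborhood).
    """

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if bp.size != vals.size or bp.size == 0:
            raise ValueError("breakpoints and values must be equal-length and nonempty")
        if bp.size > 1 and not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoint times must be strictly increasing")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("adhesion values must be finite and >= 0")
        object.__setattr__(self, "breakpoints", tuple(bp))
        object.__setattr__(self, "values", tuple(vals))

    def __call__(self, t: float) -> float:
        return float(np.interp(t, self.breakpoints, self.values))


@dataclass(frozen=True)
class NeuriteState:
    """Lengths of the relocating neurite at time ``t`` (minutes).

    ``l_anterior`` is the length zippered onto the anterior neighborhood,
    ``l_posterior`` the length still attached posteriorly, ``l_free`` the
    unattached transit segment between the forks.  All in micrometers.
    """

    t: float
    l_anterior: float
    l_posterior: float
    l_free: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.t, self.l_anterior, self.l_posterior, self.l_free)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("neurite state values must be finite")
        if min(self.l_anterior, self.l_posterior, self.l_free) < 0:
            raise ValueError("neurite lengths must be >= 0")

    @property
    def total_length(self) -> float:
        return self.l_anterior + self.l_free + self.l_posterior


@dataclass
class Trajectory:
    """Time-ordered sequence of :class:`NeuriteState` from a simulation."""

    states: list[NeuriteState]
    params_used: ZipperParams
    schedule: Optional[AdhesionSchedule] = None
    seed: Optional[int] = None
    midline_cap: Optional[float] = None

    def __post_init__(self) -> None:
        times = [s.t for s in self.states]
        if len(times) >= 2 and not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def l_anterior(self) -> np.ndarray:
        return np.array([s.l_anterior for s in self.states])

    @property
    def l_posterior(self) -> np.ndarray:
        return np.array([s.l_posterior for s in self.states])

    @property
    def l_free(self) -> np.ndarray:
        return np.array([s.l_free for s in self.states])

    def position_series(self, subject_id: str = "sim") -> tuple[PositionSeries, PositionSeries]:
        """Split into (anterior, posterior) :class:`PositionSeries`."""
        return (
            PositionSeries(self.times, self.l_anterior, "anterior", subject_id),
            PositionSeries(self.times, self.l_posterior, "posterior", subject_id),
        )


def fork_velocities(params: ZipperParams) -> tuple[float, float]:
    """Per-fork velocities ``(v_zip, v_unzip)`` in um/min.

    Adhesion drives each fork toward more zippering in its own
    neighborhood; tension transmitted around the fork at approach angle
    ``theta`` opposes it with the geometric factor ``(1 - cos theta)``.
    Signs: positive ``v_zip`` grows the anterior segment; positive
    ``v_unzip`` shrinks the posterior one.
    """
    geom = 1.0 - math.cos(params.theta)
    v_zip = (params.s_anterior - params.t_anterior * geom) / params.eta
    v_unzip = (params.t_posterior * geom - params.s_posterior) / params.eta
    return v_zip, v_unzip


def combined_velocity(params: ZipperParams) -> float:
    """Summed fork velocity ``(dS - dT (1 - cos theta)) / eta`` in um/min."""
    geom = 1.0 - math.cos(params.theta)
    ds = params.s_anterior - params.s_posterior
    dt_ = params.t_anterior - params.t_posterior
    return (ds - dt_ * geom) / params.eta


def equilibrium_residual(params: ZipperParams) -> float:
    """Signed force residual ``dS - dT (1 - cos theta)`` (force units).

    Zero exactly when the combined velocity vanishes, i.e. when adhesion
    and tension differences balance and net repositioning stops (the
    mechanistic account of zippering halting at the dorsal midline).
    """
    geom = 1.0 - math.cos(params.theta)
    return (params.s_anterior - params.s_posterior) - (
        params.t_anterior - params.t_posterior
    ) * geom


def simulate(
    params: ZipperParams,
    initial: NeuriteState,
    dt: float,
    t_end: float,
    schedule: Optional[AdhesionSchedule] = None,
    midline_cap: Optional[float] = None,
    conserve_length: bool = False,
) -> Trajectory:
    """Integrate the two-fork balance by explicit forward Euler steps.

    At each step the fork velocities are evaluated (re-reading
    ``s_anterior`` from ``schedule`` if given), zippering halts at
    ``midline_cap``, and lengths are clamped at zero.  With
    ``conserve_length`` the free segment absorbs the difference so that
    ``l_anterior + l_free + l_posterior`` stays constant, truncating the
    zippering step when the free segment would be exhausted.  Forward Euler
    is exact for piecewise-constant velocities and adequate for the
    piecewise-linear schedules used here at dt of order 1 min.
    """
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError("dt must be positive and finite")
    if not math.isfinite(t_end) or t_end <= initial.t:
        raise ValueError("t_end must exceed the initial time")
    if dt > t_end - initial.t:
        raise ValueError("dt larger than the integration window")
    if midline_cap is not None and midline_cap < 0:
        raise ValueError("midline_cap must be >= 0")

    total0 = initial.total_length
    states = [initial]
    t, l_a, l_p, l_f = initial.t, initial.l_anterior, initial.l_posterior, initial.l_free
    eps = 1e-9 * max(1.0, abs(t_end))
    while t < t_end - eps:
        step = min(dt, t_end - t)
        p = params
        if schedule is not None:
            p = replace(params, s_anterior=schedule(t))
        v_zip, v_unzip = fork_velocities(p)
        if midline_cap is not None and l_a >= midline_cap:
            v_zip = 0.0  # force balance reached at the cap: zippering halts
        new_a = l_a + v_zip * step
        new_p = l_p - v_unzip * step
        if midline_cap is not None and new_a > midline_cap:
            new_a = midline_cap
        if new_a < 0:
            logger.warning("l_anterior clamped at 0 at t=%.3f (overshoot)", t + step)
            new_a = 0.0
        if new_p < 0:
            logger.warning("l_posterior clamped at 0 at t=%.3f (overshoot)", t + step)
            new_p = 0.0
        if conserve_length:
            new_f = total0 - new_a - new_p
            if new_f < 0:
                # zippering outran the available free segment: truncate
                new_a = total0 - new_p
                new_f = 0.0
                logger.warning("zippering step truncated at t=%.3f (free segment exhausted)", t + step)
        else:
            new_f = l_f
        t = t + step
        l_a, l_p, l_f = new_a, new_p, new_f
        states.append(NeuriteState(t, l_a, l_p, l_f))
    return Trajectory(states, params, schedule=schedule, midline_cap=midline_cap)


@dataclass(frozen=True)
class DifferentialAdhesionEstimate:
    """Per-interval and aggregate estimates of ``(S_ant - S_post)/eta``.

    Valid under the uniform-tension assumption (``delta T = 0``), where the
    summed finite-difference fork velocity equals the differential adhesion
    per unit friction, in um/min.  ``direction`` reports the sign of the
    aggregate: "anterior" for net adhesion toward the anterior
    neighborhood, "posterior" for the reverse, "balanced" at zero.
    """

    interval_start_times: np.ndarray
    per_interval: np.ndarray
    aggregate: float
    direction: str
    theta: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "interval_start_times_min": [float(v) for v in self.interval_start_times],
            "per_interval_um_per_min": [float(v) for v in self.per_interval],
            "aggregate_um_per_min": float(self.aggregate),
            "direction": self.direction,
            "assumes_uniform_tension": True,
            "theta_rad": self.theta,
        }


def infer_differential_adhesion(
    anterior: PositionSeries,
    posterior: PositionSeries,
    theta: Optional[float] = None,
) -> DifferentialAdhesionEstimate:
    """Estimate differential adhesion per unit friction from fork tracks.

    For each interval shared by both series the summed finite-difference
    velocity ``(dL_a - dL_p)/dt`` is an estimate of ``dS/eta`` under the
    uniform-tension assumption; the aggregate is the mean over intervals.
    ``theta`` is recorded for provenance only — under ``delta T = 0`` the
    estimate does not depend on it.  Series on different time grids are
    intersected on common timestamps; intervals lacking either measurement
    are dropped with a log message.
    """
    if anterior.times.size < 2 or posterior.times.size < 2:
        raise ValueError("each series needs at least two time points")
    common = np.intersect1d(anterior.times, posterior.times)
    if common.size < 2:
        raise ValueError("series time grids share fewer than two timestamps; cannot align")
    dropped = anterior.times.size + posterior.times.size - 2 * common.size
    if dropped:
        logger.info("dropped %d unmatched timestamps when aligning series", dropped)
    a = anterior.positions[np.isin(anterior.times, common)]
    p = posterior.positions[np.isin(posterior.times, common)]
    dt_ = np.diff(common)
    per_interval = (np.diff(a) - np.diff(p)) / dt_
    aggregate = float(np.mean(per_interval))
    if aggregate > 0:
        direction = "anterior"
    elif aggregate < 0:
        direction = "posterior"
    else:
        direction = "balanced"
    return DifferentialAdhesionEstimate(common[:-1], per_interval, aggregate, direction, theta)
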