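"""Scalar morphometric quantifications on traced neurites and intensities.

The ratio and percentage formulas used to score neurite-placement
phenotypes: percent detachment of a defasciculated neurite, percent of the
distal neurite left in the source neighborhood, anterior/posterior reporter
enrichment, background-subtracted region intensities, the 3-D chiasm
(midline shift) length from section counts, minimum distance between
traced neurites, and penetrance of a scored defect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

__all__ = [
    "NeuriteTrace",
    "MorphometricRecord",
    "PenetranceResult",
    "arc_length",
    "percent_detachment",
    "percent_distal_in_posterior",
    "relative_enrichment",
    "background_subtracted_mean",
    "chiasm_length_3d",
    "min_distance",
    "penetrance",
]


@dataclass(frozen=True)
class NeuriteTrace:
    """Ordered 2-D/3-D polyline tracing a neurite segment (um)."""

    points: np.ndarray
    subject_id: str = ""
    neurite_label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] not in (2, 3):
            raise ValueError("trace needs >= 2 points of dimension 2 or 3")
        if not np.all(np.isfinite(pts)):
            raise ValueError("trace coordinates must be finite")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")
        object.__setattr__(self, "points", pts)


@dataclass
class MorphometricRecord:
    """Named scalar results for one subject, units recorded per key."""

    subject_id: str
    genotype: str = ""
    results: dict = field(default_factory=dict)  # name -> (value, unit)

    def add(self, name: str, value: float, unit: str) -> None:
        self.results[name] = (float(value), unit)


@dataclass(frozen=True)
class PenetranceResult:
    proportion: float
    percent: float
    n_defective: int
    n_total: int


def arc_length(trace: NeuriteTrace) -> float:
    """Polyline length: sum of consecutive point distances (um)."""
    return float(np.sum(np.linalg.norm(np.diff(trace.points, axis=0), axis=1)))


def percent_detachment(l_detached: float, l_total: float) -> float:
    """Detached length as % of total contact length: L_d * 100 / L_t.

    Zero for fully attached neurites.
    """
    if l_total <= 0:
        raise ValueError("total length must be > 0")
    if not 0 <= l_detached <= l_total:
        raise ValueError("detached length must lie in [0, total length]")
    return 100.0 * l_detached / l_total


def percent_distal_in_posterior(l_p: float, l_t: float) -> float:
    """Percent of the distal neurite placed posteriorly: (L_p / L_t) * 100."""
    if l_t <= 0:
        raise ValueError("total length must be > 0")
    if not 0 <= l_p <= l_t:
        raise ValueError("posterior length must lie in [0, total length]")
    return 100.0 * l_p / l_t


def relative_enrichment(i_anterior: float, i_posterior: float) -> float:
    """Anterior enrichment ratio I_a / I_p of band mean intensities."""
    if i_posterior <= 0:
        raise ValueError("posterior intensity must be > 0")
    if i_anterior < 0:
        raise ValueError("intensities must be >= 0")
    return i_anterior / i_posterior


def background_subtracted_mean(region_mean: float, reference_mean: float) -> float:
    """Region intensity subtracted from its reference (cell body) mean.

    Convention: returns ``reference_mean - region_mean`` (region subtracted
    *from* the reference); callers needing the opposite sign negate it.
    """
    if not (math.isfinite(region_mean) and math.isfinite(reference_mean)):
        raise ValueError("intensities must be finite")
    return reference_mean - region_mean


def chiasm_length_3d(n_slices: int, z_spacing_nm: float, d_xy_nm: float) -> float:
    """3-D midline-shift length l = sqrt(d_z^2 + d_xy^2) in nm.

    ``d_z = n_slices * z_spacing_nm`` is the span of sections containing
    the shift; ``d_xy_nm`` the in-plane distance between its endpoints.
    """
    if n_slices < 1 or int(n_slices) != n_slices:
        raise ValueError("n_slices must be a positive integer")
    if z_spacing_nm <= 0 or d_xy_nm < 0:
        raise ValueError("z_spacing_nm must be > 0 and d_xy_nm >= 0")
    d_z = n_slices * z_spacing_nm
    return math.hypot(d_z, d_xy_nm)


def min_distance(trace_a: NeuriteTrace, trace_b: NeuriteTrace) -> float:
    """Global minimum distance between two traced neurites (um).

    The exact polyline-polyline minimum, a deterministic stand-in for the
    manual shortest-perpendicular-gap measurement.  3-D traces are compared
    by exhaustive segment-pair distance; 2-D traces via exact geometric
    distance.  Zero when the traces intersect.
    """
    a, b = trace_a.points, trace_b.points
    if a.shape[1] != b.shape[1]:
        raise ValueError("traces must have the same dimensionality")
    if a.shape[1] == 2:
        return float(LineString(a).distance(LineString(b)))
    return min(
        _segment_distance_3d(a[i], a[i + 1], b[j], b[j + 1])
        for i in range(len(a) - 1)
        for j in range(len(b) - 1)
    )


def _segment_distance_3d(p1, p2, q1, q2) -> float:
    """Minimum distance between 3-D segments p1p2 and q1q2.

    The squared distance is a convex quadratic in the segment parameters
    (s, t) over the unit box, so the minimum is either the interior
    stationary point or lies on one of the four box edges; all candidates
    are evaluated exactly.
    """
    u, v, w0 = p2 - p1, q2 - q1, p1 - q1
    a, b, c = float(u @ u), float(u @ v), float(v @ v)
    d, e = float(u @ w0), float(v @ w0)

    def f(s: float, t: float) -> float:
        diff = w0 + s * u - t * v
        return float(diff @ diff)

    candidates = []
    denom = a * c - b * b
    if denom > 0:
        s0 = (b * e - c * d) / denom
        t0 = (a * e - b * d) / denom
        if 0.0 <= s0 <= 1.0 and 0.0 <= t0 <= 1.0:
            candidates.append((s0, t0))
    for s in (0.0, 1.0):  # edges s fixed: minimize over t
        t = min(max((e + s * b) / c, 0.0), 1.0) if c > 0 else 0.0
        candidates.append((s, t))
    for t in (0.0, 1.0):  # edges t fixed: minimize over s
        s = min(max((t * b - d) / a, 0.0), 1.0) if a > 0 else 0.0
        candidates.append((s, t))
    return math.sqrt(min(f(s, t) for s, t in candidates))


def penetrance(n_defective: int, n_total: int) -> PenetranceResult:
    """Fraction of scored animals displaying the defect, with n reported."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_defective <= n_total:
        raise ValueError("n_defective must lie in [0, n_total]")
    prop = n_defective / n_total
    return PenetranceResult(prop, 100.0 * prop, int(n_defective), int(n_total))
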