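"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library code paths (and networkx/shapely/
morphology routines) they are used to verify.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_betweenness(weights: np.ndarray, directed: bool = False) -> np.ndarray:
    """Normalized betweenness by exhaustive simple-path enumeration.

    For every ordered (or unordered) vertex pair, all simple paths are
    enumerated, shortest ones kept, and each interior vertex credited with
    its fraction of those shortest paths.  Feasible for n <= 8.
    """
    adj = weights > 0
    n = adj.shape[0]
    if not directed:
        adj = adj | adj.T
    np.fill_diagonal(adj, False)

    def all_paths(s: int, t: int):
        paths = []
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                paths.append(path)
                continue
            for nxt in range(n):
                if adj[node, nxt] and nxt not in path:
                    stack.append((nxt, path + [nxt]))
        return paths

    bc = np.zeros(n)
    pairs = (
        itertools.permutations(range(n), 2)
        if directed
        else itertools.combinations(range(n), 2)
    )
    for s, t in pairs:
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        best = [p for p in paths if len(p) == shortest]
        for p in best:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(best)
    norm = (n - 1) * (n - 2) * (0.5 if not directed else 1.0)
    return bc / norm


def chebyshev_gap(mask_a: np.ndarray, mask_b: np.ndarray) -> int:
    """Background gap between two masks: min Chebyshev pixel distance - 1."""
    pa = np.argwhere(mask_a)
    pb = np.argwhere(mask_b)
    d = np.abs(pa[:, None, :] - pb[None, :, :]).max(axis=2).min()
    return int(d) - 1


def brute_force_contact_pixels(
    mask_a: np.ndarray, mask_b: np.ndarray, k: int
) -> "tuple[set, set]":
    """Pixels of each mask within Chebyshev distance k of the other mask.

    Returns (pixels of b near a, pixels of a near b); their union is the
    merged contact patch at dilation radius k.
    """
    pa = np.argwhere(mask_a)
    pb = np.argwhere(mask_b)
    d = np.abs(pa[:, None, :] - pb[None, :, :]).max(axis=2)
    b_near_a = {tuple(p) for p in pb[(d <= k).any(axis=0)]}
    a_near_b = {tuple(p) for p in pa[(d <= k).any(axis=1)]}
    return b_near_a, a_near_b


def sampled_min_distance(a: np.ndarray, b: np.ndarray, step: float = 1e-4) -> float:
    """Minimum polyline distance by dense point sampling of both polylines.

    Points are sampled along each polyline at the given arclength step
    (segment endpoints included exactly) and measured against the other
    polyline's segments with the exact point-to-segment distance; taking
    the minimum over both directions bounds the true minimum to within
    O(step^2) near smooth interior minima and exactly at vertices.
    """

    def sample(poly: np.ndarray) -> np.ndarray:
        pts = []
        for p, q in zip(poly[:-1], poly[1:]):
            seg_len = np.linalg.norm(q - p)
            m = max(2, int(np.ceil(seg_len / step)) + 1)
            t = np.linspace(0.0, 1.0, m)[:, None]
            pts.append(p + t * (q - p))
        return np.vstack(pts)

    def point_to_segments(points: np.ndarray, poly: np.ndarray) -> float:
        best = np.inf
        for p, q in zip(poly[:-1], poly[1:]):
            u = q - p
            denom = float(u @ u)
            t = np.clip((points - p) @ u / denom, 0.0, 1.0)
            feet = p + t[:, None] * u
            best = min(best, float(np.linalg.norm(points - feet, axis=1).min()))
        return best

    return min(point_to_segments(sample(a), b), point_to_segments(sample(b), a))
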