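"""Douglas-Peucker characteristic-point extraction and compression ratio.

The Douglas-Peucker algorithm connects the end nodes of a curve with a
chord, finds the curve point farthest from that chord, and — if its
distance exceeds the tolerance ``epsilon`` — splits the curve there and
recurses on both halves, until every intermediate point lies within the
tolerance of its chord.  The retained points are the *characteristic
points* that anchor the diameter triangles downstream.

Distances are perpendicular distances to the infinite line through the
chord (the classic formulation); the clamped segment distance is available
via ``distance="segment"``.  Ties on the farthest point split at the lower
index so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "CompressionReport",
    "perpendicular_distance",
    "douglas_peucker",
    "compression_ratio",
]


def perpendicular_distance(point, seg_start, seg_end,
                           distance: Literal["line", "segment"] = "line") -> float:
    """Orthogonal distance from ``point`` to the chord ``seg_start→seg_end``.

    ``"line"`` measures to the infinite line through the chord; ``"segment"``
    clamps the foot of the perpendicular to the chord.  A degenerate chord
    (coincident ends) falls back to the point-to-point distance.
    """
    p = np.asarray(point, dtype=float)
    a = np.asarray(seg_start, dtype=float)
    b = np.asarray(seg_end, dtype=float)
    ab = b - a
    base = float(np.hypot(*ab))
    if base == 0.0:
        return float(np.hypot(*(p - a)))
    if distance == "line":
        cross = ab[0] * (p - a)[1] - ab[1] * (p - a)[0]
        return abs(cross) / base
    t = float(np.dot(p - a, ab)) / (base * base)
    t = min(1.0, max(0.0, t))
    return float(np.hypot(*(p - (a + t * ab))))


def douglas_peucker(curve: np.ndarray, epsilon: float,
                    distance: Literal["line", "segment"] = "line") -> np.ndarray:
    """Reduce a polyline to its characteristic points at tolerance ``epsilon``.

    Returns an ordered subset of the input rows that always contains both end
    nodes.  A chord is subdivided at its farthest point whenever that
    point's distance strictly exceeds ``epsilon``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    pts = np.asarray(curve, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("curve must be an (n>=2, 2) point array")

    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        a, b = pts[i], pts[j]
        seg = pts[i + 1:j]
        ab = b - a
        base = np.hypot(*ab)
        if base == 0.0:
            d = np.hypot(seg[:, 0] - a[0], seg[:, 1] - a[1])
        elif distance == "line":
            d = np.abs(ab[0] * (seg[:, 1] - a[1]) - ab[1] * (seg[:, 0] - a[0])) / base
        else:
            t = ((seg - a) @ ab) / (base * base)
            t = np.clip(t, 0.0, 1.0)
            feet = a + t[:, None] * ab
            d = np.hypot(*(seg - feet).T)
        k = int(np.argmax(d))            # argmax takes the lowest index on ties
        if d[k] > epsilon:
            split = i + 1 + k
            keep[split] = True
            stack.append((i, split))
            stack.append((split, j))
    return pts[keep]


@dataclass(frozen=True)
class CompressionReport:
    """Point-count bookkeeping for one simplified curve (or curve set)."""

    n_total: int
    n_kept: int

    def __post_init__(self):
        if not (1 <= self.n_kept <= self.n_total):
            raise ValueError("need 1 <= n_kept <= n_total")

    @property
    def dcr(self) -> float:
        return compression_ratio(self.n_total, self.n_kept)


def compression_ratio(n_total: int, n_kept: int) -> float:
    """Data compression ratio: the percentage of points removed.

    DCR = 100 · (N − n) / N for N input points and n characteristic points.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 1 <= n_kept <= n_total:
        raise ValueError("need 1 <= n_kept <= n_total")
    return 100.0 * (n_total - n_kept) / n_total
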