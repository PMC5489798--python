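"""Vessel diameter from characteristic points and contour points.

For each consecutive pair (N, P) of characteristic points on a centerline,
one contour point is selected on each side of the chord NP (M on one side,
K on the other).  Each triple forms a triangle whose sides

    a = |NP|,  b = |MP|,  c = |NM|

give the area by Heron's formula, A = sqrt(S(S−a)(S−b)(S−c)) with
S = (a+b+c)/2 the half-perimeter, and the height from the contour point
onto the chord, h = 2A/a.  The local vessel diameter is the sum of the two
heights h1 + h2 — one triangle per side — which is independent of where
the chord sits between the two edges as long as it is parallel to them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .snake import SnakeContour

__all__ = [
    "TriangleMeasure",
    "DiameterMeasurement",
    "side_lengths",
    "heron_area",
    "triangle_height",
    "select_contour_points",
    "measure_segment",
    "measure_vessel",
]

_HERON_TOL = 1e-9


@dataclass(frozen=True)
class TriangleMeasure:
    """One triangle (N, P, M) with its Heron bookkeeping."""

    N: tuple[float, float]
    P: tuple[float, float]
    M: tuple[float, float]
    a: float            # |NP|, the base
    b: float            # |MP|
    c: float            # |NM|
    s_half: float       # half-perimeter
    area: float
    height: float       # from M onto NP; equals 2*area/a


@dataclass(frozen=True)
class DiameterMeasurement:
    """Diameter at one characteristic-point segment: h1 + h2."""

    N: tuple[float, float]
    P: tuple[float, float]
    M_up: tuple[float, float]
    M_down: tuple[float, float]
    h1: float
    h2: float
    segment_index: int = 0

    @property
    def diameter(self) -> float:
        return self.h1 + self.h2


def side_lengths(N, P, M) -> tuple[float, float, float]:
    """Euclidean side lengths (a, b, c) = (|NP|, |MP|, |NM|)."""
    N = np.asarray(N, float)
    P = np.asarray(P, float)
    M = np.asarray(M, float)
    a = float(np.hypot(*(N - P)))
    b = float(np.hypot(*(M - P)))
    c = float(np.hypot(*(N - M)))
    return a, b, c


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from side lengths via Heron's formula.

    The radicand S(S−a)(S−b)(S−c) can dip slightly negative for
    near-degenerate triangles under floating point; magnitudes within the
    1e−9 guard are clamped to zero, gross triangle-inequality violations
    raise.
    """
    if min(a, b, c) < 0:
        raise ValueError("side lengths must be non-negative")
    s = (a + b + c) / 2.0
    excess = max(a, b, c) - (a + b + c - max(a, b, c))
    if excess > _HERON_TOL * max(1.0, a + b + c):
        raise ValueError(
            f"sides ({a}, {b}, {c}) grossly violate the triangle inequality"
        )
    rad = s * (s - a) * (s - b) * (s - c)
    if rad < 0:
        rad = 0.0
    return math.sqrt(rad)


def triangle_height(area: float, a: float) -> float:
    """Height onto the base of length ``a``: h = 2A/a (from A = h·a/2)."""
    if a <= 0:
        raise ValueError("base length must be positive")
    return 2.0 * area / a


def _foot_params(N: np.ndarray, P: np.ndarray, pts: np.ndarray):
    """Per point: signed side of line NP and foot parameter t along NP."""
    d = P - N
    rel = pts - N
    cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
    t = rel @ d / float(d @ d)
    return cross, t


def select_contour_points(N, P, contour: SnakeContour | np.ndarray):
    """Pick one contour point per side of the chord NP.

    Side membership is the sign of the cross product (P−N)×(M−N); points
    exactly on the line belong to neither side.  On each side, candidates
    whose perpendicular foot falls within the segment NP are preferred, the
    winner being the one whose foot is nearest the segment midpoint; a side
    with no in-segment foot falls back to its point with foot nearest the
    midpoint overall.  Returns (M_up, M_down) as float pairs, or None (with
    a warning) when a side has no points at all.
    """
    N = np.asarray(N, float)
    P = np.asarray(P, float)
    if np.allclose(N, P):
        raise ValueError("characteristic points N and P coincide")
    pts = contour.points if isinstance(contour, SnakeContour) else \
        np.asarray(contour, float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("contour is empty")
    cross, t = _foot_params(N, P, pts)

    def pick(side_mask: np.ndarray):
        if not side_mask.any():
            return None
        idx = np.flatnonzero(side_mask)
        score = np.abs(t[idx] - 0.5)
        inseg = (t[idx] >= 0.0) & (t[idx] <= 1.0)
        pool = idx[inseg] if inseg.any() else idx
        pool_score = score[inseg] if inseg.any() else score
        return tuple(pts[pool[int(np.argmin(pool_score))]])

    m_up = pick(cross > 0)
    m_down = pick(cross < 0)
    if m_up is None or m_down is None:
        warnings.warn("contour lies entirely on one side of the chord NP; "
                      "measurement skipped", stacklevel=2)
        return None
    return m_up, m_down


def _triangle(N, P, M) -> TriangleMeasure:
    a, b, c = side_lengths(N, P, M)
    A = heron_area(a, b, c)
    return TriangleMeasure(N=tuple(N), P=tuple(P), M=tuple(M), a=a, b=b, c=c,
                           s_half=(a + b + c) / 2.0, area=A,
                           height=triangle_height(A, a))


def measure_segment(N, P, contour: SnakeContour | np.ndarray,
                    segment_index: int = 0) -> DiameterMeasurement | None:
    """Diameter h1 + h2 at the chord NP, or None when no point pair exists."""
    sel = select_contour_points(N, P, contour)
    if sel is None:
        return None
    m_up, m_down = sel
    N = np.asarray(N, float)
    P = np.asarray(P, float)
    t1 = _triangle(N, P, np.asarray(m_up))
    t2 = _triangle(N, P, np.asarray(m_down))
    return DiameterMeasurement(N=tuple(N), P=tuple(P), M_up=tuple(m_up),
                               M_down=tuple(m_down), h1=t1.height,
                               h2=t2.height, segment_index=segment_index)


def measure_vessel(characteristic_points: np.ndarray,
                   contour: SnakeContour | np.ndarray,
                   ) -> tuple[list[DiameterMeasurement], list[int]]:
    """One diameter per consecutive characteristic-point pair.

    Returns (measurements, skipped_segment_indices); a segment is skipped
    when no contour point exists on one of its sides.
    """
    cp = np.asarray(characteristic_points, float).reshape(-1, 2)
    if len(cp) < 2:
        raise ValueError("need at least 2 characteristic points")
    out: list[DiameterMeasurement] = []
    skipped: list[int] = []
    for k in range(len(cp) - 1):
        m = measure_segment(cp[k], cp[k + 1], contour, segment_index=k)
        if m is None:
            skipped.append(k)
        else:
            out.append(m)
    return out, skipped
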