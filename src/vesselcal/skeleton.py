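"""Skeleton-pixel classification and centerline branch tracing.

Every foreground pixel of a thinned skeleton is classified by the number of
active pixels among its 8 neighbors (a 3×3 sliding mask minus the center):
exactly 1 → endpoint, exactly 2 → inner point, more than 2 → bifurcation
point.  Pixels with no active neighbor get an explicit ``isolated`` class
(thinning noise) and are excluded from measurement.

Branches are the maximal inner-point chains running terminal-to-terminal,
where a terminal is an endpoint or a bifurcation pixel.  Thinning often
leaves 2-pixel junction clusters; adjacent bifurcation pixels are merged
into one junction node whose representative is the lexicographically
smallest (row, col) member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PixelClass",
    "SkeletonPoints",
    "CenterlineBranch",
    "neighbor_counts",
    "classify_pixel",
    "detect_points",
    "trace_branches",
]

PixelClass = str  # one of "endpoint" | "inner" | "bifurcation" | "isolated"

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)
_EIGHT = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_S8 = np.ones((3, 3), dtype=np.uint8)


def neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    """Count active 8-neighbors of every pixel (3×3 mask minus center)."""
    sk = np.asarray(skeleton, dtype=np.uint8)
    return ndimage.convolve(sk, _NEIGHBOR_KERNEL, mode="constant", cval=0)


def _classify_counts(counts: int) -> PixelClass:
    if counts == 0:
        return "isolated"
    if counts == 1:
        return "endpoint"
    if counts == 2:
        return "inner"
    return "bifurcation"


def classify_pixel(skeleton: np.ndarray, coord: tuple[int, int]) -> PixelClass:
    """Classify one foreground skeleton pixel by its active-neighbor count."""
    sk = np.asarray(skeleton)
    r, c = coord
    if not sk[r, c]:
        raise ValueError(f"pixel {coord} is not on the skeleton foreground")
    n = 0
    h, w = sk.shape
    for dr, dc in _EIGHT:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and sk[rr, cc]:
            n += 1
    return _classify_counts(n)


@dataclass
class SkeletonPoints:
    """Partition of skeleton foreground pixels into the four classes."""

    endpoints: np.ndarray       # (n, 2) int arrays of (row, col)
    inner: np.ndarray
    bifurcations: np.ndarray
    isolated: np.ndarray

    def total(self) -> int:
        return sum(len(a) for a in
                   (self.endpoints, self.inner, self.bifurcations, self.isolated))


def detect_points(skeleton: np.ndarray) -> SkeletonPoints:
    """Partition all skeleton pixels into endpoint/inner/bifurcation/isolated.

    The four coordinate lists are disjoint and their union is exactly the
    foreground; each list is sorted in row-major order.
    """
    sk = np.asarray(skeleton, dtype=np.uint8)
    counts = neighbor_counts(sk)
    fg = sk.astype(bool)

    def _coords(cond: np.ndarray) -> np.ndarray:
        rc = np.argwhere(fg & cond)
        return rc.reshape(-1, 2)

    return SkeletonPoints(
        endpoints=_coords(counts == 1),
        inner=_coords(counts == 2),
        bifurcations=_coords(counts > 2),
        isolated=_coords(counts == 0),
    )


@dataclass
class CenterlineBranch:
    """Ordered skeleton-pixel chain between two terminals.

    ``points`` runs from the start terminal to the end terminal; interior
    points are all inner-class.  ``start_node``/``end_node`` give the
    junction-cluster representative when the terminal is a bifurcation
    pixel (the pixel itself otherwise).
    """

    points: np.ndarray          # (n, 2) int, consecutive entries 8-adjacent
    start_kind: PixelClass
    end_kind: PixelClass
    start_node: tuple[int, int] = field(default=None)  # type: ignore[assignment]
    end_node: tuple[int, int] = field(default=None)    # type: ignore[assignment]
    closed: bool = False

    def __len__(self) -> int:
        return len(self.points)


def _junction_clusters(bif_mask: np.ndarray) -> dict[tuple[int, int], tuple[int, int]]:
    """Map each bifurcation pixel to its 8-connected cluster representative."""
    labels, n = ndimage.label(bif_mask, structure=_S8)
    rep: dict[tuple[int, int], tuple[int, int]] = {}
    if n == 0:
        return rep
    coords = np.argwhere(labels > 0)
    by_label: dict[int, list[tuple[int, int]]] = {}
    for r, c in coords:
        by_label.setdefault(labels[r, c], []).append((int(r), int(c)))
    for members in by_label.values():
        anchor = min(members)
        for m in members:
            rep[m] = anchor
    return rep


def trace_branches(skeleton: np.ndarray) -> list[CenterlineBranch]:
    """Trace every centerline branch of a 1-px skeleton, deterministically.

    Walks from each terminal (endpoint or bifurcation pixel, visited in
    row-major order with neighbors scanned row-major) through inner pixels
    until another terminal is met.  Every inner pixel ends up in exactly one
    branch.  Pure cycles with no terminal are emitted as closed branches with
    a warning.  Output is sorted by terminal coordinates.
    """
    sk = np.asarray(skeleton, dtype=np.uint8)
    h, w = sk.shape
    counts = neighbor_counts(sk)
    fg = sk.astype(bool)
    is_inner = fg & (counts == 2)
    is_terminal = fg & ((counts == 1) | (counts > 2))
    rep = _junction_clusters(fg & (counts > 2))

    def kind_of(p: tuple[int, int]) -> PixelClass:
        return _classify_counts(int(counts[p]))

    def node_of(p: tuple[int, int]) -> tuple[int, int]:
        return rep.get(p, p)

    def nbrs(p: tuple[int, int]):
        r, c = p
        for dr, dc in _EIGHT:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and fg[rr, cc]:
                yield (rr, cc)

    visited_edges: set[frozenset] = set()
    inner_used = np.zeros_like(fg)
    branches: list[CenterlineBranch] = []

    terminals = [tuple(p) for p in np.argwhere(is_terminal)]
    for t in terminals:
        for n0 in nbrs(t):
            edge = frozenset((t, n0))
            if edge in visited_edges:
                continue
            if is_terminal[n0] and node_of(t) == node_of(n0):
                # internal edge of one junction cluster, not a branch
                visited_edges.add(edge)
                continue
            visited_edges.add(edge)
            path = [t, n0]
            prev, cur = t, n0
            while is_inner[cur]:
                inner_used[cur] = True
                nxt = None
                for cand in nbrs(cur):
                    if cand != prev:
                        nxt = cand
                        break
                if nxt is None:     # dangling inner pixel (shouldn't occur)
                    break
                visited_edges.add(frozenset((cur, nxt)))
                path.append(nxt)
                prev, cur = cur, nxt
            end = path[-1]
            branches.append(CenterlineBranch(
                points=np.array(path, dtype=int),
                start_kind=kind_of(t), end_kind=kind_of(end),
                start_node=node_of(t), end_node=node_of(end),
            ))

    # pure cycles: inner pixels never reached from any terminal
    leftover = np.argwhere(is_inner & ~inner_used)
    seen = set()
    for r, c in leftover:
        p0 = (int(r), int(c))
        if p0 in seen:
            continue
        warnings.warn("skeleton contains a closed loop with no terminal; "
                      "emitting it as a closed branch", stacklevel=2)
        path = [p0]
        seen.add(p0)
        prev, cur = None, p0
        while True:
            nxt = None
            for cand in nbrs(cur):
                if cand != prev and cand not in seen:
                    nxt = cand
                    break
            if nxt is None:
                break
            path.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        path.append(p0)  # close the loop
        branches.append(CenterlineBranch(
            points=np.array(path, dtype=int),
            start_kind="inner", end_kind="inner",
            start_node=p0, end_node=p0, closed=True,
        ))

    branches.sort(key=lambda b: (tuple(b.points[0]), tuple(b.points[-1])))
    return branches
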