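"""Active-contour (snake) vessel-edge detection.

A snake is an ordered point chain v(s) = (x(s), y(s)) that deforms to
minimize

    E_snake = Σ_i  E_cont(i) + E_curv(i) + E_ext(i)

where the continuity term penalizes uneven point spacing (elasticity
weight ``alpha``), the curvature term penalizes bending via the discrete
second difference (rigidity weight ``beta``), and the external term

    E_ext = −gamma · |∇(G_sigma ∗ I)|²

pulls points toward strong image gradients, i.e. vessel edges.  The
minimizer is the greedy discrete local search of Williams & Shah: each
sweep moves every point to the position in its (2·search_radius+1)²
neighborhood that minimizes that point's own energy terms (the local rule
that lets a smooth contour contract across flat image regions).  A sweep
whose net effect fails to lower the *total* contour energy is rolled back
and the search moves to a finer step size, so the recorded per-sweep
energy trace is non-increasing by construction; iteration stops when no
step size can improve the total or ``max_iterations`` is reached.

By default the continuity term uses the mean-spacing form
``alpha · (d̄ − |v_i − v_{i−1}|)²`` (d̄ the mean inter-point spacing), which
keeps points evenly distributed without collapsing the contour; the raw
first-difference form ``alpha · |v_i − v_{i−1}|²`` is available with
``continuity="raw"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours
from skimage.morphology import dilation, disk

__all__ = [
    "SnakeParams",
    "SnakeContour",
    "external_energy_field",
    "sample_field",
    "internal_energy",
    "total_energy",
    "evolve_snake",
    "initialize_vessel_contour",
    "circular_contour",
]


@dataclass(frozen=True)
class SnakeParams:
    """Weights and controls of the snake energy and its greedy minimizer."""

    alpha: float = 1.0          # elasticity weight (continuity term)
    beta: float = 1.0           # rigidity weight (curvature term)
    gamma: float = 1.2          # external-force weight
    sigma: float = 1.0          # Gaussian smoothing scale, pixels
    max_iterations: int = 200   # greedy sweeps, shared across the step schedule
    search_radius: int = 1      # half-width of the per-point search window
    continuity: Literal["mean_spacing", "raw"] = "mean_spacing"
    # coarse-to-fine move sizes: once no whole-pixel move improves the
    # energy, the search window shrinks so points can settle on edges that
    # fall between pixel centers
    step_schedule: tuple[float, ...] = (1.0, 0.5, 0.25)

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.sigma) < 0:
            raise ValueError("alpha, beta, gamma, sigma must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")


@dataclass
class SnakeContour:
    """Ordered subpixel contour points in (row, col), optionally closed."""

    points: np.ndarray
    closed: bool = True
    energy_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 3:
            raise ValueError("a snake contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)


def external_energy_field(image: np.ndarray, sigma: float = 1.0,
                          gamma: float = 1.2) -> np.ndarray:
    """Per-pixel external energy −gamma·|∇(G_sigma ∗ I)|² (≤ 0 everywhere).

    The image is smoothed by a Gaussian of scale ``sigma`` (0 = no
    smoothing) and the gradient taken by central differences.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    smoothed = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    gr, gc = np.gradient(smoothed)
    return -gamma * (gr * gr + gc * gc)


def sample_field(fieldgrid: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a 2-D field at subpixel (row, col) points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return ndimage.map_coordinates(fieldgrid, pts.T, order=1, mode="nearest")


def _spacings(pts: np.ndarray, closed: bool) -> np.ndarray:
    diffs = np.diff(pts, axis=0)
    if closed:
        diffs = np.vstack([diffs, pts[:1] - pts[-1:]])
    return np.hypot(diffs[:, 0], diffs[:, 1])


def _curvature_sq(pts: np.ndarray, closed: bool) -> np.ndarray:
    if closed:
        second = np.roll(pts, 1, axis=0) - 2 * pts + np.roll(pts, -1, axis=0)
        return np.einsum("ij,ij->i", second, second)
    out = np.zeros(len(pts))
    if len(pts) >= 3:
        second = pts[:-2] - 2 * pts[1:-1] + pts[2:]
        out[1:-1] = np.einsum("ij,ij->i", second, second)
    return out


def internal_energy(contour: SnakeContour, index: int,
                    params: SnakeParams) -> tuple[float, float]:
    """(E_cont, E_curv) of one contour point under ``params``.

    E_cont uses the backward first difference |v_i − v_{i−1}| (mean-spacing
    or raw form per ``params.continuity``); E_curv uses the second
    difference |v_{i−1} − 2 v_i + v_{i+1}|².  On open contours the first
    point has no continuity term and end points no curvature term.
    """
    pts = contour.points
    n = len(pts)
    if not 0 <= index < n:
        raise IndexError(f"point index {index} out of range for {n} points")
    sp = _spacings(pts, contour.closed)
    dbar = sp.mean()
    if contour.closed:
        s_i = sp[index - 1] if index > 0 else sp[-1]
    else:
        s_i = sp[index - 1] if index > 0 else None
    if s_i is None:
        e_cont = 0.0
    elif params.continuity == "mean_spacing":
        e_cont = params.alpha * (dbar - s_i) ** 2
    else:
        e_cont = params.alpha * s_i ** 2
    e_curv = params.beta * float(_curvature_sq(pts, contour.closed)[index])
    return float(e_cont), float(e_curv)


def total_energy(pts: np.ndarray, closed: bool, params: SnakeParams,
                 ext: np.ndarray) -> float:
    """Total snake energy for explicit points and pre-sampled external values."""
    sp = _spacings(pts, closed)
    if params.continuity == "mean_spacing":
        e_cont = params.alpha * np.sum((sp - sp.mean()) ** 2)
    else:
        e_cont = params.alpha * np.sum(sp ** 2)
    e_curv = params.beta * np.sum(_curvature_sq(pts, closed))
    return float(e_cont + e_curv + np.sum(ext))


def evolve_snake(init: SnakeContour, image: np.ndarray, params: SnakeParams,
                 fieldgrid: np.ndarray | None = None) -> SnakeContour:
    """Run the greedy minimizer from ``init`` on ``image``.

    Each sweep computes, for every point simultaneously, the position in
    its (2·search_radius+1)² window that minimizes that point's own energy
    terms (continuity to its predecessor, curvature, external energy; the
    mean spacing d̄ and the neighbors are frozen at the sweep start).  The
    resulting collective displacement is applied with a backtracking line
    search (full step, then halved) and kept only when it strictly lowers
    the total contour energy; otherwise the move size is refined through
    ``step_schedule``.  The returned ``energy_trace`` — initial energy
    first, then one entry per accepted sweep — is therefore non-increasing
    by construction.
    """
    if fieldgrid is None:
        fieldgrid = external_energy_field(image, params.sigma, params.gamma)
    h, w = fieldgrid.shape
    pts = np.asarray(init.points, dtype=float).copy()
    if np.any(pts < -0.5) or np.any(pts[:, 0] > h - 0.5) or np.any(pts[:, 1] > w - 0.5):
        raise ValueError("initial contour lies outside the image bounds")
    n = len(pts)
    if n < 3:
        raise ValueError("contour degenerated below 3 points")
    closed = init.closed

    r = params.search_radius
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    base_offsets = np.stack([dr.ravel(), dc.ravel()], axis=1).astype(float)

    alpha, beta = params.alpha, params.beta
    mean_form = params.continuity == "mean_spacing"
    ext = sample_field(fieldgrid, pts)
    energy = total_energy(pts, closed, params, ext)
    trace = [energy]

    sweeps_left = params.max_iterations
    for step in params.step_schedule:
        offsets = base_offsets * step          # includes the null move
        improving = True
        while improving and sweeps_left > 0:
            sweeps_left -= 1
            dbar = float(_spacings(pts, closed).mean())
            prev_pts = np.roll(pts, 1, axis=0)
            next_pts = np.roll(pts, -1, axis=0)
            if not closed:
                # head point has no predecessor: measure continuity forward
                prev_pts[0] = next_pts[0]

            cands = pts[:, None, :] + offsets[None, :, :]    # (n, K, 2)
            cands[..., 0] = np.clip(cands[..., 0], 0.0, h - 1.0)
            cands[..., 1] = np.clip(cands[..., 1], 0.0, w - 1.0)
            flat = cands.reshape(-1, 2)
            cand_ext = sample_field(fieldgrid, flat).reshape(n, -1)

            s = np.hypot(cands[..., 0] - prev_pts[:, None, 0],
                         cands[..., 1] - prev_pts[:, None, 1])
            e_local = alpha * ((dbar - s) ** 2 if mean_form else s * s)
            second_r = prev_pts[:, None, 0] - 2 * cands[..., 0] + next_pts[:, None, 0]
            second_c = prev_pts[:, None, 1] - 2 * cands[..., 1] + next_pts[:, None, 1]
            curv = second_r ** 2 + second_c ** 2
            if not closed:
                curv[0] = 0.0
                curv[-1] = 0.0
            e_local += beta * curv + cand_ext
            best = np.argmin(e_local, axis=1)
            proposals = cands[np.arange(n), best]
            delta = proposals - pts
            if not np.any(delta):
                break                           # refine the step size

            accepted = False
            lam = 1.0
            while lam >= 0.125:
                trial = pts + lam * delta
                trial[:, 0] = np.clip(trial[:, 0], 0.0, h - 1.0)
                trial[:, 1] = np.clip(trial[:, 1], 0.0, w - 1.0)
                trial_ext = sample_field(fieldgrid, trial)
                e = total_energy(trial, closed, params, trial_ext)
                if e < energy - 1e-12:
                    pts, ext, energy = trial, trial_ext, e
                    trace.append(energy)
                    accepted = True
                    break
                lam /= 2.0
            if not accepted:
                improving = False               # refine the step size

    return SnakeContour(points=pts, closed=closed, energy_trace=trace)


def _signed_area_xy(pts: np.ndarray) -> float:
    """Shoelace area in right-handed coords (x = col, y = −row)."""
    x, y = pts[:, 1], -pts[:, 0]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _resample_closed(pts: np.ndarray, spacing: float) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n = max(8, int(round(total / spacing)))
    s = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(s, arc, closed[:, 0])
    out[:, 1] = np.interp(s, arc, closed[:, 1])
    return out


def initialize_vessel_contour(mask: np.ndarray, branch, margin: int = 2,
                              spacing: float = 2.5) -> SnakeContour:
    """Closed initial contour around the vessel region a branch belongs to.

    Takes the 8-connected foreground component of ``mask`` containing the
    branch, dilates it by a disk of radius ``margin`` (0 = the boundary
    itself), extracts the subpixel outer boundary and resamples it to
    roughly uniform ``spacing``.  Points are ordered counterclockwise in
    conventional (x right, y up) terms.
    """
    m = np.asarray(mask).astype(bool)
    bpts = np.asarray(branch.points if hasattr(branch, "points") else branch,
                      dtype=int).reshape(-1, 2)
    labels, nlab = ndimage.label(m, structure=np.ones((3, 3), int))
    on = labels[bpts[:, 0], bpts[:, 1]]
    on = on[on > 0]
    if nlab == 0 or on.size == 0:
        raise ValueError("branch does not lie on any mask foreground component")
    lab = np.bincount(on).argmax()
    region = labels == lab
    if margin > 0:
        region = dilation(region, disk(int(round(margin))))
    contours = find_contours(region.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found around the branch region")
    boundary = max(contours, key=len)
    if np.allclose(boundary[0], boundary[-1]):
        boundary = boundary[:-1]
    pts = _resample_closed(boundary, spacing)
    if _signed_area_xy(pts) < 0:
        pts = pts[::-1].copy()
    return SnakeContour(points=pts, closed=True)


def circular_contour(center: tuple[float, float], radius: float,
                     n_points: int = 24) -> SnakeContour:
    """Closed circle of ``n_points``, counterclockwise, for initialization."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    pts = np.stack([center[0] - radius * np.sin(t),
                    center[1] + radius * np.cos(t)], axis=1)
    return SnakeContour(points=pts, closed=True)
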