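# Methods

`vesselcal` measures the caliber of retinal blood vessels in fundus images.
The chain is: grayscale reduction → threshold binarization → thinning →
skeleton-point classification and branch tracing → Douglas-Peucker
characteristic points → active-contour (snake) edge detection → Heron
triangle-height diametry → agreement statistics. This note records the
model choices, the defaults and why, the numerical decisions, and what the
synthetic phantoms do and do not demonstrate.

## Coordinates and images

All image grids are row-major, origin top-left, 0-based `(row, col)`;
subpixel coordinates are floats in the same frame. Intensities live in
[0, 255] for integer images and [0, 1] for unit-scaled float images.
Lengths are pixels throughout; no micrometer conversion is attempted
because the conversion factor is camera-specific.

## Binarization

A pixel is vessel iff its intensity strictly exceeds the threshold S
(`bright_vessels`, the convention for hand-labeled vessel maps) or is
strictly below it (`dark_vessels`, for raw fundus photographs where blood
absorbs light). Pixels exactly equal to S map to background in both
polarities: the strict inequalities leave the tie undefined, and
background is the conservative assignment. `threshold="auto"` (the
default) selects S by Otsu's criterion, which is deterministic and needs
no tuning; the green channel is the default plane for color input because
it carries the highest vessel contrast in fundus photography.

## Thinning

Zhang–Suen two-subiteration parallel thinning (via scikit-image) erodes
outer pixel layers until no layer can be removed. The parallel scheme can
leave a full 2×2 block where two vessels cross in an X; a cleanup pass
deletes pixels from such blocks one at a time, only when the pixel's
foreground neighbors remain mutually 8-connected without it (checked by
explicit adjacency, not the ring crossing number, which is conservative at
diagonal contacts). The published skeleton contract is therefore: subset
of the foreground, no full 2×2 block, 8-connected component count
preserved.

## Skeleton points and branches

A skeleton pixel with exactly 1 active 8-neighbor is an endpoint, 2 an
inner point, more than 2 a bifurcation. Pixels with no neighbor get an
explicit `isolated` class and are excluded from measurement rather than
silently mislabeled. Thinning often produces 2-pixel junction clusters;
adjacent bifurcation pixels are merged into one junction node represented
by the lexicographically smallest member. Branches run
terminal-to-terminal through inner pixels, traced in row-major order so
output is reproducible; pure cycles are emitted as closed branches with a
warning. Diameters are only measured on branch interiors — how close to a
junction a measurement remains meaningful is not defined by the method, so
we stay off the junctions entirely.

## Characteristic points (Douglas-Peucker)

The chord between a curve's end nodes is split recursively at the farthest
point whenever its distance exceeds the tolerance ε, with ties split at
the lower index. Distance is measured to the infinite line through the
chord (the classic construction); the clamped segment distance is
available behind a flag. Default ε = 1.0 px: at 1 px the simplification
tracks the rasterized centerline within its own quantization noise, and
the useful range in practice is roughly 0.5–2 px. The data compression
ratio is reported as DCR = 100·(N−n)/N for N input and n kept points.

## Snake edge detection

Energy terms per contour point v_i:

* continuity `α(d̄ − |v_i − v_{i−1}|)²` with d̄ the mean inter-point
  spacing — keeps points evenly spread without collapsing the contour
  (the raw `α|v_i − v_{i−1}|²` form is available via `continuity="raw"`);
* curvature `β|v_{i−1} − 2v_i + v_{i+1}|²`;
* external `−γ|∇(G_σ ∗ I)|²`, the negative squared gradient magnitude of
  the Gaussian-smoothed image, sampled bilinearly at subpixel positions.

Defaults α = 1.0, β = 1.0, γ = 1.2, σ = 1.0 px. With intensity contrasts
of order 100, γ|∇|² at an edge is O(10³) while internal terms are O(1), so
edges win wherever a gradient exists and the internal terms only govern
behavior in flat regions; σ = 1 px keeps the two gradient ridges of
vessels as narrow as 3 px separable.

**Minimizer.** Each sweep computes, for every point simultaneously, the
position in its (2·search_radius+1)² window minimizing that point's own
three terms, with neighbors and d̄ frozen at the sweep start. The
collective displacement is then applied through a backtracking line search
(λ = 1, 1/2, 1/4, 1/8) and kept only if it strictly lowers the *total*
contour energy; otherwise the move size is refined through the step
schedule (1, 0.5, 0.25 px) and finally the run stops. Two failure modes
motivated this design over the more obvious alternatives:

* accepting single-point moves only when they lower the total energy can
  never contract a smooth contour across a flat-gradient gap — an inward
  move lowers the moved point's curvature term but raises its neighbors'
  by more — so an enclosing contour would never reach an edge beyond the
  gradient's reach;
* accepting single-point moves on their local terms alone (the textbook
  greedy rule) does contract, but sequential updates jag the contour and
  can raise the total energy within a sweep.

The collective update inherits the contraction of the local rule while the
line-search acceptance makes the recorded per-sweep energy trace
non-increasing by construction. The sub-pixel step refinements matter
because an image edge generally falls between pixel centers: a whole-pixel
search starting from half-pixel boundary coordinates would systematically
miss integer-positioned gradient ridges by 0.5 px per side.

The point spacing sets the contraction range: a contour can only shrink
through a flat region while the curvature relief per move is resolvable,
which requires inter-point spacing comparable to or larger than the move
size times the local radius. Closed initializations therefore use ~24–32
points (circles) or a ~2.5 px resampling of the mask boundary offset by a
2 px margin, which keeps every contour point within the σ = 1 gradient
apron of the true edge.

The snake runs on the grayscale image by default (the external term needs
intensities); a mask-input mode rasterizes the binary mask to 0/255 for
pipelines that start from hand-labeled maps only.

## Diametry

For each consecutive characteristic-point pair (N, P), one snake-contour
point is selected on each side of the chord NP (side = sign of the cross
product (P−N)×(M−N); points exactly on the line belong to neither side).
Per side, candidates whose perpendicular foot falls inside the segment are
preferred, the winner being the one with foot nearest the segment midpoint
— deterministic, and it measures the width near the segment center where
the chord best approximates the centerline. Each triple (N, P, M) gives
side lengths a = |NP|, b = |MP|, c = |NM|, the Heron area
A = √(S(S−a)(S−b)(S−c)) with S the half-perimeter, and the height
h = 2A/a. The local diameter is h₁ + h₂, the two heights from opposite
sides; this sum is independent of where the chord sits between the two
edges as long as it runs parallel to them, which is what makes the
construction robust to the skeleton's half-pixel centerline quantization.

Numerics: the Heron radicand is clamped to zero when it dips negative
within 1e−9 (floating-point near-degeneracy); gross triangle-inequality
violations raise. A segment whose contour candidates all lie on one side
is skipped with a warning rather than guessed.

## Evaluation statistics

For paired manual (x) and method (x̄) diameters the package reports the
signed differences x − x̄, the mean absolute difference
E_avg = Σ|x − x̄|/n, and the root-mean-square spread
SD_rms = √(Σ|x − x̄|²/n), plus the conventional sample standard deviation
(divisor n−1) as a diagnostic — published vessel-caliber comparisons are
not always explicit about which spread convention they used, so both are
shown. Reports round to 4 decimal places.

A 30-row reference table of manual/method diameters for three hand-labeled
STARE images and three HRF images ships with the package. One row
(im0002.ah.jpg, vessel 5) is internally inconsistent as published: the
difference column prints −0.0777 but the diameter columns subtract to
−0.0747, and the tabulated E_avg for that image follows the difference
column. The table is shipped verbatim; recomputed statistics use the
diameter columns, so the im0002 E_avg recomputes to 0.0205 against the
tabulated 0.0211. The tabulated SD column is not reproducible from the
printed diameters under any of the conventions above and is therefore
reported but never validated against.

## Synthetic phantoms

Phantoms render a tube of known width around an analytic centerline
(straight, sinusoidal, tapering, or a three-arm Y-junction) with
coverage-fraction anti-aliasing: a one-pixel linear intensity ramp
straddling the true edge, so gradient-based edge detection sees a
subpixel-placed edge. Defaults emulate hand-labeled maps: vessel 200,
background 50, bright-on-dark, no noise; Gaussian pixel noise is available
and fully seeded. The truth object carries the subpixel centerline, the
width profile as a function of arc position, and the mask of pixels within
half the local width of the centerline.

What the phantoms do not emulate: illumination gradients, the central
light reflex of real vessels, optic disc and background texture, branching
geometry beyond a single Y, and sensor noise correlation. Passing the
phantom-recovery checks therefore demonstrates the geometry chain
(skeleton → characteristic points → contour → triangle heights) is
unbiased to well under a pixel on clean tubes — it does not by itself
establish accuracy on clinical images.

Known discretization limit: when a vessel edge falls exactly on a pixel
boundary (even widths centered between pixel rows), the discrete gradient
has two equally deep nodes and the bilinear external field is flat between
them; the internal terms then settle the contour on the inner edge of that
one-pixel plateau, giving a worst-case half-pixel bias per side. This is
the dominant contribution to the ~0.33 px mean absolute error over the
width/orientation grid used in the accuracy checks.

## Problem sizes in the shipped checks

The bundled checks use 96–160 px images, 25 straight tubes (widths 3–20 px
× 5 orientations), one sinusoidal and one tapering tube, a radius-20 disc
with a radius-30 24-point circular initialization, 200 random short
polylines against a brute-force Douglas-Peucker reference, 1000 random
triangles for the Heron identities, and 50 random blob masks for the
thinning invariants. These sizes exercise every code path while keeping
the whole suite in the tens of seconds.
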