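"""End-to-end measurement pipeline: image → per-segment vessel diameters.

Stage order: grayscale reduction → threshold binarization → thinning →
skeleton-point classification and branch tracing → Douglas-Peucker
characteristic points → active-contour edge detection → Heron
triangle-height diametry → agreement statistics.  Every stage parameter
lives in :class:`PipelineConfig`, which round-trips through JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
import pandas as pd

from . import diametry, preprocess, simplify, skeleton, snake, stats

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_evaluation"]

log = logging.getLogger("vesselcal")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with their defaults; JSON-serializable."""

    # binarization
    threshold: Union[float, str] = "auto"   # Otsu when "auto"
    polarity: Literal["bright_vessels", "dark_vessels"] = "bright_vessels"
    channel: Literal["green", "luminance", "red", "blue"] = "green"
    # characteristic points
    epsilon: float = 1.0                    # Douglas-Peucker tolerance, px
    # snake energy and minimizer
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.2
    sigma: float = 1.0
    max_iterations: int = 200
    search_radius: int = 1
    continuity: Literal["mean_spacing", "raw"] = "mean_spacing"
    snake_input: Literal["image", "mask"] = "image"
    # contour initialization
    contour_margin: int = 2                 # dilation radius, px
    contour_spacing: float = 2.5            # resampling spacing, px
    # branch filtering
    min_branch_len: int = 12                # skip spurs shorter than this, px
    seed: int = 0                           # reserved for stochastic inputs

    def snake_params(self) -> snake.SnakeParams:
        return snake.SnakeParams(
            alpha=self.alpha, beta=self.beta, gamma=self.gamma,
            sigma=self.sigma, max_iterations=self.max_iterations,
            search_radius=self.search_radius, continuity=self.continuity,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    measurements: pd.DataFrame              # one row per measured segment
    n_endpoints: int = 0
    n_bifurcations: int = 0
    n_branches: int = 0
    n_branches_measured: int = 0
    n_centerline_points: int = 0
    n_characteristic_points: int = 0
    skipped_segments: int = 0
    message: str = ""

    @property
    def dcr(self) -> float | None:
        if self.n_centerline_points == 0:
            return None
        return simplify.compression_ratio(self.n_centerline_points,
                                          max(1, self.n_characteristic_points))

    @property
    def mean_diameter(self) -> float | None:
        if self.measurements.empty:
            return None
        return float(self.measurements["diameter_px"].mean())


_MEASUREMENT_COLUMNS = ["image", "branch_id", "segment_id",
                        "xN", "yN", "xP", "yP", "h1", "h2", "diameter_px"]


def run_pipeline(image, config: PipelineConfig = PipelineConfig(),
                 out_dir: str | Path | None = None,
                 image_id: str = "image") -> PipelineReport:
    """Run the full measurement chain on a file path or 2-D/3-D array.

    Returns a :class:`PipelineReport`; when ``out_dir`` is given also writes
    ``points.csv``, ``characteristic_points.csv``, ``contours.csv``,
    ``diameters.csv`` and an ``overlay.png``.
    """
    if isinstance(image, (str, Path)):
        image_id = Path(image).name
        gray = preprocess.load_image(image, channel_policy=config.channel)
    else:
        gray = preprocess.to_gray(np.asarray(image), config.channel)

    mask = preprocess.binarize(gray, config.threshold, config.polarity)
    sk = preprocess.skeletonize(mask)
    pts = skeleton.detect_points(sk)
    branches = skeleton.trace_branches(sk)
    log.info("%s: %d endpoints, %d bifurcation px, %d branches",
             image_id, len(pts.endpoints), len(pts.bifurcations), len(branches))

    params = config.snake_params()
    snake_img = gray.astype(float) if config.snake_input == "image" \
        else mask.astype(float) * 255.0

    rows: list[dict] = []
    char_rows: list[dict] = []
    contour_rows: list[dict] = []
    n_total = n_kept = 0
    n_measured_branches = skipped_total = 0
    for bid, br in enumerate(branches):
        if br.closed or len(br) < config.min_branch_len:
            continue
        curve = br.points.astype(float)
        cp = simplify.douglas_peucker(curve, config.epsilon)
        n_total += len(curve)
        n_kept += len(cp)
        for r, c in cp:
            char_rows.append({"branch_id": bid, "row": r, "col": c})
        if len(cp) < 2:
            continue
        try:
            init = snake.initialize_vessel_contour(
                mask, br, margin=config.contour_margin,
                spacing=config.contour_spacing)
        except ValueError as exc:
            log.warning("branch %d: contour initialization failed (%s)", bid, exc)
            continue
        contour = snake.evolve_snake(init, snake_img, params)
        log.debug("branch %d: snake %d points, %d sweeps", bid, len(contour),
                  len(contour.energy_trace) - 1)
        for r, c in contour.points:
            contour_rows.append({"branch_id": bid, "row": r, "col": c})
        measurements, skipped = diametry.measure_vessel(cp, contour)
        skipped_total += len(skipped)
        if measurements:
            n_measured_branches += 1
        for m in measurements:
            rows.append({
                "image": image_id, "branch_id": bid,
                "segment_id": m.segment_index,
                "xN": m.N[1], "yN": m.N[0], "xP": m.P[1], "yP": m.P[0],
                "h1": m.h1, "h2": m.h2, "diameter_px": m.diameter,
            })

    report = PipelineReport(
        measurements=pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS),
        n_endpoints=len(pts.endpoints),
        n_bifurcations=len(pts.bifurcations),
        n_branches=len(branches),
        n_branches_measured=n_measured_branches,
        n_centerline_points=n_total,
        n_characteristic_points=n_kept,
        skipped_segments=skipped_total,
        message="" if rows else "no vessels found",
    )
    if out_dir is not None:
        _write_artifacts(Path(out_dir), gray, mask, sk, pts, report,
                         char_rows, contour_rows)
    return report


def _write_artifacts(out_dir: Path, gray, mask, sk, pts,
                     report: PipelineReport, char_rows, contour_rows) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / "binary.png", (mask * 255).astype(np.uint8))
    iio.imwrite(out_dir / "skeleton.png", (sk * 255).astype(np.uint8))

    point_rows = [{"kind": kind, "row": int(r), "col": int(c)}
                  for kind, arr in (("endpoint", pts.endpoints),
                                    ("inner", pts.inner),
                                    ("bifurcation", pts.bifurcations),
                                    ("isolated", pts.isolated))
                  for r, c in arr]
    pd.DataFrame(point_rows, columns=["kind", "row", "col"]).to_csv(
        out_dir / "points.csv", index=False)
    pd.DataFrame(char_rows, columns=["branch_id", "row", "col"]).to_csv(
        out_dir / "characteristic_points.csv", index=False)
    pd.DataFrame(contour_rows, columns=["branch_id", "row", "col"]).to_csv(
        out_dir / "contours.csv", index=False)
    report.measurements.to_csv(out_dir / "diameters.csv", index=False,
                               float_format="%.6f")

    # color overlay: endpoints red, bifurcations green, contours blue,
    # characteristic points yellow
    g = np.asarray(gray, dtype=float)
    if g.max() > 0:
        g = g / g.max() * 255.0
    rgb = np.stack([g, g, g], axis=-1).astype(np.uint8)

    def paint(coords, color):
        for r, c in coords:
            rr, cc = int(round(r)), int(round(c))
            if 0 <= rr < rgb.shape[0] and 0 <= cc < rgb.shape[1]:
                rgb[rr, cc] = color

    paint([(d["row"], d["col"]) for d in contour_rows], (0, 0, 255))
    paint(pts.endpoints, (255, 0, 0))
    paint(pts.bifurcations, (0, 255, 0))
    paint([(d["row"], d["col"]) for d in char_rows], (255, 255, 0))
    iio.imwrite(out_dir / "overlay.png", rgb)

    summary = {
        "n_endpoints": report.n_endpoints,
        "n_bifurcations": report.n_bifurcations,
        "n_branches": report.n_branches,
        "n_centerline_points": report.n_centerline_points,
        "n_characteristic_points": report.n_characteristic_points,
        "dcr_percent": report.dcr,
        "mean_diameter_px": report.mean_diameter,
        "message": report.message,
    }
    (out_dir / "report.json").write_text(json.dumps(summary, indent=2))


def run_evaluation(pairs_csv: str | Path,
                   out_csv: str | Path | None = None) -> pd.DataFrame:
    """Per-image Difference/SD/E_avg report from a paired-diameters CSV.

    The CSV needs ``image, vessel, manual, proposed`` columns.  Malformed
    input raises with the offending line where pandas can identify it.
    """
    try:
        table = pd.read_csv(pairs_csv)
    except pd.errors.ParserError as exc:
        raise ValueError(f"cannot parse {pairs_csv}: {exc}") from exc
    result = stats.evaluate_table(table)
    if out_csv is not None:
        result.to_csv(out_csv, index=False, float_format="%.4f")
    return result
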