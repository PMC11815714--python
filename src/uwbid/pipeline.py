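"""End-to-end identification pipeline and evaluation report.

Stages: ranging log -> per-exchange distances -> (optional) calibration
correction -> trilateration -> tag fixes; detections -> homography ->
world footprints; temporal pairing of images with fixes; margin-gated
one-to-one association.  Every stage writes its intermediate so a run can
be audited.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .association import MatchResult, TagFix, annotate, associate
from .calibration import CalibrationModel, load_model, predict
from .mapping import (
    Detection,
    Homography,
    ScaleSpec,
    apply_homography,
    apply_homography_many,
    estimate_homography,
    pixel_to_world,
    read_correspondence_config,
    read_detections_csv,
)
from .ranging import compute_all_distances, read_ranging_log
from .trilateration import Anchor, PositionFix, read_anchors, rmse_2d, trilaterate

logger = logging.getLogger("uwbid")

__all__ = ["PipelineConfig", "EvaluationReport", "run_identify", "run_evaluate", "locate_tags"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one identification run."""

    anchors_path: str
    correspondences_path: str
    ranging_log_path: str
    detections_path: str
    calibration_model_path: str | None = None
    image_times_path: str | None = None
    margin_m: float = 1.4
    temporal_window_s: float = 2.5
    containment: str = "footprint"
    method: str = "greedy"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.margin_m <= 0:
            raise ValueError("margin_m must be positive")
        if self.temporal_window_s <= 0:
            raise ValueError("temporal_window_s must be positive")


@dataclass
class EvaluationReport:
    """Localisation accuracy before/after calibration filtering."""

    rmse_before_m: float
    rmse_after_m: float
    table: pd.DataFrame
    identification_accuracy: float | None = None

    def summary(self) -> str:
        lines = ["Test point localisation results", ""]
        disp = self.table.copy()
        for col in disp.columns:
            if disp[col].dtype.kind == "f":
                disp[col] = disp[col].round(3)
        lines.append(disp.to_string(index=False))
        lines.append("")
        lines.append(f"RMSE before filtering: {self.rmse_before_m:.3f} m")
        lines.append(f"RMSE after filtering:  {self.rmse_after_m:.3f} m")
        if self.identification_accuracy is not None:
            lines.append(f"Identification accuracy: {self.identification_accuracy:.1%}")
        return "\n".join(lines)


def locate_tags(
    exchanges,
    anchors: Sequence[Anchor],
    model: CalibrationModel | None = None,
) -> list[PositionFix]:
    """Ranging -> (correction) -> trilateration for every exchange."""
    by_id = {a.anchor_id: a for a in anchors}
    fixes = []
    for ex in exchanges:
        result = compute_all_distances(ex)
        ids = [aid for aid in result.distances if aid in by_id]
        if len(ids) < 3:
            logger.warning(
                "exchange %s has %d usable anchors (<3); skipped", ex.exchange_id, len(ids)
            )
            continue
        dists = np.array([result.distances[aid] for aid in ids])
        if model is not None:
            dists = np.asarray(predict(model, dists))
        fixes.append(
            trilaterate(
                [by_id[aid] for aid in ids],
                dists,
                tag_id=ex.tag_id,
                timestamp=result.timestamp,
            )
        )
    return fixes


def _detections_to_world(
    detections: Sequence[Detection], h: Homography, scale: ScaleSpec
) -> None:
    for det in detections:
        x0, y0, x1, y1 = det.box_px
        cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        det.center_world = pixel_to_world(apply_homography(h, (cx, cy)), scale)
        corners = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        rect = apply_homography_many(h, corners)
        det.footprint_world = rect / scale.pixels_per_cm / 100.0


def _read_image_times(path) -> dict[str, float]:
    df = pd.read_csv(path)
    return {str(r.image_id): float(r.timestamp) for r in df.itertuples(index=False)}


def run_identify(config: PipelineConfig) -> dict[str, MatchResult]:
    """Run the full pipeline; returns one MatchResult per image.

    When ``output_dir`` is set, writes per-stage intermediates
    (``fixes.csv``) and a per-image ``identify_<image>.json`` report.
    """
    anchors = read_anchors(config.anchors_path)
    corr, scale = read_correspondence_config(config.correspondences_path)
    h = estimate_homography(corr)
    exchanges, skipped = read_ranging_log(config.ranging_log_path)
    logger.info(
        "ranging: %d exchanges read, %d corrupt rows skipped", len(exchanges), skipped
    )

    model = None
    if config.calibration_model_path:
        model = load_model(config.calibration_model_path)
        logger.info("calibration: model with %d hidden nodes", model.hidden_size)
    else:
        logger.warning("no calibration model: running on uncorrected ranges")

    fixes = locate_tags(exchanges, anchors, model)
    logger.info("trilateration: %d fixes", len(fixes))

    detections = read_detections_csv(config.detections_path)
    _detections_to_world(detections, h, scale)
    logger.info("mapping: %d detections mapped to world frame", len(detections))

    image_times: dict[str, float] = {}
    if config.image_times_path and Path(config.image_times_path).exists():
        image_times = _read_image_times(config.image_times_path)

    by_image: dict[str, list[tuple[int, Detection]]] = {}
    for j, det in enumerate(detections):
        by_image.setdefault(det.image_id, []).append((j, det))

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {
                    "timestamp": f.timestamp,
                    "tag_id": f.tag_id,
                    "x_m": f.position[0],
                    "y_m": f.position[1],
                    "residual_m": f.residual_norm,
                }
                for f in fixes
            ]
        ).to_csv(outdir / "fixes.csv", index=False, float_format="%.6f")

    results: dict[str, MatchResult] = {}
    for image_id in sorted(by_image):
        img_dets = [d for _, d in by_image[image_id]]
        # temporal pairing: per tag, the fix nearest the image time within
        # the window; without image times every fix is eligible
        per_tag: dict[str, PositionFix] = {}
        t_img = image_times.get(image_id)
        for f in fixes:
            if t_img is not None and abs(f.timestamp - t_img) > config.temporal_window_s:
                continue
            cur = per_tag.get(f.tag_id)
            if (
                cur is None
                or t_img is not None
                and abs(f.timestamp - t_img) < abs(cur.timestamp - t_img)
            ):
                per_tag[f.tag_id] = f
        tag_fixes = [
            TagFix(tag_id, fix.position, fix.timestamp) for tag_id, fix in per_tag.items()
        ]
        res = associate(
            tag_fixes,
            img_dets,
            config.margin_m,
            containment=config.containment,  # type: ignore[arg-type]
            method=config.method,  # type: ignore[arg-type]
        )
        annotate(img_dets, res)
        # re-key detection indices to the global list
        res = MatchResult(
            assignments=[
                (code, image_id, by_image[image_id][j][0], dist)
                for code, _img, j, dist in res.assignments
            ],
            unmatched_detections=[by_image[image_id][j][0] for j in res.unmatched_detections],
            unmatched_tags=res.unmatched_tags,
        )
        results[image_id] = res
        if outdir:
            doc = {
                "image_id": image_id,
                "assignments": [
                    {
                        "cow_code": code,
                        "bbox_px": list(detections[j].box_px),
                        "world_xy_m": list(detections[j].center_world),
                        "distance_m": dist,
                    }
                    for code, _img, j, dist in res.assignments
                ],
                "unmatched_tags": res.unmatched_tags,
                "unmatched_detections": res.unmatched_detections,
            }
            (outdir / f"identify_{image_id}.json").write_text(json.dumps(doc, indent=1))
        logger.info(
            "associate[%s]: %d assigned, %d detections unmatched, %d tags unmatched",
            image_id,
            len(res.assignments),
            len(res.unmatched_detections),
            len(res.unmatched_tags),
        )
    return results


def run_evaluate(
    fixes_before: Sequence[tuple[float, float]],
    fixes_after: Sequence[tuple[float, float]],
    truths: Sequence[tuple[float, float]],
    identification_accuracy: float | None = None,
) -> EvaluationReport:
    """Planar RMSE of uncorrected and corrected fixes against ground truth."""
    if not (len(fixes_before) == len(fixes_after) == len(truths)):
        raise ValueError("before/after/truth lists must be aligned")
    table = pd.DataFrame(
        {
            "point": range(1, len(truths) + 1),
            "real_x_m": [p[0] for p in truths],
            "real_y_m": [p[1] for p in truths],
            "before_x_m": [p[0] for p in fixes_before],
            "before_y_m": [p[1] for p in fixes_before],
            "after_x_m": [p[0] for p in fixes_after],
            "after_y_m": [p[1] for p in fixes_after],
        }
    )
    return EvaluationReport(
        rmse_before_m=rmse_2d(fixes_before, truths),
        rmse_after_m=rmse_2d(fixes_after, truths),
        table=table,
        identification_accuracy=identification_accuracy,
    )
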