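"""Image-to-world registration via a four-point planar homography.

A camera viewing a flat floor region induces a projective map between
image pixels and floor coordinates.  Four point correspondences in general
position (no three collinear on either side) determine the 3x3 matrix C
exactly: a source pixel (x, y), taken homogeneous as (x, y, 1), maps to

    u = c11 x + c12 y + c13
    v = c21 x + c22 y + c23
    w = c31 x + c32 y + c33

followed by the perspective division (u/w, v/w).  C is defined only up to
scale, so c33 is fixed to 1 and the remaining eight entries are solved as
a linear system (direct linear transform).  A pixels-per-centimetre scale
then converts rectified pixels to metres.

Pixel convention: origin at the image's top-left corner, x rightward,
y downward, continuous coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PointCorrespondences",
    "Homography",
    "ScaleSpec",
    "HorizonError",
    "estimate_homography",
    "apply_homography",
    "pixel_to_world",
    "Detection",
    "detection_center",
    "yolo_to_pixel_box",
    "read_yolo_txt",
    "read_detections_csv",
    "write_detections_csv",
    "read_correspondence_config",
    "write_correspondence_config",
]


class HorizonError(ValueError):
    """Point maps to the line at infinity (w ~ 0)."""


def _collinear_triple(points: np.ndarray, tol: float = 1e-8) -> bool:
    from itertools import combinations

    for i, j, k in combinations(range(len(points)), 3):
        a, b, c = points[i], points[j], points[k]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        span = max(np.abs(points[[i, j, k]]).max(), 1.0)
        if abs(cross) < tol * span**2:
            return True
    return False


@dataclass(frozen=True)
class PointCorrespondences:
    """Exactly four (source pixel, destination) point pairs."""

    src: np.ndarray  # (4, 2)
    dst: np.ndarray  # (4, 2)

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        if src.shape != (4, 2) or dst.shape != (4, 2):
            raise ValueError("need exactly four 2-D points on each side")
        if _collinear_triple(src):
            raise ValueError("three of the source points are collinear")
        if _collinear_triple(dst):
            raise ValueError("three of the destination points are collinear")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)


@dataclass(frozen=True)
class Homography:
    """3x3 projective matrix with c33 normalised to 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography matrix is singular")
        if abs(m[2, 2]) > 1e-12 and m[2, 2] != 1.0:
            m = m / m[2, 2]
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


@dataclass(frozen=True)
class ScaleSpec:
    """Rectified-pixel to physical scale, in pixels per centimetre."""

    pixels_per_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")


def estimate_homography(corr: PointCorrespondences) -> Homography:
    """Direct linear transform on four correspondences (c33 = 1).

    Exact for four points in general position: each destination is
    reproduced to solver tolerance.
    """
    A = np.zeros((8, 8))
    b = np.zeros(8)
    for i, ((x, y), (u, v)) in enumerate(zip(corr.src, corr.dst)):
        A[2 * i] = [x, y, 1, 0, 0, 0, -u * x, -u * y]
        A[2 * i + 1] = [0, 0, 0, x, y, 1, -v * x, -v * y]
        b[2 * i] = u
        b[2 * i + 1] = v
    try:
        h = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"homography system is singular: {err}") from err
    return Homography(np.array([h[0:3], h[3:6], [h[6], h[7], 1.0]]))


def apply_homography(h: Homography, point: Sequence[float]) -> tuple[float, float]:
    """Map one pixel through the homography with perspective division."""
    x, y = float(point[0]), float(point[1])
    u, v, w = h.matrix @ np.array([x, y, 1.0])
    if abs(w) < 1e-12:
        raise HorizonError(f"point ({x}, {y}) maps to the line at infinity (w={w})")
    return (u / w, v / w)


def apply_homography_many(h: Homography, points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    homog = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = homog[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise HorizonError("a point maps to the line at infinity")
    return homog[:, :2] / w[:, None]


def pixel_to_world(
    point: Sequence[float], scale: ScaleSpec, origin_m: tuple[float, float] = (0.0, 0.0)
) -> tuple[float, float]:
    """Rectified pixel -> world metres (optionally offset to barn coordinates)."""
    return (
        point[0] / scale.pixels_per_cm / 100.0 + origin_m[0],
        point[1] / scale.pixels_per_cm / 100.0 + origin_m[1],
    )


# ---------------------------------------------------------------------------
# Detections

@dataclass
class Detection:
    """One detector bounding box, optionally with world-frame geometry.

    ``center_world`` and ``footprint_world`` are populated by the pipeline
    once a homography and scale are known; ``footprint_world`` is the
    (4, 2) array of the box corners mapped to world metres.
    """

    image_id: str
    box_px: tuple[float, float, float, float]  # x_min, y_min, x_max, y_max
    confidence: float = 1.0
    class_id: int = 0
    center_world: tuple[float, float] | None = None
    footprint_world: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box_px
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box_px} (need x_min < x_max, y_min < y_max)")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


def detection_center(box: Detection) -> tuple[float, float]:
    """Pixel midpoint of the bounding box — the stand-in for the body centre."""
    x0, y0, x1, y1 = box.box_px
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


def yolo_to_pixel_box(
    xc: float, yc: float, w: float, h: float, image_size: tuple[int, int]
) -> tuple[float, float, float, float]:
    """Normalised YOLO (xc, yc, w, h) -> pixel (x_min, y_min, x_max, y_max)."""
    iw, ih = image_size
    return (
        (xc - w / 2) * iw,
        (yc - h / 2) * ih,
        (xc + w / 2) * iw,
        (yc + h / 2) * ih,
    )


def read_yolo_txt(path, image_id: str, image_size: tuple[int, int]) -> list[Detection]:
    """YOLO-style txt: one ``class xc yc w h [conf]`` line per detection."""
    detections = []
    for line in open(path):
        parts = line.split()
        if not parts:
            continue
        cls, xc, yc, w, h = int(parts[0]), *map(float, parts[1:5])
        conf = float(parts[5]) if len(parts) > 5 else 1.0
        detections.append(
            Detection(
                image_id=image_id,
                box_px=yolo_to_pixel_box(xc, yc, w, h, image_size),
                confidence=conf,
                class_id=cls,
            )
        )
    return detections


_DET_COLUMNS = ["image_id", "class", "conf", "x_min", "y_min", "x_max", "y_max"]


def read_detections_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    missing = set(_DET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns: {sorted(missing)}")
    # "class" is a keyword, so itertuples would mangle it; go by column
    return [
        Detection(
            image_id=str(row["image_id"]),
            box_px=(
                float(row["x_min"]),
                float(row["y_min"]),
                float(row["x_max"]),
                float(row["y_max"]),
            ),
            confidence=float(row["conf"]),
            class_id=int(row["class"]),
        )
        for _, row in df.iterrows()
    ]


def write_detections_csv(detections: Sequence[Detection], path) -> None:
    rows = [
        {
            "image_id": d.image_id,
            "class": d.class_id,
            "conf": d.confidence,
            "x_min": d.box_px[0],
            "y_min": d.box_px[1],
            "x_max": d.box_px[2],
            "y_max": d.box_px[3],
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=_DET_COLUMNS).to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# Correspondence config

def read_correspondence_config(path) -> tuple[PointCorrespondences, ScaleSpec]:
    """YAML with four ``{src_px: [x, y], dst: [u, v]}`` entries + pixels_per_cm."""
    doc = yaml.safe_load(open(path))
    pairs = doc["correspondences"]
    src = np.array([p["src_px"] for p in pairs], dtype=float)
    dst = np.array([p["dst"] for p in pairs], dtype=float)
    scale = ScaleSpec(float(doc.get("pixels_per_cm", 30.0)))
    return PointCorrespondences(src, dst), scale


def write_correspondence_config(corr: PointCorrespondences, scale: ScaleSpec, path) -> None:
    doc = {
        "pixels_per_cm": scale.pixels_per_cm,
        "correspondences": [
            {"src_px": [float(s[0]), float(s[1])], "dst": [float(d[0]), float(d[1])]}
            for s, d in zip(corr.src, corr.dst)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
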