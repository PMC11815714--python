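"""Planar trilateration from anchor distances, and positional RMSE.

Each anchor i at known (x_i, y_i) constrains the tag position p = (x, y)
through the circle equation ||p - a_i||^2 = d_i^2.  Subtracting the last
circle equation from the others removes the quadratic terms and leaves a
linear system

    2 (x_K - x_i) x + 2 (y_K - y_i) y
        = d_i^2 - d_K^2 + x_K^2 - x_i^2 + y_K^2 - y_i^2,   i = 1..K-1,

solved in the least-squares sense — exact for three non-collinear anchors
with consistent distances, and well defined for noisy or over-determined
(>3 anchor) inputs.  Positioning is strictly two-dimensional: anchors and
tags are assumed coplanar and no Z coordinate is estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Anchor",
    "PositionFix",
    "CollinearAnchorsError",
    "trilaterate",
    "rmse_2d",
    "read_anchors",
    "write_anchors",
]


class CollinearAnchorsError(ValueError):
    """Raised when the anchor geometry does not pin down a planar position."""


@dataclass(frozen=True)
class Anchor:
    anchor_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"anchor {self.anchor_id} has non-finite coordinates")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class PositionFix:
    """A solved tag position with its range-consistency residual.

    ``residual_norm`` is the Euclidean norm over anchors of
    ``| ||p - a_i|| - d_i |`` — zero when the distances are consistent.
    """

    tag_id: str
    position: tuple[float, float]
    residual_norm: float
    timestamp: float = 0.0


def trilaterate(
    anchors: Sequence[Anchor],
    distances: Sequence[float],
    *,
    tag_id: str = "",
    timestamp: float = 0.0,
) -> PositionFix:
    """Solve for the planar tag position from >= 3 anchor distances."""
    if len(anchors) < 3:
        raise ValueError(f"need at least 3 anchors, got {len(anchors)}")
    if len(anchors) != len(distances):
        raise ValueError("anchors and distances must have equal length")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite and non-negative")
    pos = np.array([[a.x, a.y] for a in anchors], dtype=float)

    # collinearity: singular values of centred geometry
    centred = pos - pos.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] < 1e-9 * sv[0]:
        raise CollinearAnchorsError(
            f"anchors {[a.anchor_id for a in anchors]} are (near-)collinear"
        )

    ref = pos[-1]
    d_ref = d[-1]
    A = 2.0 * (ref - pos[:-1])  # (K-1, 2)
    b = (
        d[:-1] ** 2
        - d_ref**2
        + np.sum(ref**2)
        - np.sum(pos[:-1] ** 2, axis=1)
    )
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    residual = float(np.linalg.norm(np.linalg.norm(pos - p, axis=1) - d))
    return PositionFix(
        tag_id=tag_id,
        position=(float(p[0]), float(p[1])),
        residual_norm=residual,
        timestamp=timestamp,
    )


def rmse_2d(
    estimates: Sequence[tuple[float, float]], actuals: Sequence[tuple[float, float]]
) -> float:
    """Planar RMSE: sqrt( mean_i [ (x_i - x̂_i)^2 + (y_i - ŷ_i)^2 ] )."""
    e = np.asarray(estimates, dtype=float)
    a = np.asarray(actuals, dtype=float)
    if e.shape != a.shape or e.ndim != 2 or e.shape[1] != 2 or e.shape[0] == 0:
        raise ValueError("estimates and actuals must be non-empty (n, 2) arrays of equal shape")
    return float(np.sqrt(np.mean(np.sum((e - a) ** 2, axis=1))))


def read_anchors(path) -> list[Anchor]:
    """Anchors from a YAML config: ``anchors: [{id, x_m, y_m}, ...]``."""
    doc = yaml.safe_load(open(path))
    entries = doc["anchors"] if isinstance(doc, dict) else doc
    return [Anchor(str(e["id"]), float(e["x_m"]), float(e["y_m"])) for e in entries]


def write_anchors(anchors: Sequence[Anchor], path) -> None:
    doc = {"anchors": [{"id": a.anchor_id, "x_m": a.x, "y_m": a.y} for a in anchors]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
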