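"""Tag-to-detection identity association.

A UWB tag gives the position of a cow's *head*; a detection's box centre
stands in for the *body centre*, roughly 1.2 m away in an adult cow
(2.5 m body length) and further displaced by posture.  Rather than guess
the heading from a single fix, that offset is absorbed into a gating
margin (default 1.4 m): a (fix, detection) pair is a candidate when

  * the Euclidean world distance between fix and detection centre is
    within the margin, and
  * the fix lies inside the detection box's world-mapped footprint
    (the default reading of the requirement that the corrected range stay
    within the detected bounding box; an alternative "box-size" gate that
    compares the distance against the footprint's longer side is
    selectable).

Candidates are resolved one-to-one, nearest pair first (greedy); an
optimal bipartite assignment minimising total distance is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .mapping import Detection

__all__ = ["TagFix", "MatchResult", "associate", "annotate", "UNKNOWN_LABEL"]

#: Label attached to detections no tag could claim.
UNKNOWN_LABEL = "unknown"


@dataclass(frozen=True)
class TagFix:
    """A localised tag: the farm-registry cow code plus its world position."""

    cow_code: str
    position_world: tuple[float, float]
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position_world)):
            raise ValueError(f"non-finite fix position for {self.cow_code}")


@dataclass
class MatchResult:
    """One-to-one assignment of cow codes to detections.

    ``assignments`` rows are (cow_code, image_id, detection_index,
    distance_m); indices refer to the detection list passed to
    :func:`associate`.
    """

    assignments: list[tuple[str, str, int, float]] = field(default_factory=list)
    unmatched_detections: list[int] = field(default_factory=list)
    unmatched_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [a[0] for a in self.assignments]
        dets = [a[2] for a in self.assignments]
        if len(set(codes)) != len(codes) or len(set(dets)) != len(dets):
            raise ValueError("assignment is not one-to-one")


def _footprint_gate(fix_xy: np.ndarray, det: Detection, mode: str, dist: float) -> bool:
    if det.footprint_world is None:
        return True
    poly = Polygon(np.asarray(det.footprint_world))
    if mode == "footprint":
        # boundary counts as inside
        return poly.covers(Point(fix_xy))
    if mode == "box-size":
        xs, ys = np.asarray(det.footprint_world).T
        return dist <= max(xs.max() - xs.min(), ys.max() - ys.min())
    raise ValueError(f"unknown containment mode {mode!r}")


def associate(
    fixes: Sequence[TagFix],
    detections: Sequence[Detection],
    margin: float = 1.4,
    *,
    containment: Literal["footprint", "box-size"] = "footprint",
    method: Literal["greedy", "optimal"] = "greedy",
) -> MatchResult:
    """Assign tag identities to detections under the margin/containment gate."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    for det in detections:
        if det.center_world is None:
            raise ValueError(
                f"detection in image {det.image_id!r} lacks world coordinates; "
                "map detections through the homography before associating"
            )

    candidates: list[tuple[float, int, int]] = []  # (distance, fix idx, det idx)
    for i, fix in enumerate(fixes):
        fxy = np.asarray(fix.position_world, dtype=float)
        for j, det in enumerate(detections):
            dist = float(np.linalg.norm(fxy - np.asarray(det.center_world)))
            if dist <= margin and _footprint_gate(fxy, det, containment, dist):
                candidates.append((dist, i, j))

    matched_fix: dict[int, tuple[int, float]] = {}
    if method == "greedy":
        used_d: set[int] = set()
        for dist, i, j in sorted(candidates):
            if i in matched_fix or j in used_d:
                continue
            matched_fix[i] = (j, dist)
            used_d.add(j)
    elif method == "optimal":
        from scipy.optimize import linear_sum_assignment

        if candidates:
            fi = sorted({i for _, i, _ in candidates})
            dj = sorted({j for _, _, j in candidates})
            big = 1e6
            cost = np.full((len(fi), len(dj)), big)
            for dist, i, j in candidates:
                cost[fi.index(i), dj.index(j)] = dist
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    matched_fix[fi[r]] = (dj[c], float(cost[r, c]))
    else:
        raise ValueError(f"unknown method {method!r}")

    assignments = [
        (fixes[i].cow_code, detections[j].image_id, j, dist)
        for i, (j, dist) in sorted(matched_fix.items())
    ]
    used = {j for j, _ in matched_fix.values()}
    return MatchResult(
        assignments=assignments,
        unmatched_detections=[j for j in range(len(detections)) if j not in used],
        unmatched_tags=[f.cow_code for i, f in enumerate(fixes) if i not in matched_fix],
    )


def annotate(detections: Sequence[Detection], result: MatchResult) -> list[Detection]:
    """Write each matched detection's cow code into its ``label`` field.

    Unmatched detections get the :data:`UNKNOWN_LABEL` sentinel.  Returns
    the same detection objects for chaining.
    """
    for det in detections:
        det.label = UNKNOWN_LABEL
    for cow_code, _image_id, j, _dist in result.assignments:
        if j >= len(detections):
            raise ValueError(f"assignment index {j} outside detection list")
        detections[j].label = cow_code
    return list(detections)
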