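"""Synthetic barn scenes with full ground truth.

Everything the identification pipeline consumes can be generated here:
DS-TWR timestamp exchanges (with per-device clock skew, receive-timestamp
jitter and a systematic range-bias model), the 1-20 m static calibration
sweep, camera correspondences, and per-image detection files, together
with the true cow placements and identities.

The emulated setup: a 12 m x 9 m pen observed by one fixed camera and
three UWB anchors; adult cows (2.5 m body length) carry head-mounted tags
offset 1.2 m from the body centre along the heading; one image is taken
per ranging round (5 s apart).  Cows are static within a frame.  The
camera model *is* the ground-plane homography — detection boxes are drawn
in world coordinates and mapped into the image through its inverse, so no
3-D projection or occlusion is modelled.

The default noise/bias figures emulate an uncalibrated UWB link with a
range error on the 0.15-0.2 m scale and centimetre-level ranging noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .association import TagFix
from .mapping import (
    Detection,
    Homography,
    PointCorrespondences,
    ScaleSpec,
    apply_homography_many,
    estimate_homography,
    write_correspondence_config,
    write_detections_csv,
)
from .ranging import SPEED_OF_LIGHT, AnchorRecord, RangingExchange, write_ranging_log
from .trilateration import Anchor, write_anchors

__all__ = [
    "SimConfig",
    "SimScene",
    "CowTruth",
    "simulate_exchange",
    "simulate_calibration_sweep",
    "simulate_scene",
    "jitter_propagation_constant",
    "timestamp_noise_for_range_sd",
]


def _default_anchors() -> tuple[tuple[str, float, float], ...]:
    return (("A1", 0.0, 0.0), ("A2", 12.0, 0.0), ("A3", 6.0, 9.0))


def _default_correspondences() -> dict:
    # Arena corners (m) seen by an oblique camera in a 900x780 px image;
    # rectified at 0.75 px/cm so the 12 m side spans 900 px.
    return {
        "src_px": [[100.0, 90.0], [820.0, 60.0], [40.0, 700.0], [860.0, 740.0]],
        "world_m": [[0.0, 0.0], [12.0, 0.0], [0.0, 9.0], [12.0, 9.0]],
        "pixels_per_cm": 0.75,
    }


@dataclass
class SimConfig:
    """Scene-generation parameters; defaults emulate the studied pen."""

    arena: tuple[float, float] = (12.0, 9.0)
    anchors: tuple[tuple[str, float, float], ...] = field(default_factory=_default_anchors)
    n_cows: int = 2
    n_tagged: int | None = None  # None -> every cow carries a tag
    n_frames: int = 1
    cow_length_m: float = 2.5
    cow_width_m: float = 1.0
    head_offset_m: float = 1.2
    head_radius_m: float = 0.25  # the detector box encloses the head, not just the torso
    min_separation_m: float = 3.0
    tag_clock_skew_ppm: float = 10.0
    anchor_clock_skew_ppm: float = 10.0
    anchor_clock_offset_s: float = 0.0  # DS-TWR is insensitive; non-zero costs float precision
    timestamp_noise_s: float = 1.1e-10  # ~2 cm of ranging noise after propagation
    range_bias_slope: float = 1.002
    range_bias_intercept_m: float = 0.15
    ranging_interval_s: float = 5.0
    anchor_reply_delay_s: float = 1e-4
    tag_reply_delay_s: float = 1.5e-4
    camera: dict = field(default_factory=_default_correspondences)
    image_size: tuple[int, int] = (900, 780)
    bbox_jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena[0] <= 0 or self.arena[1] <= 0:
            raise ValueError("arena dimensions must be positive")
        if self.n_cows < 1:
            raise ValueError("n_cows must be >= 1")
        if len(self.anchors) < 3:
            raise ValueError("need at least 3 anchors")
        if self.timestamp_noise_s < 0 or self.bbox_jitter_px < 0:
            raise ValueError("noise levels must be non-negative")
        pos = np.array([[a[1], a[2]] for a in self.anchors])
        sv = np.linalg.svd(pos - pos.mean(axis=0), compute_uv=False)
        if sv[-1] < 1e-9 * sv[0]:
            raise ValueError("anchors are collinear")

    @property
    def anchor_objects(self) -> list[Anchor]:
        return [Anchor(a[0], a[1], a[2]) for a in self.anchors]

    def camera_correspondences(self) -> tuple[PointCorrespondences, ScaleSpec]:
        scale = ScaleSpec(float(self.camera["pixels_per_cm"]))
        src = np.asarray(self.camera["src_px"], dtype=float)
        world = np.asarray(self.camera["world_m"], dtype=float)
        dst = world * 100.0 * scale.pixels_per_cm  # metres -> rectified pixels
        return PointCorrespondences(src, dst), scale


def jitter_propagation_constant(
    anchor_reply_delay_s: float, tag_reply_delay_s: float, tof_s: float = 0.0
) -> float:
    """First-order gain from receive-timestamp jitter to time-of-flight error.

    Linearising the DS-TWR estimator around the ideal timestamps, the three
    jittered receive timestamps (ti, ti1, ti3) enter with sensitivities
    1/2, (tof + Dt)/S and (tof + Da)/S, where S is the interval sum
    2*(2*tof + Da + Dt).  Independent jitter of s.d. sigma therefore maps
    to a tof s.d. of approximately k * sigma with k the root sum of
    squares returned here.
    """
    Da, Dt = anchor_reply_delay_s, tag_reply_delay_s
    S = 2.0 * (2.0 * tof_s + Da + Dt)
    return float(np.sqrt(0.25 + ((tof_s + Dt) / S) ** 2 + ((tof_s + Da) / S) ** 2))


def timestamp_noise_for_range_sd(range_sd_m: float, config: SimConfig) -> float:
    """Receive-jitter s.d. that yields a target ranging s.d. in metres."""
    k = jitter_propagation_constant(config.anchor_reply_delay_s, config.tag_reply_delay_s)
    return range_sd_m / (SPEED_OF_LIGHT * k)


def simulate_exchange(
    true_distance,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    tag_id: str = "tag",
    t_start: float = 0.0,
    exchange_id: str = "",
) -> RangingExchange:
    """Construct one DS-TWR exchange from true tag-anchor distance(s).

    ``true_distance`` is a scalar (one anchor) or a mapping
    anchor_id -> metres.  Ideal-clock timestamps are built from
    tof = d_eff / c (with the systematic bias model applied to the
    distance), anchors replying in a staggered sequence; each device's
    clock then scales true time by (1 + skew) and receive timestamps get
    additive Gaussian jitter.  Deterministic for a given generator state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if np.isscalar(true_distance):
        dists = {config.anchors[0][0]: float(true_distance)}
    else:
        dists = {str(k): float(v) for k, v in dict(true_distance).items()}
    for aid, d in dists.items():
        if d < 0:
            raise ValueError(f"negative true distance {d} for anchor {aid}")

    e_tag = config.tag_clock_skew_ppm * 1e-6
    clock_tag = lambda t: (1.0 + e_tag) * t

    taus = {
        aid: (config.range_bias_slope * d + config.range_bias_intercept_m) / SPEED_OF_LIGHT
        for aid, d in dists.items()
    }

    # true-time schedule: poll at t_start; anchor k replies after (k+1)
    # reply delays (staggered so responses do not collide); final goes out
    # one tag delay after the last response arrives.
    poll_tx = t_start
    resp_tx = {}
    resp_rx = {}
    for k, aid in enumerate(dists):
        poll_rx = poll_tx + taus[aid]
        resp_tx[aid] = poll_rx + config.anchor_reply_delay_s * (k + 1)
        resp_rx[aid] = resp_tx[aid] + taus[aid]
    final_tx = max(resp_rx.values()) + config.tag_reply_delay_s

    records = []
    for aid in dists:
        e_anchor = config.anchor_clock_skew_ppm * 1e-6
        offset = config.anchor_clock_offset_s
        clock_anchor = lambda t: (1.0 + e_anchor) * t + offset
        jit = lambda: float(rng.normal(0.0, config.timestamp_noise_s)) if config.timestamp_noise_s else 0.0
        records.append(
            AnchorRecord(
                anchor_id=aid,
                ti=clock_tag(resp_rx[aid]) + jit(),
                ti1=clock_anchor(poll_tx + taus[aid]) + jit(),
                ti2=clock_anchor(resp_tx[aid]),
                ti3=clock_anchor(final_tx + taus[aid]) + jit(),
            )
        )
    return RangingExchange(
        tag_id=tag_id,
        t0=clock_tag(poll_tx),
        t4=clock_tag(final_tx),
        anchors=tuple(records),
        exchange_id=exchange_id,
    )


def simulate_calibration_sweep(config: SimConfig | None = None) -> "CalibrationDataset":
    """Static 1-20 m sweep: 10 measurements at each metre mark, 200 pairs.

    Measured values come out of the full exchange simulation (bias model
    plus timestamp jitter), so the sweep carries exactly the error
    structure the corrector will face in the pen.
    """
    from .calibration import CalibrationDataset

    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    from .ranging import compute_distance

    true_vals = []
    measured = []
    for metre in range(1, 21):
        for _ in range(10):
            d = float(metre)
            ex = simulate_exchange(d, config, rng)
            true_vals.append(d)
            measured.append(compute_distance(ex, config.anchors[0][0]))
    return CalibrationDataset(
        np.array(measured), np.array(true_vals), split_seed=config.seed
    )


@dataclass
class CowTruth:
    cow_code: str
    body_center: tuple[float, float]
    heading_rad: float
    head_position: tuple[float, float]
    tagged: bool


@dataclass
class SimScene:
    """A generated scene: ground truth plus every pipeline input."""

    config: SimConfig
    cows: list[CowTruth]
    exchanges: list[RangingExchange]
    detections: list[Detection]
    true_identity: dict[int, str]  # detection index -> cow code
    image_times: dict[str, float]
    homography_true: Homography  # source pixels -> rectified pixels

    @property
    def tag_truth(self) -> list[TagFix]:
        return [
            TagFix(c.cow_code, c.head_position) for c in self.cows if c.tagged
        ]

    def write(self, outdir) -> None:
        """Write every standard input file plus ground truth and manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_ranging_log(self.exchanges, out / "ranging.csv")
        write_detections_csv(self.detections, out / "detections.csv")
        write_anchors(self.config.anchor_objects, out / "anchors.yaml")
        corr, scale = self.config.camera_correspondences()
        write_correspondence_config(corr, scale, out / "correspondences.yaml")

        by_image: dict[str, list[Detection]] = {}
        for det in self.detections:
            by_image.setdefault(det.image_id, []).append(det)
        iw, ih = self.config.image_size
        for image_id, dets in by_image.items():
            lines = []
            for d in dets:
                x0, y0, x1, y1 = d.box_px
                lines.append(
                    f"{d.class_id} {(x0 + x1) / 2 / iw:.6f} {(y0 + y1) / 2 / ih:.6f} "
                    f"{(x1 - x0) / iw:.6f} {(y1 - y0) / ih:.6f} {d.confidence:.4f}"
                )
            (out / f"{image_id}.txt").write_text("\n".join(lines) + "\n")

        with open(out / "images.csv", "w") as fh:
            fh.write("image_id,timestamp\n")
            for image_id, t in sorted(self.image_times.items()):
                fh.write(f"{image_id},{t:.6f}\n")

        truth = {
            "cows": [asdict(c) for c in self.cows],
            "true_identity": {str(k): v for k, v in self.true_identity.items()},
            "image_times": self.image_times,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
        manifest = {"config": _config_dict(self.config), "seed": self.config.seed}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_dict(config: SimConfig) -> dict:
    doc = asdict(config)
    doc["anchors"] = [list(a) for a in config.anchors]
    return doc


def _place_cows(config: SimConfig, rng: np.random.Generator) -> list[CowTruth]:
    w, h = config.arena
    wall = config.cow_length_m / 2.0
    if w <= 2 * wall or h <= 2 * wall:
        raise ValueError("arena too small for a cow")
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < config.n_cows:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                f"could not place {config.n_cows} cows with separation "
                f"{config.min_separation_m} m in a {w} x {h} m arena after 10000 draws"
            )
        p = np.array([rng.uniform(wall, w - wall), rng.uniform(wall, h - wall)])
        if all(np.linalg.norm(p - q) >= config.min_separation_m for q in centres):
            centres.append(p)
    n_tagged = config.n_cows if config.n_tagged is None else min(config.n_tagged, config.n_cows)
    cows = []
    for i, c in enumerate(centres):
        heading = float(rng.uniform(0.0, 2.0 * np.pi))
        head = c + config.head_offset_m * np.array([np.cos(heading), np.sin(heading)])
        cows.append(
            CowTruth(
                cow_code=f"COW{i + 1:03d}",
                body_center=(float(c[0]), float(c[1])),
                heading_rad=heading,
                head_position=(float(head[0]), float(head[1])),
                tagged=i < n_tagged,
            )
        )
    return cows


def simulate_scene(config: SimConfig | None = None) -> SimScene:
    """Generate a ground-truthed scene under the configured conditions.

    Cows are placed uniformly with rejection until all pairwise
    body-centre separations meet ``min_separation_m``; each frame yields
    one DS-TWR exchange per tagged cow (staggered 0.1 s apart within the
    ranging round) and one detection per cow, drawn as the cow's oriented
    world footprint mapped into the image through the inverse camera
    homography with pixel jitter on the box corners.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    cows = _place_cows(config, rng)
    anchors = config.anchor_objects
    corr, _scale = config.camera_correspondences()
    H = estimate_homography(corr)  # source px -> rectified px
    H_inv = H.inverse()
    ppcm = float(config.camera["pixels_per_cm"])

    exchanges: list[RangingExchange] = []
    detections: list[Detection] = []
    true_identity: dict[int, str] = {}
    image_times: dict[str, float] = {}

    for frame in range(config.n_frames):
        t_frame = frame * config.ranging_interval_s
        image_id = f"frame_{frame:04d}"
        image_times[image_id] = t_frame

        tag_slot = 0
        for cow in cows:
            if not cow.tagged:
                continue
            head = np.asarray(cow.head_position)
            dists = {
                a.anchor_id: float(np.linalg.norm(head - a.position)) for a in anchors
            }
            exchanges.append(
                simulate_exchange(
                    dists,
                    config,
                    rng,
                    tag_id=cow.cow_code,
                    t_start=t_frame + 0.1 * tag_slot,
                    exchange_id=f"{image_id}_{cow.cow_code}",
                )
            )
            tag_slot += 1

        for cow in cows:
            c = np.asarray(cow.body_center)
            u = np.array([np.cos(cow.heading_rad), np.sin(cow.heading_rad)])
            v = np.array([-u[1], u[0]])
            # the box encloses the whole animal: torso behind, head in front
            rear = config.cow_length_m / 2.0
            front = max(
                config.cow_length_m / 2.0, config.head_offset_m + config.head_radius_m
            )
            half_w = config.cow_width_m / 2.0
            corners_world = np.array(
                [
                    c + front * u + half_w * v,
                    c + front * u - half_w * v,
                    c - rear * u - half_w * v,
                    c - rear * u + half_w * v,
                ]
            )
            corners_rect = corners_world * 100.0 * ppcm  # metres -> rectified px
            corners_src = apply_homography_many(H_inv, corners_rect)
            x0, y0 = corners_src.min(axis=0)
            x1, y1 = corners_src.max(axis=0)
            if config.bbox_jitter_px:
                x0, y0, x1, y1 = (
                    np.array([x0, y0, x1, y1])
                    + rng.normal(0.0, config.bbox_jitter_px, 4)
                )
                if x1 <= x0 or y1 <= y0:  # pathological jitter draw
                    x0, y0 = corners_src.min(axis=0)
                    x1, y1 = corners_src.max(axis=0)
            det = Detection(
                image_id=image_id,
                box_px=(float(x0), float(y0), float(x1), float(y1)),
                confidence=float(np.clip(rng.normal(0.9, 0.05), 0.5, 1.0)),
            )
            true_identity[len(detections)] = cow.cow_code
            detections.append(det)

    return SimScene(
        config=config,
        cows=cows,
        exchanges=exchanges,
        detections=detections,
        true_identity=true_identity,
        image_times=image_times,
        homography_true=H,
    )
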