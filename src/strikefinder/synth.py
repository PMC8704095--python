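"""Ground-truthed synthetic monitoring scenes for both channels.

The generator renders the disturbance modes a nacelle-mounted camera
actually sees, so every pipeline stage is testable without field data:

* a static textured vegetation background (smoothed white noise — rich in
  keypoints, as registration requires);
* global illumination steps, as when clouds move in front of the sun;
* wind events: spatially coherent, zero-mean gray-value fluctuation over
  a contiguous area — it elevates scores over a broad surround without a
  persistent step, the signature the surround criterion rejects;
* walkers: transient warm (LWIR) or dark (VIS) animals crossing the
  scene at a few pixels per frame;
* sitters: animals dwelling in place with small positional jitter;
* drops: sudden persistent small objects — the strike events.  Thermal
  drops cool exponentially toward the background; VIS drops are
  persistent darkenings;
* per-frame nacelle motion (affine jitter) and per-pixel sensor noise.

Same spec + seed produces bit-identical frames.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

from .frames import Channel, Frame

__all__ = [
    "IlluminationEvent",
    "WindEvent",
    "WalkerEvent",
    "SitterEvent",
    "DropEvent",
    "SceneSpec",
    "GroundTruth",
    "SynthError",
    "cooling_curve",
    "footprint_offsets",
    "textured_background",
    "generate_sequence",
    "benchmark_lwir_scene",
    "scene_from_dict",
]


class SynthError(ValueError):
    pass


def cooling_curve(delta0: float, tau: float, t: float) -> float:
    """Contrast of a warm dropped object ``t`` seconds after the drop.

    Newton-style exponential cooling, ``delta0 * exp(-t / tau)``.  The
    default time constant used by the scene factories (300 s) keeps a
    30-gray-level object detectable about five minutes after the drop.
    """
    if tau <= 0:
        raise SynthError("tau must be positive")
    if t < 0:
        raise SynthError("t must be >= 0")
    return float(delta0 * math.exp(-t / tau))


def footprint_offsets(n_px: int) -> np.ndarray:
    """Deterministic (row, col) offsets of an ``n_px``-pixel footprint.

    Lattice points ordered by distance from the origin (ties broken
    lexicographically) so footprints grow compactly: 1 px is a single
    pixel, 2 px a horizontal pair, etc.
    """
    if n_px < 1:
        raise SynthError("footprint must be >= 1 px")
    r = int(math.ceil(math.sqrt(n_px))) + 1
    pts = [(dr, dc) for dr in range(-r, r + 1) for dc in range(-r, r + 1)]
    pts.sort(key=lambda p: (p[0] ** 2 + p[1] ** 2, p[0], p[1]))
    return np.array(pts[:n_px], dtype=np.intp)


# ------------------------------------------------------------------- events
@dataclass(frozen=True)
class IlluminationEvent:
    """Global brightness step from ``frame`` onward (cloud edge)."""

    frame: int
    offset: float


@dataclass(frozen=True)
class WindEvent:
    """Coherent zero-mean fluctuation over a box while active."""

    start: int
    stop: int
    center: tuple[int, int]
    area_fraction: float = 0.2
    amplitude: float = 8.0


@dataclass(frozen=True)
class WalkerEvent:
    """Animal crossing the scene; present only while inside the image."""

    start_frame: int
    start: tuple[int, int]
    velocity: tuple[float, float]  # px per frame
    size_px: int = 3
    contrast: float = 40.0


@dataclass(frozen=True)
class SitterEvent:
    """Animal dwelling in place with small per-frame jitter."""

    start_frame: int
    position: tuple[int, int]
    dwell: int = 10
    jitter_px: int = 1
    size_px: int = 3
    contrast: float = 40.0


@dataclass(frozen=True)
class DropEvent:
    """Sudden persistent small object — the simulated strike.

    ``contrast`` is a positive magnitude in gray levels; the generator
    applies the channel-appropriate sign (warm-on-cool for LWIR,
    dark-on-bright for VIS).  The same convention holds for walker and
    sitter contrasts.
    """

    frame: int
    position: tuple[int, int]
    footprint_px: int = 2
    contrast: float = 30.0
    tau: float = 300.0


@dataclass
class SceneSpec:
    """Full description of one synthetic monitoring sequence."""

    shape: tuple[int, int] = (64, 64)
    n_frames: int = 40
    frame_interval: float = 10.0
    channel: Channel = Channel.LWIR
    base_gray: float = 100.0
    texture_sigma: float = 8.0
    texture_scale: float = 3.0
    noise_sigma: float = 2.0
    illumination: list[IlluminationEvent] = field(default_factory=list)
    wind: list[WindEvent] = field(default_factory=list)
    walkers: list[WalkerEvent] = field(default_factory=list)
    sitters: list[SitterEvent] = field(default_factory=list)
    drops: list[DropEvent] = field(default_factory=list)
    jitter_translation: float = 0.0  # max |px| per frame
    jitter_rotation: float = 0.0  # max |deg| per frame
    seed: int = 0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        for ev in self.illumination + self.wind + self.walkers + self.sitters + self.drops:
            f = getattr(ev, "frame", getattr(ev, "start_frame", getattr(ev, "start", None)))
            if isinstance(f, tuple):
                f = None
            if f is not None and not (0 <= f < self.n_frames):
                raise SynthError(f"event frame {f} outside sequence of {self.n_frames}")
        # ambiguous ground truth: overlapping drop footprints
        taken: set[tuple[int, int]] = set()
        for d in self.drops:
            px = {
                (d.position[0] + dr, d.position[1] + dc)
                for dr, dc in footprint_offsets(d.footprint_px)
            }
            if taken & px:
                raise SynthError("overlapping drop footprints: ambiguous ground truth")
            taken |= px


@dataclass
class GroundTruth:
    """Event records and the per-frame nacelle transforms actually applied."""

    records: list[dict]
    frame_transforms: list[np.ndarray]  # 3x3 homogeneous, xy convention

    def drops(self) -> list[dict]:
        return [r for r in self.records if r["type"] == "drop"]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["type", "frame", "time", "row", "col", "footprint_px"]
            )
            writer.writeheader()
            for r in self.records:
                writer.writerow({k: r.get(k, "") for k in writer.fieldnames})


# ---------------------------------------------------------------- rendering
def _coherent_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Unit-variance spatially correlated noise field."""
    raw = ndi.gaussian_filter(rng.standard_normal(shape), scale, mode="reflect")
    std = raw.std()
    return raw / std if std > 0 else raw


def textured_background(
    shape: tuple[int, int],
    rng: np.random.Generator,
    base_gray: float = 100.0,
    sigma: float = 8.0,
    scale: float = 3.0,
) -> np.ndarray:
    """Static vegetation-like texture: smoothed noise around a base gray."""
    return base_gray + sigma * _coherent_field(rng, shape, scale)


def _stamp(img: np.ndarray, position, offsets: np.ndarray, value: float) -> None:
    h, w = img.shape
    rows = np.round(position[0] + offsets[:, 0]).astype(int)
    cols = np.round(position[1] + offsets[:, 1]).astype(int)
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    img[rows[ok], cols[ok]] += value


def _wind_box(ev: WindEvent, shape) -> tuple[slice, slice]:
    h, w = shape
    side = int(round(math.sqrt(ev.area_fraction * h * w)))
    r0 = max(0, ev.center[0] - side // 2)
    c0 = max(0, ev.center[1] - side // 2)
    return slice(r0, min(h, r0 + side)), slice(c0, min(w, c0 + side))


def generate_sequence(spec: SceneSpec) -> tuple[list[Frame], GroundTruth]:
    """Render a sequence and its ground truth from a scene spec."""
    rng = np.random.default_rng(spec.seed)
    background = textured_background(
        spec.shape, rng, spec.base_gray, spec.texture_sigma, spec.texture_scale
    )
    sign = 1.0 if spec.channel == Channel.LWIR else -1.0

    records: list[dict] = []
    for ev in spec.illumination:
        records.append({"type": "illumination", "frame": ev.frame,
                        "time": spec.t0 + ev.frame * spec.frame_interval})
    for ev in spec.wind:
        records.append({"type": "wind", "frame": ev.start,
                        "time": spec.t0 + ev.start * spec.frame_interval,
                        "row": ev.center[0], "col": ev.center[1]})
    for ev in spec.walkers:
        records.append({"type": "walker", "frame": ev.start_frame,
                        "time": spec.t0 + ev.start_frame * spec.frame_interval,
                        "row": ev.start[0], "col": ev.start[1],
                        "footprint_px": ev.size_px})
    for ev in spec.sitters:
        records.append({"type": "sitter", "frame": ev.start_frame,
                        "time": spec.t0 + ev.start_frame * spec.frame_interval,
                        "row": ev.position[0], "col": ev.position[1],
                        "footprint_px": ev.size_px})
    for ev in spec.drops:
        records.append({"type": "drop", "frame": ev.frame,
                        "time": spec.t0 + ev.frame * spec.frame_interval,
                        "row": ev.position[0], "col": ev.position[1],
                        "footprint_px": ev.footprint_px})

    # pre-draw per-(event, frame) randomness in a fixed order for determinism
    sitter_jitter = {
        (i, t): rng.integers(-ev.jitter_px, ev.jitter_px + 1, size=2)
        for i, ev in enumerate(spec.sitters)
        for t in range(ev.start_frame, min(ev.start_frame + ev.dwell, spec.n_frames))
    }

    frames: list[Frame] = []
    transforms: list[np.ndarray] = []
    h, w = spec.shape
    for t in range(spec.n_frames):
        time_s = spec.t0 + t * spec.frame_interval
        img = background.copy()

        for ev in spec.illumination:
            if t >= ev.frame:
                img += ev.offset

        for ev in spec.wind:
            if ev.start <= t < ev.stop:
                box = _wind_box(ev, spec.shape)
                field_ = _coherent_field(rng, img[box].shape, spec.texture_scale)
                img[box] += ev.amplitude * field_

        for ev in spec.walkers:
            dt = t - ev.start_frame
            if dt >= 0:
                pos = (ev.start[0] + dt * ev.velocity[0], ev.start[1] + dt * ev.velocity[1])
                if 0 <= pos[0] < h and 0 <= pos[1] < w:
                    _stamp(img, pos, footprint_offsets(ev.size_px), sign * ev.contrast)

        for i, ev in enumerate(spec.sitters):
            if ev.start_frame <= t < ev.start_frame + ev.dwell:
                jr, jc = sitter_jitter[(i, t)]
                pos = (ev.position[0] + jr, ev.position[1] + jc)
                _stamp(img, pos, footprint_offsets(ev.size_px), sign * ev.contrast)

        for ev in spec.drops:
            if t >= ev.frame:
                age = (t - ev.frame) * spec.frame_interval
                if spec.channel == Channel.LWIR:
                    contrast = cooling_curve(ev.contrast, ev.tau, age)
                else:
                    contrast = ev.contrast
                _stamp(img, ev.position, footprint_offsets(ev.footprint_px), sign * contrast)

        matrix = np.eye(3)
        if spec.jitter_translation > 0 or spec.jitter_rotation > 0:
            tx, ty = rng.uniform(-spec.jitter_translation, spec.jitter_translation, size=2)
            theta = math.radians(
                rng.uniform(-spec.jitter_rotation, spec.jitter_rotation)
            )
            cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
            center = _SkAffine(translation=(cx, cy)).params
            back = _SkAffine(translation=(-cx, -cy)).params
            rot = _SkAffine(rotation=theta, translation=(tx, ty)).params
            matrix = center @ rot @ back
            inv = _SkAffine(matrix=np.linalg.inv(matrix))
            img = _sk_warp(img, inverse_map=inv, order=1, mode="reflect", preserve_range=True)
        transforms.append(matrix)

        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

        img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        frames.append(
            Frame(pixels=img, timestamp=time_s, channel=spec.channel, frame_id=t)
        )
    return frames, GroundTruth(records=records, frame_transforms=transforms)


# ------------------------------------------------------------ scene factory
def benchmark_lwir_scene(seed: int, with_drop: bool = True) -> SceneSpec:
    """Standard thermal benchmark scene: one 2-px strike plus distractors.

    64x64 px, 40 frames at 10 s: a 3-px walker crosses early, a wind gust
    fluctuates a corner late, and (optionally) a 2-px object of 30 gray
    levels of contrast drops at frame 18 on a seed-derived position.  The
    matched no-drop scene (``with_drop=False``) contains the identical
    distractors for false-positive measurement.
    """
    pos_rng = np.random.default_rng([int(seed), 7])
    position = tuple(int(v) for v in pos_rng.integers(12, 52, size=2))
    drops = (
        [DropEvent(frame=18, position=position, footprint_px=2, contrast=30.0, tau=300.0)]
        if with_drop else []
    )
    return SceneSpec(
        shape=(64, 64),
        n_frames=40,
        channel=Channel.LWIR,
        seed=int(seed),
        walkers=[WalkerEvent(start_frame=2, start=(54, 1), velocity=(-1.0, 7.0),
                             size_px=3, contrast=40.0)],
        wind=[WindEvent(start=26, stop=34, center=(14, 47),
                        area_fraction=0.18, amplitude=8.0)],
        drops=drops,
    )


# ----------------------------------------------------------------- from YAML
_EVENT_TYPES = {
    "illumination": IlluminationEvent,
    "wind": WindEvent,
    "walkers": WalkerEvent,
    "sitters": SitterEvent,
    "drops": DropEvent,
}


def scene_from_dict(data: dict) -> SceneSpec:
    """Build a :class:`SceneSpec` from a plain mapping (e.g. parsed YAML)."""
    data = dict(data)
    kwargs: dict = {}
    for key, cls in _EVENT_TYPES.items():
        items = data.pop(key, [])
        events = []
        for item in items:
            item = dict(item)
            for fld in ("position", "start", "center", "velocity"):
                # "start" is a frame index for wind but a position for walkers
                if isinstance(item.get(fld), (list, tuple)):
                    item[fld] = tuple(item[fld])
            events.append(cls(**item))
        kwargs[key] = events
    if "shape" in data:
        data["shape"] = tuple(data["shape"])
    kwargs.update(data)
    return SceneSpec(**kwargs)
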