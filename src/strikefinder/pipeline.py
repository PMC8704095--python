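"""End-to-end detection over a frame sequence.

For every full stack position the stages run in fixed order: register all
frames to the newest frame, adjust brightness, compute the channel's
pixel score, adaptive-threshold it, generate candidate regions, and pass
each candidate through preselection and structural analysis.  Accepted
candidates become :class:`DetectionEvent`s; a dropped object remains
visible in consecutive stacks, so events repeating near a recent event
are merged (duplicate suppression).

Registration is estimated once per consecutive frame pair and composed
along the chain to the newest frame; a pair that cannot be registered
(untextured view) makes the affected stack positions skip with a logged
warning instead of crashing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .decision import (
    CandidateEvaluation,
    PreselectionThresholds,
    StructuralThresholds,
    Verdict,
    evaluate_candidate,
)
from .frames import Channel, Frame
from .photometry import normalize_stack
from .regions import adaptive_threshold, generate_regions
from .register import AffineTransform2D, RegistrationError, estimate_alignment, warp_to_reference
from .scoring import ScoringConfig, ShiftLUT, score_lwir, score_vis
from .stack import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "RegistrationConfig",
    "RegionConfig",
    "DetectorConfig",
    "DetectionEvent",
    "process_sequence",
    "events_to_jsonl",
    "events_to_dataframe",
]


@dataclass
class RegistrationConfig:
    enabled: bool = True
    min_keypoints: int = 10
    n_keypoints: int = 500
    residual_threshold: float = 2.0


@dataclass
class RegionConfig:
    """Thresholding and morphology parameters (None = channel default)."""

    block_size: int = 31
    offset: float | None = None  # 5 gray levels: >=3 sigma above score noise
    opening_radius: int | None = None  # VIS 1 (removes specks), LWIR 0 (1-px targets)
    dilate_iters: int | None = None  # VIS 3; LWIR 2 keeps regions compact
    gap_iters: int = 1

    def resolved(self, channel: Channel) -> "RegionConfig":
        vis = Channel(channel) == Channel.VIS
        return RegionConfig(
            block_size=self.block_size,
            offset=5.0 if self.offset is None else self.offset,
            opening_radius=(1 if vis else 0)
            if self.opening_radius is None else self.opening_radius,
            dilate_iters=(3 if vis else 2)
            if self.dilate_iters is None else self.dilate_iters,
            gap_iters=self.gap_iters,
        )


@dataclass
class DetectorConfig:
    """Complete, channel-aware configuration of the detector."""

    channel: Channel = Channel.LWIR
    half_size: int = 5
    exclude_middle: bool = False
    frame_interval: float = 10.0
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    photometry_enabled: bool | None = None  # None: VIS yes, LWIR no
    photometry_mode: str = "additive"
    alpha: float = 1.0
    lut_anchors: tuple = ShiftLUT().anchors
    regions: RegionConfig = field(default_factory=RegionConfig)
    preselection: PreselectionThresholds | None = None  # None: channel default
    structural: StructuralThresholds = field(default_factory=StructuralThresholds)
    dedup_window: int | None = None  # None: half_size
    dedup_radius_factor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)

    def resolved(self) -> "DetectorConfig":
        cfg = dataclasses.replace(self)
        cfg.regions = self.regions.resolved(self.channel)
        if cfg.preselection is None:
            cfg.preselection = PreselectionThresholds.for_channel(self.channel)
        if cfg.dedup_window is None:
            cfg.dedup_window = self.half_size
        return cfg

    # ------------------------------------------------------------- YAML I/O
    @classmethod
    def for_channel(cls, channel: Channel | str, **overrides) -> "DetectorConfig":
        return cls(channel=Channel(channel), **overrides)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Channel):
                return obj.value
            if isinstance(obj, tuple):
                return [plain(v) for v in obj]
            return obj

        data = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        data["channel"] = self.channel.value
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "registration" in data and isinstance(data["registration"], dict):
            data["registration"] = RegistrationConfig(**data["registration"])
        if "regions" in data and isinstance(data["regions"], dict):
            data["regions"] = RegionConfig(**data["regions"])
        if isinstance(data.get("preselection"), dict):
            data["preselection"] = PreselectionThresholds(**data["preselection"])
        if isinstance(data.get("structural"), dict):
            data["structural"] = StructuralThresholds(**data["structural"])
        if "lut_anchors" in data:
            data["lut_anchors"] = tuple(tuple(a) for a in data["lut_anchors"])
        return cls(**data)


@dataclass
class DetectionEvent:
    """An accepted candidate: when, where, and why it was accepted."""

    timestamp: float
    frame_id: int
    centroid: tuple[float, float]
    area: int
    channel: Channel
    criteria: dict
    sdiffs: list[float]

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "frame_id": self.frame_id,
            "row": self.centroid[0],
            "col": self.centroid[1],
            "area": self.area,
            "channel": self.channel.value,
            "criteria": self.criteria,
            "sdiffs": self.sdiffs,
        }


def _compose_to_newest(
    frames: list[Frame],
    pair_transforms: dict[int, AffineTransform2D | None],
) -> list[AffineTransform2D] | None:
    """Transforms mapping each frame to the newest frame's coordinates.

    ``pair_transforms[fid]`` maps frame ``fid - 1``'s coordinates onto
    frame ``fid``'s.  Returns None when any link in the chain is missing.
    """
    out: list[AffineTransform2D | None] = [None] * len(frames)
    out[-1] = AffineTransform2D.identity()
    acc = AffineTransform2D.identity()
    for i in range(len(frames) - 1, 0, -1):
        link = pair_transforms.get(frames[i].frame_id)
        if link is None:
            return None
        acc = acc.compose(link)
        out[i - 1] = acc
    return out  # type: ignore[return-value]


def process_sequence(
    frames: Iterable[Frame],
    config: DetectorConfig,
) -> list[DetectionEvent]:
    """Run the full detector over a frame sequence.

    Deterministic for identical frames, config, and seed.  Returns one
    event per accepted, de-duplicated candidate.
    """
    cfg = config.resolved()
    stack = ImageStack(
        half_size=cfg.half_size,
        exclude_middle=cfg.exclude_middle,
        frame_interval=cfg.frame_interval,
    )
    scoring_cfg = ScoringConfig(
        channel=cfg.channel, alpha=cfg.alpha, lut=ShiftLUT(anchors=tuple(map(tuple, cfg.lut_anchors)))
    )
    pair_transforms: dict[int, AffineTransform2D | None] = {}
    events: list[DetectionEvent] = []
    recent: list[tuple[int, tuple[float, float], float]] = []  # (position idx, centroid, diag)
    prev_frame: Frame | None = None
    position = 0

    for frame in frames:
        if cfg.registration.enabled and prev_frame is not None:
            try:
                pair_transforms[frame.frame_id] = estimate_alignment(
                    prev_frame,
                    frame,
                    min_keypoints=cfg.registration.min_keypoints,
                    n_keypoints=cfg.registration.n_keypoints,
                    residual_threshold=cfg.registration.residual_threshold,
                    rng=(cfg.seed * 1_000_003 + frame.frame_id) % (2**31 - 1),
                )
            except RegistrationError as exc:
                logger.warning("registration failed at frame %d: %s", frame.frame_id, exc)
                pair_transforms[frame.frame_id] = None
        prev_frame = frame
        stack.push(frame)
        if not stack.is_full:
            continue
        position += 1

        t_start = time.perf_counter()
        raw = list(stack.frames)
        if cfg.registration.enabled:
            chain = _compose_to_newest(raw, pair_transforms)
            if chain is None:
                logger.warning(
                    "skipping stack position at frame %d: incomplete registration chain",
                    frame.frame_id,
                )
                continue
            registered = [
                f if np.allclose(tf.matrix, np.eye(3), atol=1e-12)
                else warp_to_reference(f, tf)
                for f, tf in zip(raw, chain)
            ]
            work = stack.replace_frames(registered)
        else:
            work = stack.replace_frames(raw)

        work = normalize_stack(work, enabled=cfg.photometry_enabled, mode=cfg.photometry_mode)
        if cfg.channel == Channel.VIS:
            score = score_vis(work, scoring_cfg)
        else:
            score = score_lwir(work)

        binary = adaptive_threshold(score, cfg.regions.block_size, cfg.regions.offset)
        region_set = generate_regions(
            binary,
            opening_radius=cfg.regions.opening_radius,
            dilate_iters=cfg.regions.dilate_iters,
            gap_iters=cfg.regions.gap_iters,
        )

        for region in region_set:
            ev = evaluate_candidate(
                region, work, score, cfg.preselection, cfg.structural, channel=cfg.channel
            )
            if ev.verdict != Verdict.DETECTED:
                continue
            centroid = region.centroid
            diag = region.bbox_diagonal
            duplicate = False
            for pos0, c0, d0 in recent:
                if position - pos0 > cfg.dedup_window:
                    continue
                dist = float(np.hypot(centroid[0] - c0[0], centroid[1] - c0[1]))
                if dist <= cfg.dedup_radius_factor * max(diag, d0):
                    duplicate = True
                    break
            if duplicate:
                logger.info(
                    "merged duplicate candidate at (%.1f, %.1f), frame %d",
                    centroid[0], centroid[1], frame.frame_id,
                )
                continue
            middle_frame = list(stack.frames)[stack.half_size]
            events.append(
                DetectionEvent(
                    timestamp=middle_frame.timestamp,
                    frame_id=middle_frame.frame_id,
                    centroid=centroid,
                    area=region.area,
                    channel=cfg.channel,
                    criteria=dict(ev.criterion_values),
                    sdiffs=[float(s) for s in (ev.sdiff_series if ev.sdiff_series is not None else [])],
                )
            )
            recent.append((position, centroid, diag))

        recent = [r for r in recent if position - r[0] <= cfg.dedup_window]
        logger.debug(
            "stack position %d (frame %d): %d candidates, %.1f ms",
            position, frame.frame_id, len(region_set),
            1e3 * (time.perf_counter() - t_start),
        )
    return events


def events_to_jsonl(events: list[DetectionEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict()) + "\n")


def events_to_dataframe(events: list[DetectionEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "timestamp": ev.timestamp,
            "frame_id": ev.frame_id,
            "row": ev.centroid[0],
            "col": ev.centroid[1],
            "area": ev.area,
            "channel": ev.channel.value,
        }
        row.update({f"criterion_{k}": v for k, v in ev.criteria.items()})
        rows.append(row)
    return pd.DataFrame(rows)
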