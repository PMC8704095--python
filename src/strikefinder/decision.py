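"""Detection decision: preselection criteria and structural analysis.

Candidates surviving region generation pass two filter banks:

1. **Preselection** — cheap checks that discard unrealistic candidates
   before the more expensive structural analysis: the inner area must be
   within channel-specific limits; the inner pixels must be discernible
   from the old frames (over time) and from the surrounding annulus (over
   space) by their median gray value; and the average absolute score in a
   wider surround must be low, because wind gusts tilt the grass and
   spread high scores over a large area around a candidate.

2. **Structural analysis** — the structural similarity (SSIM) of the full
   region's pixel vector between consecutive time steps.  A genuine
   strike changes the region's structure exactly once, at the middle
   frame pair, so its structural difference SDIFF = 1 - SSIM must be high
   at the middle pair, low at every side pair, and high relative to the
   largest side value.  Illumination drifts (content unchanged at the
   middle pair) fail the first rule; sitting, slightly moving animals
   (content changing at side pairs too) fail the second.

SSIM is computed on gray values normalized to [0, 1] with the usual
stabilizers; the C2 stabilizer dominates for near-constant patches and
keeps sensor noise from drowning the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.ndimage as ndi

from .frames import Channel
from .regions import Region
from .scoring import ScoreMap
from .stack import ImageStack

__all__ = [
    "PreselectionThresholds",
    "StructuralThresholds",
    "Verdict",
    "CandidateEvaluation",
    "DecisionError",
    "ssim",
    "preselect",
    "sdiff_series",
    "structural_decision",
    "evaluate_candidate",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class DecisionError(ValueError):
    pass


class Verdict(str, Enum):
    REJECTED_PRESELECTION = "rejected_preselection"
    REJECTED_STRUCTURAL = "rejected_structural"
    DETECTED = "detected"


@dataclass
class PreselectionThresholds:
    """Thresholds for the four preselection criteria.

    ``surround_radius=None`` derives the surround distance per candidate
    as 3x the full region's bounding-box diagonal.
    """

    area_min: int = 1
    area_max: int = 100
    temporal_discernibility_min: float = 11.0
    spatial_discernibility_min: float = 11.0
    surround_score_max: float = 2.9
    surround_radius: int | None = None

    def __post_init__(self) -> None:
        if self.area_min > self.area_max:
            raise DecisionError("area_min must be <= area_max")

    @classmethod
    def for_channel(cls, channel: Channel) -> "PreselectionThresholds":
        """Channel defaults.

        LWIR values follow the field-calibrated operating point (area 1-100 px,
        discernibilities > 11 gray levels, surround score < 2.9).  The VIS
        values are unvalidated defaults scaled to the ~7x finer ground
        sampling of that camera.
        """
        if Channel(channel) == Channel.LWIR:
            return cls()
        return cls(area_min=4, area_max=4000)


@dataclass
class StructuralThresholds:
    """Thresholds and stabilizers for the structural criteria.

    ``c2=0.03`` is the SSIM variance stabilizer on the normalized [0, 1]
    gray scale; ``c1`` only guards the zero-mean degeneracy.  The SDIFF
    thresholds are first-class configuration: with C2 = 0.03 a small
    target of 15-30 gray levels of contrast shifts the region variance by
    much less than C2, so genuine middle SDIFFs sit in the 0.02-0.5 range
    depending on target size — the default floor of 0.015 keeps 1-2 px
    thermal targets detectable while the side ceiling and the quotient
    carry the discrimination.
    """

    middle_sdiff_min: float = 0.015
    side_sdiff_max: float = 0.05
    sdiff_quotient_min: float = 3.0
    c1: float = 1e-4
    c2: float = 0.03

    def __post_init__(self) -> None:
        for name in ("middle_sdiff_min", "side_sdiff_max", "sdiff_quotient_min", "c1", "c2"):
            if getattr(self, name) <= 0:
                raise DecisionError(f"{name} must be positive")


@dataclass
class CandidateEvaluation:
    """Criteria record of one candidate region."""

    region: Region
    criterion_values: dict = field(default_factory=dict)
    sdiff_series: np.ndarray | None = None
    verdict: Verdict | None = None
    rejection_reason: str | None = None


# --------------------------------------------------------------------- SSIM
def ssim(x, y, c1: float = 1e-4, c2: float = 0.03) -> float:
    """Structural similarity of two equal-length gray-value vectors.

    Inputs are expected on the normalized [0, 1] scale.  Uses population
    variance and covariance over the region's pixels; the region may be
    any shape (the vectors are flat pixel lists).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise DecisionError("ssim inputs must have equal length")
    if x.size < 2:
        raise DecisionError("ssim needs at least 2 pixels")
    mx = x.mean()
    my = y.mean()
    dx = x - mx
    dy = y - my
    vx = (dx * dx).mean()
    vy = (dy * dy).mean()
    cov = (dx * dy).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


# ------------------------------------------------------------- preselection
def _pooled_median(frames, coords: np.ndarray) -> float:
    rows, cols = coords[:, 0], coords[:, 1]
    vals = np.concatenate([f.pixels[rows, cols] for f in frames])
    return float(np.median(vals))


def _surround_mean_score(region: Region, score: ScoreMap, radius: int | None) -> float:
    if radius is None:
        radius = max(1, math.ceil(3.0 * region.bbox_diagonal))
    full_m = region.mask(score.values.shape, "full")
    ring = ndi.binary_dilation(full_m, structure=_STRUCT8, iterations=int(radius))
    ring &= ~full_m & score.mask
    if not ring.any():
        return 0.0
    return float(np.abs(score.values[ring]).mean())


def preselect(
    region: Region,
    stack: ImageStack,
    score: ScoreMap,
    thresholds: PreselectionThresholds,
    channel: Channel | None = None,
) -> CandidateEvaluation:
    """Apply the four preselection criteria to one candidate region.

    Criteria are evaluated cheapest-first with early exit; the returned
    evaluation carries the values computed so far and, on failure, the
    name of the first failing criterion.  The discernibility sign assumes
    warm-on-cool for the thermal channel and dark-on-bright for VIS.
    """
    channel = Channel(channel if channel is not None else stack.channel)
    sign = 1.0 if channel == Channel.LWIR else -1.0
    ev = CandidateEvaluation(region=region)
    old, new = stack.split_halves()

    # 1: area within limits
    ev.criterion_values["area"] = region.area
    if not (thresholds.area_min <= region.area <= thresholds.area_max):
        ev.verdict = Verdict.REJECTED_PRESELECTION
        ev.rejection_reason = (
            f"area {region.area} outside [{thresholds.area_min}, {thresholds.area_max}]"
        )
        return ev

    # 2: discernibility over time
    temporal = sign * (_pooled_median(new, region.inner) - _pooled_median(old, region.full))
    ev.criterion_values["temporal_discernibility"] = temporal
    if temporal <= thresholds.temporal_discernibility_min:
        ev.verdict = Verdict.REJECTED_PRESELECTION
        ev.rejection_reason = (
            f"temporal discernibility {temporal:.2f} <= "
            f"{thresholds.temporal_discernibility_min}"
        )
        return ev

    # 3: spatial discernibility
    if len(region.outer) == 0:
        ev.verdict = Verdict.REJECTED_PRESELECTION
        ev.rejection_reason = "outer region empty; spatial discernibility incomputable"
        return ev
    spatial = sign * (_pooled_median(new, region.inner) - _pooled_median(new, region.outer))
    ev.criterion_values["spatial_discernibility"] = spatial
    if spatial <= thresholds.spatial_discernibility_min:
        ev.verdict = Verdict.REJECTED_PRESELECTION
        ev.rejection_reason = (
            f"spatial discernibility {spatial:.2f} <= "
            f"{thresholds.spatial_discernibility_min}"
        )
        return ev

    # 4: average score in the surrounding region (wind rejection)
    surround = _surround_mean_score(region, score, thresholds.surround_radius)
    ev.criterion_values["surround_score"] = surround
    if surround >= thresholds.surround_score_max:
        ev.verdict = Verdict.REJECTED_PRESELECTION
        ev.rejection_reason = (
            f"surround score {surround:.2f} >= {thresholds.surround_score_max}"
        )
        return ev

    return ev  # verdict None: preselection passed


# --------------------------------------------------------------- structural
def sdiff_series(
    region: Region,
    stack: ImageStack,
    thresholds: StructuralThresholds,
    max_masked_fraction: float = 0.2,
) -> np.ndarray:
    """SDIFF = 1 - SSIM of the full region between consecutive frames.

    One value per consecutive pair over the whole stack (2N - 1 values).
    Gray values are normalized to [0, 1] before comparison.  Raises when
    more than ``max_masked_fraction`` of the region is masked in any
    frame.
    """
    frames = list(stack.frames)
    rows, cols = region.full[:, 0], region.full[:, 1]
    vectors = []
    for f in frames:
        valid = f.mask[rows, cols]
        if valid.mean() < 1.0 - max_masked_fraction:
            raise DecisionError(
                f"region masked beyond {max_masked_fraction:.0%} in frame {f.frame_id}"
            )
        vectors.append(f.pixels[rows, cols] / 255.0)
    return np.array(
        [1.0 - ssim(a, b, thresholds.c1, thresholds.c2) for a, b in zip(vectors, vectors[1:])]
    )


def structural_decision(
    sdiffs: np.ndarray,
    thresholds: StructuralThresholds,
) -> tuple[bool, str | None, dict]:
    """Apply the three structural criteria to an SDIFF series.

    The series must have odd length so the middle pair (the assumed
    strike transition) is well defined.  Returns (detected, rejection
    reason, criterion values).  A zero side maximum makes the quotient
    +inf, which passes the quotient criterion whenever the middle
    criterion passes.
    """
    sdiffs = np.asarray(sdiffs, dtype=np.float64)
    if sdiffs.ndim != 1 or len(sdiffs) % 2 == 0 or len(sdiffs) < 3:
        raise DecisionError("SDIFF series must be 1-D with odd length >= 3")
    mid_idx = len(sdiffs) // 2
    middle = float(sdiffs[mid_idx])
    sides = np.delete(sdiffs, mid_idx)
    side_max = float(sides.max())
    quotient = middle / side_max if side_max > 0 else float("inf")
    values = {"middle_sdiff": middle, "side_sdiff_max": side_max, "sdiff_quotient": quotient}

    if middle <= thresholds.middle_sdiff_min:
        return False, (
            f"middle SDIFF {middle:.4f} <= {thresholds.middle_sdiff_min}"
        ), values
    if side_max >= thresholds.side_sdiff_max:
        return False, (
            f"max side SDIFF {side_max:.4f} >= {thresholds.side_sdiff_max}"
        ), values
    if quotient <= thresholds.sdiff_quotient_min:
        return False, (
            f"SDIFF quotient {quotient:.2f} <= {thresholds.sdiff_quotient_min}"
        ), values
    return True, None, values


def evaluate_candidate(
    region: Region,
    stack: ImageStack,
    score: ScoreMap,
    preselection: PreselectionThresholds,
    structural: StructuralThresholds,
    channel: Channel | None = None,
) -> CandidateEvaluation:
    """Full decision for one candidate: preselection, then structure."""
    ev = preselect(region, stack, score, preselection, channel=channel)
    if ev.verdict is not None:
        return ev
    try:
        sdiffs = sdiff_series(region, stack, structural)
    except DecisionError as exc:
        ev.verdict = Verdict.REJECTED_STRUCTURAL
        ev.rejection_reason = str(exc)
        return ev
    ev.sdiff_series = sdiffs
    detected, reason, values = structural_decision(sdiffs, structural)
    ev.criterion_values.update(values)
    ev.verdict = Verdict.DETECTED if detected else Verdict.REJECTED_STRUCTURAL
    ev.rejection_reason = reason
    return ev
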