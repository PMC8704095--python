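"""Per-pixel strike scores for the current image stack.

The ideal strike signature at a pixel is a sudden, persistent step between
the two stack halves: constant gray before, a different constant gray
after.  Two channel-specific scores capture this:

* VIS: the magnitude of the step at the middle frame pair, passed through
  a gray-difference lookup table, minus temporal-variation penalties —
  the mean absolute consecutive difference within each half, weighted by
  ``alpha``.  Moving grass or walking animals alternate within a half and
  are penalized; a clean step is not.

* LWIR: the difference of the temporal medians of the new and old halves.
  The median discards transient outliers such as an animal crossing the
  scene, which matters at thermal resolution where an animal is 1-3
  pixels.

Scores are signed so that larger means more fatality-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frames import Channel
from .stack import ImageStack, StackError

__all__ = ["ShiftLUT", "ScoringConfig", "ScoreMap", "ScoringError", "score_vis", "score_lwir"]

#: Default gray-difference response anchors for the VIS score.
#: Identity through the informative 15-30 gray-level band (the contrast an
#: artificial collision victim typically produces), flat above 70 — large
#: differences are very rarely fatalities and must not be overestimated.
#: The printed endpoint anchor maps a maximal difference of 255 to 70.
DEFAULT_LUT_ANCHORS: tuple[tuple[float, float], ...] = ((0.0, 0.0), (70.0, 70.0), (255.0, 70.0))


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ShiftLUT:
    """Piecewise-linear lookup table reshaping the gray-difference scale.

    Anchor inputs must be strictly increasing and cover [0, 255]; the
    output is linearly interpolated between anchors.
    """

    anchors: tuple[tuple[float, float], ...] = DEFAULT_LUT_ANCHORS

    def __post_init__(self) -> None:
        xs = [a[0] for a in self.anchors]
        if len(xs) < 2 or any(b <= a for a, b in zip(xs, xs[1:])):
            raise ScoringError("LUT anchor inputs must be strictly increasing")
        if xs[0] != 0 or xs[-1] != 255:
            raise ScoringError("LUT anchors must cover [0, 255]")

    def __call__(self, d):
        d = np.asarray(d, dtype=np.float64)
        if np.any(d < 0) or np.any(d > 255):
            raise ScoringError("gray difference outside [0, 255]")
        xs = np.array([a[0] for a in self.anchors])
        ys = np.array([a[1] for a in self.anchors])
        out = np.interp(d, xs, ys)
        return float(out) if out.ndim == 0 else out


@dataclass
class ScoringConfig:
    """Channel, temporal-penalty weight and LUT for the pixel score."""

    channel: Channel = Channel.VIS
    alpha: float = 1.0
    lut: ShiftLUT = field(default_factory=ShiftLUT)

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        if self.alpha < 0:
            raise ScoringError("alpha must be >= 0")


@dataclass
class ScoreMap:
    """Per-pixel strike score aligned with the stack's frames."""

    values: np.ndarray
    mask: np.ndarray
    channel: Channel

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ScoringError("score and mask shapes differ")


def _penalty(frames, alpha: float) -> np.ndarray:
    """Mean absolute consecutive difference within one half, times alpha."""
    cube = ImageStack.cube(frames)
    diffs = np.abs(np.diff(cube, axis=0))
    return alpha * diffs.mean(axis=0)


def score_vis(stack: ImageStack, config: ScoringConfig | None = None) -> ScoreMap:
    """VIS strike score: LUT(step magnitude) minus temporal penalties.

    The step is |I_T - I_{T-1}| per pixel (a VIS fatality darkens the
    NIR-bright vegetation, but the magnitude is scored so the convention
    is contrast-agnostic).  Penalty sums run over consecutive pairs within
    each half only; the middle pair contributes solely to the step term.
    """
    config = config or ScoringConfig(channel=Channel.VIS)
    old, new = stack.split_halves()
    if len(old) < 2 or len(new) < 2:
        raise ScoringError("halves too short for temporal penalties (need N >= 2)")
    prev, cur = stack.middle_pair()
    step = np.abs(cur.pixels - prev.pixels)
    values = config.lut(step) - _penalty(new, config.alpha) - _penalty(old, config.alpha)
    mask = stack.joint_mask()
    values = np.where(mask, values, 0.0)
    return ScoreMap(values=values, mask=mask, channel=Channel.VIS)


def score_lwir(stack: ImageStack) -> ScoreMap:
    """LWIR strike score: temporal median of new half minus old half."""
    if not stack.is_full:
        raise StackError("stack not full")
    old, new = stack.split_halves()
    values = np.median(ImageStack.cube(new), axis=0) - np.median(ImageStack.cube(old), axis=0)
    mask = stack.joint_mask()
    values = np.where(mask, values, 0.0)
    return ScoreMap(values=values, mask=mask, channel=Channel.LWIR)
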