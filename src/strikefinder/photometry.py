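"""Global brightness compensation between frames of a stack.

Clouds moving in front of the sun change the brightness of the whole VIS
image between the compared time steps.  The compensation shifts each
frame so that its median gray value matches the reference frame's: the
median tracks the (dominant) background, so a small dark object — a
potential fatality covering a few dozen pixels — is an outlier and does
not influence the offset.  Histogram equalization is deliberately not
used: redistributing gray values based on another image destroys the
meaning of absolute value differences that the region analysis relies on.

The thermal channel bypasses brightness adjustment by default because its
gain control happens in-camera.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import Channel, Frame
from .stack import ImageStack

__all__ = ["BrightnessAdjustment", "PhotometryError", "adjust_median", "normalize_stack"]


class PhotometryError(ValueError):
    pass


@dataclass(frozen=True)
class BrightnessAdjustment:
    """Record of one brightness compensation."""

    offset: float
    reference_median: float
    subject_median: float
    mode: str = "additive"


def adjust_median(
    subject: Frame,
    reference: Frame,
    mode: str = "additive",
) -> tuple[Frame, BrightnessAdjustment]:
    """Shift ``subject`` so its valid-pixel median matches ``reference``'s.

    Additive by default; a multiplicative variant is available for
    experimentation.  Operates in floating point (re-quantization happens
    only at I/O boundaries) and clips to the valid gray range.
    """
    if subject.shape != reference.shape or subject.channel != reference.channel:
        raise PhotometryError("subject and reference must share shape and channel")
    if not subject.mask.any() or not reference.mask.any():
        raise PhotometryError("all pixels masked; median undefined")

    med_s = float(np.median(subject.valid_values()))
    med_r = float(np.median(reference.valid_values()))

    if mode == "additive":
        offset = med_r - med_s
        adjusted = subject.pixels + offset
    elif mode == "multiplicative":
        if med_s <= 0:
            raise PhotometryError("multiplicative adjustment needs positive subject median")
        offset = med_r / med_s
        adjusted = subject.pixels * offset
    else:
        raise PhotometryError(f"unknown mode {mode!r}")

    out = subject.with_pixels(np.clip(adjusted, 0.0, 255.0))
    return out, BrightnessAdjustment(
        offset=offset, reference_median=med_r, subject_median=med_s, mode=mode,
    )


def normalize_stack(
    stack: ImageStack,
    enabled: bool | None = None,
    mode: str = "additive",
    reference_index: int = -1,
) -> ImageStack:
    """Median-adjust every frame of a full stack to its reference frame.

    ``enabled=None`` resolves per channel: the VIS channel is adjusted, the
    LWIR channel is passed through unchanged (in-camera gain control).  The
    reference defaults to the newest frame, the same frame registration
    aligns to.
    """
    if not stack.is_full:
        raise PhotometryError("stack must be full before normalization")
    frames = list(stack.frames)
    if enabled is None:
        enabled = frames[0].channel == Channel.VIS
    if not enabled:
        return stack.replace_frames(frames)

    reference = frames[reference_index]
    adjusted = []
    for f in frames:
        if f is reference:
            adjusted.append(f)
        else:
            out, _ = adjust_median(f, reference, mode=mode)
            adjusted.append(out)
    return stack.replace_frames(adjusted)
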