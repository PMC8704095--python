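"""First-in-first-out temporal window of frames (the image stack).

A collision victim is defined, from the computer-vision point of view, as
an object present in all *new* frames of the stack and in none of the
*old* ones.  The stack therefore holds exactly ``2 * half_size`` frames;
the older half is *old*, the newer half is *new*, and the first frame of
the new half is the assumed strike frame T.
"""

from __future__ import annotations

import logging
from collections import deque

import numpy as np

from .frames import Frame

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "StackError"]


class StackError(ValueError):
    """Raised on invalid stack operations (mismatched frames, not full)."""


class ImageStack:
    """Rolling window of ``2 * half_size`` frames of one channel.

    Parameters
    ----------
    half_size:
        N, the number of frames per half; must be >= 2 so that the temporal
        variation penalties of the VIS score are defined.
    exclude_middle:
        When True the two frames straddling the stack midpoint are omitted
        from the half lists used for temporal statistics (penalty sums and
        LWIR medians).  The strike step term always compares the middle
        frame pair directly, so excluding the middle guards against
        catching the object mid-fall without losing the step itself.
    frame_interval:
        Nominal seconds between frames (metadata only; scoring is
        index-based).  Deviations beyond 50% are logged as warnings.
    """

    def __init__(
        self,
        half_size: int = 5,
        exclude_middle: bool = False,
        frame_interval: float = 10.0,
    ) -> None:
        if half_size < 2:
            raise StackError("half_size must be >= 2")
        if frame_interval <= 0:
            raise StackError("frame_interval must be positive")
        self.half_size = int(half_size)
        self.exclude_middle = bool(exclude_middle)
        self.frame_interval = float(frame_interval)
        self.frames: deque[Frame] = deque(maxlen=2 * self.half_size)

    # ------------------------------------------------------------------ basic
    def __len__(self) -> int:
        return len(self.frames)

    @property
    def capacity(self) -> int:
        return 2 * self.half_size

    @property
    def is_full(self) -> bool:
        return len(self.frames) == self.capacity

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.frames[0].shape if self.frames else None

    @property
    def channel(self):
        return self.frames[0].channel if self.frames else None

    def push(self, frame: Frame) -> "ImageStack":
        """Append a frame, evicting the oldest once the stack is full.

        Rejects frames whose shape or channel differ from the stack's, and
        frames whose timestamp is not strictly greater than the newest.
        """
        if self.frames:
            newest = self.frames[-1]
            if frame.shape != newest.shape:
                raise StackError(
                    f"frame shape {frame.shape} != stack shape {newest.shape}"
                )
            if frame.channel != newest.channel:
                raise StackError(
                    f"frame channel {frame.channel} != stack channel {newest.channel}"
                )
            dt = frame.timestamp - newest.timestamp
            if dt <= 0:
                raise StackError("timestamps must be strictly increasing")
            if abs(dt - self.frame_interval) > 0.5 * self.frame_interval:
                logger.warning(
                    "irregular frame interval %.2f s (nominal %.2f s) at frame %d",
                    dt, self.frame_interval, frame.frame_id,
                )
        self.frames.append(frame)
        return self

    # ---------------------------------------------------------------- halves
    def split_halves(self) -> tuple[list[Frame], list[Frame]]:
        """Return (old, new) frame lists; requires a full stack.

        With ``exclude_middle`` the last old frame and the first new frame
        are dropped from the returned lists.
        """
        if not self.is_full:
            raise StackError(
                f"stack holds {len(self)} of {self.capacity} frames; "
                "insufficient history"
            )
        frames = list(self.frames)
        n = self.half_size
        old, new = frames[:n], frames[n:]
        if self.exclude_middle:
            old, new = old[:-1], new[1:]
        return old, new

    def middle_pair(self) -> tuple[Frame, Frame]:
        """The (I_{T-1}, I_T) pair straddling the assumed strike."""
        if not self.is_full:
            raise StackError("stack not full")
        frames = list(self.frames)
        n = self.half_size
        return frames[n - 1], frames[n]

    # --------------------------------------------------------------- helpers
    def joint_mask(self) -> np.ndarray:
        """Pixels valid in every frame of the stack."""
        if not self.frames:
            raise StackError("empty stack")
        mask = np.ones(self.frames[0].shape, dtype=bool)
        for f in self.frames:
            mask &= f.mask
        return mask

    def replace_frames(self, frames: list[Frame]) -> "ImageStack":
        """New stack with the same parameters holding ``frames`` verbatim."""
        out = ImageStack(
            half_size=self.half_size,
            exclude_middle=self.exclude_middle,
            frame_interval=self.frame_interval,
        )
        out.frames.extend(frames)
        return out

    @staticmethod
    def cube(frames: list[Frame]) -> np.ndarray:
        """Stack frame pixel arrays along a leading time axis."""
        return np.stack([f.pixels for f in frames], axis=0)
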