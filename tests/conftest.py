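"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from strikefinder.frames import Channel, Frame
from strikefinder.stack import ImageStack


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_frame(
    pixels,
    frame_id: int = 0,
    channel: Channel = Channel.LWIR,
    timestamp: float | None = None,
    mask=None,
) -> Frame:
    return Frame(
        pixels=np.asarray(pixels, dtype=float),
        timestamp=10.0 * frame_id if timestamp is None else timestamp,
        channel=channel,
        frame_id=frame_id,
        mask=mask,
    )


def stack_from_arrays(arrays, channel: Channel = Channel.LWIR, half_size=None) -> ImageStack:
    """Build a full stack from a list of 2-D arrays (one per frame)."""
    if half_size is None:
        half_size = len(arrays) // 2
    stack = ImageStack(half_size=half_size)
    for i, arr in enumerate(arrays):
        stack.push(make_frame(arr, frame_id=i, channel=channel))
    return stack


def flat_series_stack(series, shape=(8, 8), channel: Channel = Channel.LWIR) -> ImageStack:
    """Stack whose every pixel follows the same gray-value time series."""
    return stack_from_arrays(
        [np.full(shape, float(v)) for v in series], channel=channel
    )
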