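"""Single-channel camera frames and on-disk sequence I/O.

A :class:`Frame` is one registered (or raw) grayscale image with a
timestamp and a channel tag.  Sequences on disk are directories of PNG or
TIFF files whose timestamps come either from ISO-8601-style file names
(``YYYYMMDDTHHMMSS.*``) or from a ``timestamps.csv`` sidecar with columns
``filename,unix_timestamp``.
"""

from __future__ import annotations

import calendar
import csv
import re
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "Channel",
    "Frame",
    "FrameError",
    "read_sequence",
    "write_sequence",
]


class Channel(str, Enum):
    """Sensing channel: visible/near-infrared (day) or thermal (night)."""

    VIS = "vis"
    LWIR = "lwir"


class FrameError(ValueError):
    """Raised for malformed frames (shape, range, mask mismatch)."""


@dataclass
class Frame:
    """One grayscale image with acquisition metadata.

    Parameters
    ----------
    pixels:
        2-D array of gray values in [0, 255].  Stored as float64 so that
        downstream photometric adjustments do not accumulate rounding; the
        8-bit quantization happens only at sequence I/O boundaries.
    timestamp:
        Seconds since epoch.
    channel:
        :class:`Channel` tag; fixed for a given sequence.
    frame_id:
        Monotone integer identifying the frame within its sequence.
    mask:
        Boolean validity map (True = valid).  Pixels warped in from outside
        the field of view are invalid and excluded from all statistics.
    """

    pixels: np.ndarray
    timestamp: float
    channel: Channel
    frame_id: int
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise FrameError("pixels must be a non-empty 2-D array")
        if np.nanmin(px) < 0 or np.nanmax(px) > 255:
            raise FrameError("gray values must lie within [0, 255]")
        self.pixels = px
        self.channel = Channel(self.channel)
        if self.mask is None:
            self.mask = np.ones(px.shape, dtype=bool)
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != px.shape:
                raise FrameError("mask shape must match pixels")
            self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def valid_fraction(self) -> float:
        return float(self.mask.mean())

    def valid_values(self) -> np.ndarray:
        """Gray values at valid pixels, flattened."""
        return self.pixels[self.mask]

    def with_pixels(self, pixels: np.ndarray, mask: np.ndarray | None = None) -> "Frame":
        """Copy of this frame with replaced pixel data (metadata kept)."""
        return Frame(
            pixels=pixels,
            timestamp=self.timestamp,
            channel=self.channel,
            frame_id=self.frame_id,
            mask=self.mask.copy() if mask is None else mask,
        )


_TS_PATTERN = re.compile(r"(\d{8}T\d{6})")


def _timestamp_from_name(name: str) -> float | None:
    m = _TS_PATTERN.search(name)
    if m is None:
        return None
    st = time.strptime(m.group(1), "%Y%m%dT%H%M%S")
    return float(calendar.timegm(st))


def read_sequence(
    directory: str | Path,
    channel: Channel | str,
    timestamps_csv: str | Path | None = None,
) -> list[Frame]:
    """Load a grayscale image sequence from a directory.

    PNG/TIFF files are read in timestamp order.  Timestamps are parsed from
    the file names where possible; otherwise a sidecar CSV (default
    ``<directory>/timestamps.csv``) with columns ``filename,unix_timestamp``
    is consulted.
    """
    directory = Path(directory)
    channel = Channel(channel)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise FrameError(f"no PNG/TIFF files found in {directory}")

    sidecar: dict[str, float] = {}
    csv_path = Path(timestamps_csv) if timestamps_csv else directory / "timestamps.csv"
    if csv_path.exists():
        with open(csv_path, newline="") as fh:
            for row in csv.DictReader(fh):
                sidecar[row["filename"]] = float(row["unix_timestamp"])

    records = []
    for p in paths:
        ts = sidecar.get(p.name)
        if ts is None:
            ts = _timestamp_from_name(p.name)
        if ts is None:
            raise FrameError(
                f"cannot determine timestamp for {p.name}: no ISO name, no sidecar entry"
            )
        records.append((ts, p))
    records.sort(key=lambda r: r[0])

    frames = []
    for fid, (ts, p) in enumerate(records):
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:  # collapse accidental RGB to gray
            img = img.mean(axis=2)
        frames.append(Frame(pixels=img, timestamp=ts, channel=channel, frame_id=fid))
    return frames


def write_sequence(frames: list[Frame], directory: str | Path) -> None:
    """Write frames as 8-bit PNGs plus a ``timestamps.csv`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in frames:
        name = f"frame_{f.frame_id:05d}.png"
        iio.imwrite(directory / name, np.clip(np.round(f.pixels), 0, 255).astype(np.uint8))
        rows.append((name, f.timestamp))
    with open(directory / "timestamps.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "unix_timestamp"])
        writer.writerows(rows)
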