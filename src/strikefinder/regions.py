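"""Candidate region generation from a score map.

Adaptive thresholding separates locally high scores from their
neighborhood (a global threshold fails when part of the image is shadowed
or the ground is unevenly heated).  Morphology then turns the binary map
into labeled candidate regions, each with three pixel sets:

* ``inner`` — the thresholded pixels themselves, the putative carcass;
* ``full``  — the inner pixels dilated to include their surroundings,
  labeled as one 8-connected component;
* ``outer`` — the full region minus a dilation of the inner pixels, i.e.
  the surrounding annulus, separated from the inner set by a gap.

The operation order (optional opening, dilation, labeling, then per-label
set algebra) guarantees equal numbers of inner, outer, and full regions —
morphological operations applied after labeling could otherwise change
the number of connected components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import disk

from .scoring import ScoreMap

__all__ = ["Region", "RegionSet", "RegionError", "adaptive_threshold", "generate_regions"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class RegionError(ValueError):
    pass


@dataclass
class Region:
    """One candidate region; coordinates are 0-based (row, col) arrays."""

    label: int
    inner: np.ndarray  # (k, 2) int
    outer: np.ndarray
    full: np.ndarray

    def __post_init__(self) -> None:
        for name in ("inner", "outer", "full"):
            arr = np.asarray(getattr(self, name), dtype=np.intp).reshape(-1, 2)
            setattr(self, name, arr)
        if len(self.inner) == 0:
            raise RegionError("inner region must be non-empty")

    @property
    def area(self) -> int:
        """Inner pixel count — the putative object size."""
        return len(self.inner)

    @property
    def centroid(self) -> tuple[float, float]:
        return tuple(self.inner.mean(axis=0))  # type: ignore[return-value]

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max) of the full region, inclusive."""
        mins = self.full.min(axis=0)
        maxs = self.full.max(axis=0)
        return int(mins[0]), int(mins[1]), int(maxs[0]), int(maxs[1])

    @property
    def bbox_diagonal(self) -> float:
        r0, c0, r1, c1 = self.bbox
        return float(np.hypot(r1 - r0 + 1, c1 - c0 + 1))

    def mask(self, shape: tuple[int, int], which: str = "full") -> np.ndarray:
        coords = getattr(self, which)
        m = np.zeros(shape, dtype=bool)
        m[coords[:, 0], coords[:, 1]] = True
        return m


@dataclass
class RegionSet:
    """All candidate regions of one stack evaluation (labels unique)."""

    regions: list[Region]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(labels) != len(set(labels)):
            raise RegionError("region labels must be unique")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]


def adaptive_threshold(score: ScoreMap, block_size: int = 31, offset: float = 5.0) -> np.ndarray:
    """Binary map: score exceeds its local block mean plus ``offset``.

    The local mean is computed over valid pixels only; masked pixels are
    never set.  ``block_size`` must be odd, >= 3 and smaller than both
    image sides.
    """
    if block_size % 2 == 0 or block_size < 3:
        raise RegionError("block_size must be odd and >= 3")
    if block_size >= min(score.values.shape):
        raise RegionError("block_size must be smaller than the image")
    vals = np.where(score.mask, score.values, 0.0)
    weight = score.mask.astype(np.float64)
    num = ndi.uniform_filter(vals, size=block_size, mode="reflect")
    den = ndi.uniform_filter(weight, size=block_size, mode="reflect")
    local_mean = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return (score.values > local_mean + offset) & score.mask


def generate_regions(
    binary: np.ndarray,
    opening_radius: int = 0,
    dilate_iters: int = 3,
    gap_iters: int = 1,
) -> RegionSet:
    """Label a binary map into candidate regions with inner/outer/full sets.

    Steps: (1) optional morphological opening removes clusters smaller
    than the structuring element (skip for the thermal channel, where a
    fatality can be a single pixel); (2) dilation connects nearby pixels
    and annexes the surround; (3) 8-connected labeling of the dilated map
    defines the full regions; (4) per label, inner = pre-dilation pixels
    inside the full region, outer = full minus a ``gap_iters``-wide
    dilation of inner.
    """
    if min(opening_radius, dilate_iters, gap_iters) < 0:
        raise RegionError("morphology parameters must be >= 0")
    binary = np.asarray(binary, dtype=bool)

    if opening_radius > 0:
        seeds = ndi.binary_opening(binary, structure=disk(opening_radius))
    else:
        seeds = binary
    if dilate_iters > 0:
        dilated = ndi.binary_dilation(seeds, structure=_STRUCT8, iterations=dilate_iters)
    else:
        dilated = seeds

    labels, n_labels = ndi.label(dilated, structure=_STRUCT8)
    regions: list[Region] = []
    for label, sl in zip(range(1, n_labels + 1), ndi.find_objects(labels)):
        full_m = labels[sl] == label
        inner_m = seeds[sl] & full_m
        if not inner_m.any():
            # defensive fallback: a full region always contains seed pixels
            # by construction, but keep a single-pixel inner if it does not
            rows, cols = np.nonzero(full_m)
            center = np.array([rows.mean(), cols.mean()])
            k = int(np.argmin(((np.column_stack([rows, cols]) - center) ** 2).sum(axis=1)))
            inner_m = np.zeros_like(full_m)
            inner_m[rows[k], cols[k]] = True
        if gap_iters > 0:
            grown = ndi.binary_dilation(inner_m, structure=_STRUCT8, iterations=gap_iters)
        else:
            grown = inner_m
        outer_m = full_m & ~grown

        origin = np.array([sl[0].start, sl[1].start])
        regions.append(
            Region(
                label=label,
                inner=np.argwhere(inner_m) + origin,
                outer=np.argwhere(outer_m) + origin,
                full=np.argwhere(full_m) + origin,
            )
        )
    return RegionSet(regions=regions)
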