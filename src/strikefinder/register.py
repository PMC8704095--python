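"""Frame-to-frame registration against nacelle motion.

The camera housing yaws with the wind and vibrates, so frames must be
aligned with pixel precision before any pixel-wise comparison.  Alignment
is keypoint-based: ORB keypoints and descriptors, brute-force descriptor
matching with cross-check, and a RANSAC-fitted full affine transform.
Grass and vegetation backgrounds are keypoint-rich; a near-uniform scene
(too few keypoints) raises :class:`RegistrationError` rather than
returning a bogus transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp as _sk_warp

from .frames import Frame

__all__ = ["AffineTransform2D", "RegistrationError", "estimate_alignment", "warp_to_reference"]


class RegistrationError(RuntimeError):
    """Raised when a scene cannot be registered (untextured, degenerate)."""


@dataclass
class AffineTransform2D:
    """A 2-D affine map in homogeneous (x, y) = (col, row) convention.

    ``matrix`` is 3x3 and maps moving-frame coordinates to reference-frame
    coordinates.  ``n_inliers`` and ``median_residual`` document the fit
    quality on the matched keypoints.
    """

    matrix: np.ndarray
    n_inliers: int = 0
    median_residual: float = float("nan")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("affine matrix must be 3x3 homogeneous")
        self.matrix = m

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix[:2, :2]))

    @property
    def is_singular(self) -> bool:
        return abs(self.determinant) < 1e-8

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(matrix=np.eye(3))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform2D(matrix=self.matrix @ other.matrix)

    def inverse(self) -> "AffineTransform2D":
        if self.is_singular:
            raise RegistrationError("cannot invert a singular transform")
        return AffineTransform2D(matrix=np.linalg.inv(self.matrix))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        homo = np.column_stack([xy, np.ones(len(xy))])
        out = homo @ self.matrix.T
        return out[:, :2] / out[:, 2:3]


def _detect(img: np.ndarray, n_keypoints: int) -> tuple[np.ndarray, np.ndarray]:
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    orb.detect_and_extract(img)
    return orb.keypoints, orb.descriptors


def estimate_alignment(
    moving: Frame,
    reference: Frame,
    min_keypoints: int = 10,
    n_keypoints: int = 500,
    residual_threshold: float = 2.0,
    max_trials: int = 500,
    rng: int | np.random.Generator | None = 0,
) -> AffineTransform2D:
    """Estimate the affine transform mapping ``moving`` onto ``reference``.

    Raises :class:`RegistrationError` when fewer than ``min_keypoints``
    keypoints, matches, or RANSAC inliers are available — the signature of
    an untextured scene that cannot be aligned reliably.

    The inlier band (``residual_threshold``) is deliberately wider than
    the 1 px accuracy goal: keypoints localize to whole pixels, and the
    final least-squares refit over a large inlier set is what brings the
    transform to subpixel accuracy.
    """
    if moving.shape != reference.shape:
        raise RegistrationError("frames must share shape")
    mov = moving.pixels / 255.0
    ref = reference.pixels / 255.0

    try:
        kp_m, desc_m = _detect(mov, n_keypoints)
        kp_r, desc_r = _detect(ref, n_keypoints)
    except (RuntimeError, ValueError, IndexError) as exc:
        raise RegistrationError(f"keypoint detection failed: {exc}") from exc
    if len(kp_m) < min_keypoints or len(kp_r) < min_keypoints:
        raise RegistrationError(
            f"too few keypoints ({len(kp_m)} / {len(kp_r)}, need {min_keypoints}): "
            "scene lacks texture"
        )

    matches = match_descriptors(desc_m, desc_r, cross_check=True)
    if len(matches) < min_keypoints:
        raise RegistrationError(f"too few descriptor matches ({len(matches)})")

    # keypoints are (row, col); geometric transforms expect (x, y)
    src = kp_m[matches[:, 0]][:, ::-1]
    dst = kp_r[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst),
        _SkAffine,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=max_trials,
        rng=rng,
    )
    if model is None or inliers is None or inliers.sum() < min_keypoints:
        n_in = 0 if inliers is None else int(inliers.sum())
        raise RegistrationError(f"RANSAC found only {n_in} inliers")

    residuals = model.residuals(src[inliers], dst[inliers])
    tform = AffineTransform2D(
        matrix=np.asarray(model.params),
        n_inliers=int(inliers.sum()),
        median_residual=float(np.median(residuals)),
    )
    if tform.is_singular:
        raise RegistrationError("estimated transform is singular")
    return tform


def warp_to_reference(frame: Frame, transform: AffineTransform2D) -> Frame:
    """Resample ``frame`` into reference coordinates.

    Out-of-view pixels are marked invalid in the returned frame's mask and
    are excluded from all downstream statistics.  Bilinear interpolation;
    a pixel is valid only if every source pixel it interpolates from was
    valid and inside the view.
    """
    if transform.is_singular:
        raise RegistrationError("singular transform")
    inv = _SkAffine(matrix=np.linalg.inv(transform.matrix))
    warped = _sk_warp(
        frame.pixels, inverse_map=inv, order=1, cval=0.0,
        preserve_range=True, mode="constant",
    )
    valid = _sk_warp(
        frame.mask.astype(np.float64), inverse_map=inv, order=1, cval=0.0,
        preserve_range=True, mode="constant",
    )
    mask = valid > 1.0 - 1e-9
    return frame.with_pixels(np.clip(warped, 0.0, 255.0), mask=mask)
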