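"""Pre-processing operators for fluorescein-angiography frame pairs.

The quantification pipeline applies, in this fixed order: rigid alignment of
the 5-min frame onto the 1-min reference, rolling-ball background
subtraction, a 384x384 fovea-centred crop, per-frame iterative-intermeans
("Default" dialect) auto-thresholding and binarization, and finally the
clamped binary subtraction that yields the leakage map.  Reordering (e.g.
thresholding before background subtraction) changes the scores and is not
supported.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.restoration import rolling_ball
from skimage.transform import SimilarityTransform, resize, warp

from .types import RigidTransform, as_gray_image, validate_binary

__all__ = [
    "AlignmentError",
    "align_pair",
    "rolling_ball_subtract",
    "crop_centered",
    "isodata_default_threshold",
    "binarize",
    "leakage_map",
]


class AlignmentError(RuntimeError):
    """Raised when too few feature correspondences support a transform."""


def _motion_from_matrix(matrix: np.ndarray, center_xy: np.ndarray) -> RigidTransform:
    """Summarise a 3x3 (x, y) similarity matrix as centre-anchored motion."""
    rot = float(np.degrees(np.arctan2(matrix[1, 0], matrix[0, 0])))
    scale = float(np.hypot(matrix[0, 0], matrix[1, 0]))
    moved = matrix[:2, :2] @ center_xy + matrix[:2, 2]
    dx, dy = moved - center_xy
    return RigidTransform(rotation_deg=rot, translation=(float(dy), float(dx)), scale=scale)


def align_pair(
    reference_1min: np.ndarray,
    moving_5min: np.ndarray,
    *,
    min_matches: int = 10,
    allow_scale: bool = True,
    residual_threshold: float = 1.0,
) -> tuple[np.ndarray, RigidTransform]:
    """Register the 5-min frame onto the 1-min reference.

    Scale/rotation-invariant keypoints (SIFT) are detected in both frames,
    matched by descriptor distance with cross-checking, and a similarity
    transform (rigid + optional uniform scale) is fitted by RANSAC.  The
    moving frame is resampled into the reference frame's coordinate system;
    pixels that fall outside the moving frame's field are filled with 0.

    Returns
    -------
    aligned : uint8 array, the resampled 5-min frame.
    motion : RigidTransform, the estimated apparent motion of the moving
        frame relative to the reference (rotation about the image centre in
        degrees, residual (dy, dx) shift of the centre in pixels).

    Raises
    ------
    AlignmentError
        If fewer than ``min_matches`` RANSAC-consistent correspondences are
        found.  Callers may catch this and fall back to the identity
        transform with a warning when the frames are known to be nearly
        registered.
    """
    ref = as_gray_image(reference_1min)
    mov = as_gray_image(moving_5min)
    if ref.shape != mov.shape:
        raise ValueError("frames must share a shape")

    det_ref, det_mov = SIFT(upsampling=1), SIFT(upsampling=1)
    try:
        det_ref.detect_and_extract(ref)
        det_mov.detect_and_extract(mov)
    except RuntimeError as exc:  # no keypoints at all
        raise AlignmentError(f"feature detection failed: {exc}") from exc

    matches = match_descriptors(
        det_ref.descriptors, det_mov.descriptors, max_ratio=0.8, cross_check=True
    )
    if len(matches) < min_matches:
        raise AlignmentError(
            f"only {len(matches)} feature correspondences (need {min_matches})"
        )

    # (row, col) keypoints -> (x, y) for the geometric fit
    ref_xy = det_ref.keypoints[matches[:, 0]][:, ::-1].astype(float)
    mov_xy = det_mov.keypoints[matches[:, 1]][:, ::-1].astype(float)
    tform_cls = SimilarityTransform if allow_scale else _EuclideanAsSimilarity
    # model maps moving-frame coords -> reference coords
    model, inliers = ransac(
        (mov_xy, ref_xy),
        tform_cls,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=1000,
        rng=0,
    )
    if model is None or inliers is None or inliers.sum() < min_matches:
        n = 0 if inliers is None else int(inliers.sum())
        raise AlignmentError(f"only {n} RANSAC inliers (need {min_matches})")

    aligned = warp(
        mov.astype(np.float64), model.inverse, order=1, cval=0.0, preserve_range=True
    )
    aligned8 = np.clip(np.round(aligned), 0, 255).astype(np.uint8)

    rows, cols = ref.shape
    center_xy = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    motion = _motion_from_matrix(np.linalg.inv(model.params), center_xy)
    return aligned8, motion


class _EuclideanAsSimilarity(SimilarityTransform):
    """Similarity transform constrained to unit scale during estimation."""

    def estimate(self, src, dst):
        ok = super().estimate(src, dst)
        if ok:
            s = np.hypot(self.params[0, 0], self.params[1, 0])
            self.params[:2, :2] /= s
        return ok


def _ball_structure(radius: float) -> np.ndarray:
    """Height profile of a ball cap of the given radius (nonflat SE)."""
    r = int(np.ceil(radius))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = x * x + y * y
    h = np.sqrt(np.maximum(radius * radius - d2, 0.0))
    h[d2 > radius * radius] = -np.inf  # outside the support
    return h


def _shrink_factor(radius_px: int) -> int:
    # classical staircase used by the shrink-roll-expand approximation
    if radius_px <= 10:
        return 1
    if radius_px <= 30:
        return 2
    if radius_px <= 100:
        return 4
    return 8


def rolling_ball_subtract(img: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Remove the smooth background by the rolling-ball principle.

    The background is the envelope of a ball of ``radius_px`` rolled under
    the intensity surface (a grayscale opening by a ball-shaped structuring
    element).  For speed the classical approximation is used: the frame is
    lightly smoothed (3x3 mean), down-scaled by a radius-dependent factor,
    the exact ball roll is performed on the small copy, and the background
    is expanded back and clipped to never exceed the original frame.  The
    result is ``img`` minus that background, clamped to [0, 255].
    """
    a = as_gray_image(img)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    af = a.astype(np.float64)

    shrink = _shrink_factor(int(radius_px))
    smoothed = ndimage.uniform_filter(af, size=3, mode="nearest")
    if shrink > 1:
        # block minimum, then the ball roll at reduced radius
        rows, cols = a.shape
        pr = (-rows) % shrink
        pc = (-cols) % shrink
        padded = np.pad(smoothed, ((0, pr), (0, pc)), mode="edge")
        blocks = padded.reshape(
            padded.shape[0] // shrink, shrink, padded.shape[1] // shrink, shrink
        )
        small = blocks.min(axis=(1, 3))
        bg_small = rolling_ball(small, radius=radius_px / shrink)
        bg = resize(
            bg_small,
            padded.shape,
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )[:rows, :cols]
    else:
        bg = rolling_ball(smoothed, radius=float(radius_px))

    bg = np.minimum(bg, af)  # background can never exceed the image
    out = np.clip(np.round(af - bg), 0, 255).astype(np.uint8)
    return out


def crop_centered(img: np.ndarray, center: tuple[int, int], size_px: int) -> np.ndarray:
    """Extract the ``size_px`` x ``size_px`` window centred at ``center``.

    For even window sizes the half-open convention ``[c - s//2, c + s//2)``
    is used on each axis, which makes nested crops compose exactly.  Raises
    ``ValueError`` when the window leaves the image.
    """
    a = as_gray_image(img)
    if size_px <= 0:
        raise ValueError("size_px must be positive")
    r, c = int(center[0]), int(center[1])
    half_lo = size_px // 2
    half_hi = size_px - half_lo
    r0, r1 = r - half_lo, r + half_hi
    c0, c1 = c - half_lo, c + half_hi
    if r0 < 0 or c0 < 0 or r1 > a.shape[0] or c1 > a.shape[1]:
        raise ValueError(
            f"crop out of bounds: window [{r0}:{r1}, {c0}:{c1}] "
            f"exceeds image of shape {a.shape}"
        )
    return a[r0:r1, c0:c1].copy()


def _intermeans_next(hist: np.ndarray, t: int) -> int | None:
    """One intermeans update on a 256-bin histogram; None if a side is empty."""
    bins = np.arange(256)
    lo_n = hist[: t + 1].sum()
    hi_n = hist[t + 1 :].sum()
    if lo_n == 0 or hi_n == 0:
        return None
    m_lo = (hist[: t + 1] * bins[: t + 1]).sum() / lo_n
    m_hi = (hist[t + 1 :] * bins[t + 1 :]).sum() / hi_n
    return int(np.round((m_lo + m_hi) / 2.0))


def isodata_default_threshold(img: np.ndarray) -> int:
    """Iterative-intermeans ("Default" dialect) threshold of an 8-bit image.

    Computes the fixed point t with t = round((mean(values <= t) +
    mean(values > t)) / 2) on the 256-bin histogram, iterating from the
    middle of the histogram.  When bin 0 or bin 255 holds more than half of
    all pixels (a saturated frame), that extreme bin is ignored; if the
    trimmed histogram becomes degenerate the full histogram is used instead.

    Raises ``ValueError`` on constant images ("degenerate histogram").
    """
    a = as_gray_image(img)
    hist = np.bincount(a.ravel(), minlength=256).astype(np.int64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has < 2 distinct values")

    work = hist.copy()
    n = work.sum()
    if work[0] > n // 2:
        work[0] = 0
    if work[255] > n // 2:
        work[255] = 0
    if np.count_nonzero(work) < 2:
        work = hist  # trimming left nothing to separate

    t = 127
    seen: set[int] = set()
    while t not in seen:
        seen.add(t)
        nxt = _intermeans_next(work, t)
        if nxt is None:
            # one side empty: step toward the populated side
            nonzero = np.nonzero(work)[0]
            t = int(np.clip(t, nonzero[0], nonzero[-1] - 1))
            if t in seen:
                break
            continue
        t = nxt
    # guard against a non-fixed 2-cycle: settle on a true fixed point nearby
    if _intermeans_next(work, t) != t:
        candidates = [
            s for s in range(255) if _intermeans_next(work, s) == s
        ]
        if candidates:
            t = min(candidates, key=lambda s: abs(s - t))
        else:  # pragma: no cover - intermeans always admits a fixed point
            warnings.warn("intermeans iteration did not reach a fixed point")
    return int(np.clip(t, 0, 255))


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize: pixels strictly above ``threshold`` become 255, others 0."""
    a = as_gray_image(img)
    if not 0 <= int(threshold) <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.where(a > threshold, 255, 0).astype(np.uint8)


def leakage_map(binary_5min: np.ndarray, binary_1min: np.ndarray) -> np.ndarray:
    """Clamped binary subtraction: hyperfluorescent at 5 min but not at 1 min.

    Computes ``max(b5 - b1, 0)`` pixelwise on {0, 255} rasters; the result
    is again a {0, 255} raster whose 255-pixels are the leakage support.
    """
    b5 = validate_binary(binary_5min)
    b1 = validate_binary(binary_1min)
    if b5.shape != b1.shape:
        raise ValueError("leakage_map inputs must share a shape")
    out = b5.astype(np.int16) - b1.astype(np.int16)
    return np.clip(out, 0, 255).astype(np.uint8)
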