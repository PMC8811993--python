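"""Shared domain types for the FA-leakage pipeline.

Images are plain 2-D ``numpy.uint8`` arrays in [0, 255], indexed (row, col)
with the origin at the top-left; binary images use the value set {0, 255}.
The small dataclasses here carry the structured results that flow between
the imaging, scoring and statistics layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "FAPair",
    "GroundTruth",
    "RegionSpec",
    "LeakageResult",
    "RocComparison",
    "SelectionTrace",
    "as_gray_image",
    "validate_binary",
    "PARAFOVEAL",
    "PERIFOVEAL",
    "DEFAULT_REGIONS",
]


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Coerce ``arr`` to a valid 2-D uint8 grayscale image.

    Color (H, W, 3/4) inputs are converted to luminance first; the fundus
    camera is a confocal scanning laser ophthalmoscope, so real inputs are
    nominally grayscale already.  Raises ``ValueError`` for values outside
    [0, 255] or non-2D shapes after conversion.
    """
    a = np.asarray(arr)
    if a.ndim == 3 and a.shape[2] in (3, 4):
        rgb = a[..., :3].astype(np.float64)
        a = rgb @ np.array([0.2126, 0.7152, 0.0722])
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        af = a.astype(np.float64)
        if af.min() < 0 or af.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        a = np.round(af).astype(np.uint8)
    return a


def validate_binary(img: np.ndarray) -> np.ndarray:
    """Check that ``img`` is a {0, 255} binary raster and return it as uint8."""
    a = as_gray_image(img)
    vals = np.unique(a)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"binary image must only contain 0 and 255, got {vals[:10]}")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Rigid (plus optional uniform scale) motion between two frames.

    ``rotation_deg`` is the in-plane rotation about the image centre
    (positive = counter-clockwise in (x, y) display coordinates) and
    ``translation`` is the residual (dy, dx) shift of the centre, in pixels.
    The convention throughout is that the transform describes the apparent
    motion of the moving (5-min) frame relative to the reference (1-min)
    frame.
    """

    rotation_deg: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def is_identity(self) -> bool:
        return (
            abs(self.rotation_deg) < 1e-9
            and abs(self.translation[0]) < 1e-9
            and abs(self.translation[1]) < 1e-9
            and abs(self.scale - 1.0) < 1e-12
        )


@dataclass
class FAPair:
    """Registered-in-intent 1-min and 5-min FA frames for one eye.

    ``fovea`` is the manually supplied foveal centre as (row, col); it must
    keep at least half the crop window (192 px for the default 384 px crop)
    away from every border so the fovea-centred crop stays in bounds.
    """

    frame_1min: np.ndarray
    frame_5min: np.ndarray
    fovea: tuple[int, int]
    eye_id: str = "eye"

    def __post_init__(self) -> None:
        self.frame_1min = as_gray_image(self.frame_1min)
        self.frame_5min = as_gray_image(self.frame_5min)
        if self.frame_1min.shape != self.frame_5min.shape:
            raise ValueError(
                f"frames of {self.eye_id} differ in shape: "
                f"{self.frame_1min.shape} vs {self.frame_5min.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame_1min.shape


@dataclass
class GroundTruth:
    """Generator-side truth for a synthetic FA pair.

    ``leak_mask`` is the set of pixels whose 8-bit value increases between
    the (noise-free, motion-free) 1-min and 5-min renderings — the support
    of true leakage growth.  ``true_transform`` is the inter-frame motion
    actually applied to the 5-min frame.
    """

    leak_mask: np.ndarray
    fovea: tuple[int, int]
    true_transform: RigidTransform


@dataclass(frozen=True)
class RegionSpec:
    """A fovea-centred square analysis window.

    The parafoveal (120 px) and perifoveal (240 px) windows approximate the
    central 3 mm and 6 mm macula; both are full squares sharing the crop
    centre, so the parafoveal pixels are a subset of the perifoveal ones.
    ``annulus`` excludes a nested inner square (sensitivity-analysis
    variant; off by default).
    """

    name: str
    size_px: int
    annulus_inner_px: int | None = None

    def __post_init__(self) -> None:
        if self.size_px <= 0:
            raise ValueError("region size must be positive")
        if self.annulus_inner_px is not None and not (
            0 < self.annulus_inner_px < self.size_px
        ):
            raise ValueError("annulus inner size must lie inside the window")


PARAFOVEAL = RegionSpec("parafoveal", 120)
PERIFOVEAL = RegionSpec("perifoveal", 240)
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (PARAFOVEAL, PERIFOVEAL)


@dataclass
class LeakageResult:
    """Per-eye leakage scores (mean gray value of the regional leakage map)."""

    eye_id: str
    parafoveal_mgv: float
    perifoveal_mgv: float
    grader_id: str = "auto"
    threshold_1min: int | None = None
    threshold_5min: int | None = None
    transform: RigidTransform | None = None

    def __post_init__(self) -> None:
        for v in (self.parafoveal_mgv, self.perifoveal_mgv):
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"mean gray value {v} outside [0, 255]")


@dataclass
class RocComparison:
    """AUC of one predictor with its DeLong CI and paired contrast."""

    predictor_name: str
    auc: float
    ci95: tuple[float, float]
    delong_p_vs_reference: float | None
    reference_name: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo - 1e-12 <= self.auc <= hi + 1e-12:
            raise ValueError("CI must contain the AUC point estimate")
        if self.delong_p_vs_reference is not None and not (
            0.0 <= self.delong_p_vs_reference <= 1.0
        ):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class SelectionTrace:
    """Record of a backward-elimination logistic regression.

    ``removed`` lists (step, variable, wald_p_at_removal) in removal order;
    ``final`` maps retained variable -> dict with keys coef, odds_ratio,
    or_ci95, p.
    """

    removed: list[tuple[int, str, float]] = field(default_factory=list)
    final: dict[str, dict[str, float | tuple[float, float]]] = field(
        default_factory=dict
    )
    p_stay: float = 0.05
    separation_flag: bool = False
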