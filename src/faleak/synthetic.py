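"""Synthetic FA frame pairs and cohort tables with known ground truth.

The study's patient images and per-eye tables are not public, so this
module generates stand-ins with controlled structure: frame pairs carry a
vessel tree, a smooth background gradient, focal leakage blobs that grow
between the 1-min and 5-min timepoints, sensor noise and optional
inter-frame rigid motion; cohort tables draw every per-group variable from
the distributions whose moments the study reports (normals truncated at
zero for physically non-negative quantities).  All outputs are
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, stats
from skimage.transform import SimilarityTransform, warp

from .preprocess import _motion_from_matrix
from .types import FAPair, GroundTruth, RigidTransform

__all__ = [
    "ScenarioParams",
    "GroupMoments",
    "CohortParams",
    "RESPONSIVE_MOMENTS",
    "REFRACTORY_MOMENTS",
    "generate_fa_pair",
    "generate_cohort",
    "generate_grader_pair",
    "grader_noise_for_icc",
    "responsive_scenario",
    "refractory_scenario",
    "extramacular_scenario",
    "save_fa_pair",
    "save_cohort",
    "COHORT_COLUMNS",
]

_CROP_MARGIN = 192  # half of the 384 px fovea-centred analysis crop


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of one synthetic FA acquisition.

    Amplitudes are 8-bit intensity units.  ``blob_amp_5min`` must be at
    least ``blob_amp_1min`` (leakage only grows over the first minutes).
    ``blob_region`` places leakage either in the macula ("macular", within
    ``blob_spread_px`` of the fovea) or entirely outside the 384 px
    fovea-centred analysis crop ("peripheral" — the occlusion-far-from-
    the-macula presentation).
    ``inter_frame_shift`` is (dy, dx) in pixels and
    ``inter_frame_rotation`` degrees about the image centre, applied to the
    5-min frame.
    """

    image_size: int = 768
    n_vessels: int = 7
    vessel_intensity: float = 90.0
    background_amplitude: float = 40.0
    n_leak_blobs: int = 4
    blob_sigma_px: float = 14.0
    blob_spread_px: float = 90.0
    blob_amp_1min: float = 30.0
    blob_amp_5min: float = 100.0
    noise_sd: float = 4.0
    inter_frame_shift: tuple[float, float] = (0.0, 0.0)
    inter_frame_rotation: float = 0.0
    blob_region: str = "macular"
    fovea: tuple[int, int] | None = None  # defaults to the image centre
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 384:
            raise ValueError("image_size must be >= 384")
        if self.blob_amp_5min < self.blob_amp_1min:
            raise ValueError("blob_amp_5min must be >= blob_amp_1min")
        for name in ("vessel_intensity", "background_amplitude",
                     "blob_amp_1min", "blob_amp_5min"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.blob_region not in ("macular", "peripheral"):
            raise ValueError("blob_region must be 'macular' or 'peripheral'")

    def resolved_fovea(self) -> tuple[int, int]:
        if self.fovea is None:
            return (self.image_size // 2, self.image_size // 2)
        return (int(self.fovea[0]), int(self.fovea[1]))


def _check_fovea_margin(fovea: tuple[int, int], size: int) -> None:
    r, c = fovea
    if not (
        _CROP_MARGIN <= r <= size - _CROP_MARGIN
        and _CROP_MARGIN <= c <= size - _CROP_MARGIN
    ):
        raise ValueError(
            f"fovea {fovea} leaves < {_CROP_MARGIN} px margin in a "
            f"{size}x{size} frame; the 384x384 crop would fall outside"
        )


def _background(params: ScenarioParams) -> np.ndarray:
    """Smooth radial vignette plus a linear ramp, peak = background_amplitude."""
    n = params.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    cy = cx = (n - 1) / 2.0
    d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (0.6 * n) ** 2
    radial = np.exp(-d2)
    ramp = 0.5 * (xx / (n - 1) + yy / (n - 1))
    bg = 0.65 * radial + 0.35 * ramp
    return params.background_amplitude * bg / bg.max() if bg.max() > 0 else bg


def _render_vessels(rng: np.random.Generator, params: ScenarioParams) -> np.ndarray:
    """Branching random-walk polylines with a Gaussian cross-section."""
    n = params.image_size
    canvas = np.zeros((n, n), dtype=np.float64)
    # each trunk starts on a border heading inward; branches split off
    stack: list[tuple[float, float, float, int, float]] = []
    for _ in range(params.n_vessels):
        side = rng.integers(4)
        pos = rng.uniform(0.1 * n, 0.9 * n)
        start = {0: (0.0, pos), 1: (n - 1.0, pos), 2: (pos, 0.0), 3: (pos, n - 1.0)}[int(side)]
        heading = {0: np.pi / 2, 1: -np.pi / 2, 2: 0.0, 3: np.pi}[int(side)]
        heading += rng.normal(0, 0.3)
        stack.append((start[0], start[1], heading, int(1.2 * n), 1.0))
    step = 2.0
    while stack:
        r, c, heading, steps_left, weight = stack.pop()
        for _ in range(steps_left):
            r += step * np.sin(heading)
            c += step * np.cos(heading)
            if not (0 <= r < n and 0 <= c < n):
                break
            canvas[int(r), int(c)] += weight
            heading += rng.normal(0.0, 0.08)
            if rng.random() < 0.008 and weight > 0.4:
                stack.append(
                    (r, c, heading + rng.choice([-1, 1]) * rng.uniform(0.4, 0.9),
                     steps_left // 2, weight * 0.6)
                )
        # consumed
    blurred = ndimage.gaussian_filter(canvas, sigma=1.6)
    if blurred.max() > 0:
        blurred = params.vessel_intensity * blurred / blurred.max()
    return blurred


def _blob_field(rng: np.random.Generator, params: ScenarioParams) -> np.ndarray:
    """Unit-amplitude leakage field: pointwise max of Gaussian blobs."""
    n = params.image_size
    fr, fc = params.resolved_fovea()
    out = np.zeros((n, n), dtype=np.float64)
    if params.n_leak_blobs == 0:
        return out
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    # peripheral blobs must clear the whole 384 px analysis crop (not just
    # the 240 px window) so they cannot shift its auto-threshold
    clear = _CROP_MARGIN + 3 * 1.3 * params.blob_sigma_px
    if params.blob_region == "peripheral" and clear >= max(
        fr, fc, n - 1 - fr, n - 1 - fc
    ):
        raise ValueError(
            "image too small to place peripheral blobs outside the analysis crop"
        )
    for _ in range(params.n_leak_blobs):
        if params.blob_region == "macular":
            rad = rng.uniform(0, params.blob_spread_px)
            ang = rng.uniform(0, 2 * np.pi)
            br = np.clip(fr + rad * np.sin(ang), 0, n - 1)
            bc = np.clip(fc + rad * np.cos(ang), 0, n - 1)
        else:
            while True:  # rejection-sample a centre clear of the crop
                br = rng.uniform(0, n - 1)
                bc = rng.uniform(0, n - 1)
                if max(abs(br - fr), abs(bc - fc)) > clear:
                    break
        sigma = params.blob_sigma_px * rng.uniform(0.7, 1.3)
        g = np.exp(-(((yy - br) ** 2 + (xx - bc) ** 2) / (2 * sigma**2)))
        np.maximum(out, g, out=out)
    return out


def _quantize(scene: np.ndarray) -> np.ndarray:
    return np.clip(np.round(scene), 0, 255).astype(np.uint8)


def _motion_transform(params: ScenarioParams) -> SimilarityTransform:
    n = params.image_size
    c = (n - 1) / 2.0
    dy, dx = params.inter_frame_shift
    rot = np.deg2rad(params.inter_frame_rotation)
    return (
        SimilarityTransform(translation=(-c, -c))
        + SimilarityTransform(rotation=rot)
        + SimilarityTransform(translation=(c, c))
        + SimilarityTransform(translation=(dx, dy))
    )


def generate_fa_pair(params: ScenarioParams) -> tuple[FAPair, GroundTruth]:
    """Render one synthetic 1-min / 5-min FA frame pair with ground truth.

    The two frames share the background, vessel tree and blob centres; only
    the blob amplitude changes between timepoints, the 5-min frame is
    additionally moved by the configured rigid transform, and each frame
    receives an independent noise realization.  The ground-truth leak mask
    is the set of pixels whose quantized value increases between the
    noise-free, motion-free renderings — so with ``noise_sd=0`` and no
    motion, ``frame_5min > frame_1min`` equals the mask exactly.
    """
    fovea = params.resolved_fovea()
    _check_fovea_margin(fovea, params.image_size)
    rng = np.random.default_rng(params.seed)

    bg = _background(params)
    vessels = _render_vessels(rng, params)
    blobs = _blob_field(rng, params)
    base = bg + vessels
    scene1 = base + params.blob_amp_1min * blobs
    scene5 = base + params.blob_amp_5min * blobs

    leak_mask = _quantize(scene5) > _quantize(scene1)

    motion = _motion_transform(params)
    if params.inter_frame_rotation == 0 and params.inter_frame_shift == (0.0, 0.0):
        moved5 = scene5
        true_tf = RigidTransform()
    else:
        moved5 = warp(scene5, motion.inverse, order=1, cval=0.0, preserve_range=True)
        n = params.image_size
        center_xy = np.array([(n - 1) / 2.0, (n - 1) / 2.0])
        true_tf = _motion_from_matrix(motion.params, center_xy)

    noise1 = rng.normal(0.0, params.noise_sd, scene1.shape) if params.noise_sd else 0.0
    noise5 = rng.normal(0.0, params.noise_sd, scene1.shape) if params.noise_sd else 0.0
    frame1 = _quantize(scene1 + noise1)
    frame5 = _quantize(moved5 + noise5)

    pair = FAPair(frame_1min=frame1, frame_5min=frame5, fovea=fovea,
                  eye_id=f"synthetic-{params.seed}")
    truth = GroundTruth(leak_mask=leak_mask, fovea=fovea, true_transform=true_tf)
    return pair, truth


def responsive_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """Mild, focal macular leakage, typical of eyes that respond to anti-VEGF."""
    defaults = dict(n_leak_blobs=3, blob_sigma_px=10.0, blob_spread_px=70.0,
                    blob_amp_1min=25.0, blob_amp_5min=75.0, seed=seed)
    defaults.update(overrides)
    return ScenarioParams(**defaults)


def refractory_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """Severe leakage spread across the macula, typical of refractory eyes."""
    defaults = dict(n_leak_blobs=9, blob_sigma_px=20.0, blob_spread_px=110.0,
                    blob_amp_1min=35.0, blob_amp_5min=160.0, seed=seed)
    defaults.update(overrides)
    return ScenarioParams(**defaults)


def extramacular_scenario(seed: int = 0, **overrides) -> ScenarioParams:
    """Heavy leakage placed entirely outside the fovea-centred analysis crop.

    Emulates the occlusion-far-from-the-macula presentation in which
    whole-image leakage is large but the fovea-centred scores stay low.
    """
    defaults = dict(n_leak_blobs=7, blob_sigma_px=16.0,
                    blob_amp_1min=35.0, blob_amp_5min=150.0,
                    blob_region="peripheral", seed=seed)
    defaults.update(overrides)
    return ScenarioParams(**defaults)


# --------------------------------------------------------------------------
# cohort tables


@dataclass(frozen=True)
class GroupMoments:
    """Per-group moments/proportions of the clinical covariates.

    Continuous entries are (mean, sd) pairs in the study's units (scores in
    8-bit gray levels, CRT in micrometres, follow-up in months); proportions
    are fractions of the group.
    """

    mgv_parafoveal: tuple[float, float]
    mgv_perifoveal: tuple[float, float]
    crt_pre: tuple[float, float]
    crt_best_post: tuple[float, float]
    crt_1yr: tuple[float, float]
    injections_year1: tuple[float, float]
    age: tuple[float, float]
    followup_months: tuple[float, float]
    logmar_baseline: tuple[float, float]
    logmar_1yr: tuple[float, float]
    p_male: float
    p_od: float
    p_brvo_major: float
    p_cystoid: float
    p_diffuse: float
    p_serous: float


RESPONSIVE_MOMENTS = GroupMoments(
    mgv_parafoveal=(14.1, 12.5),
    mgv_perifoveal=(14.9, 8.9),
    crt_pre=(451.0, 157.0),
    crt_best_post=(233.0, 33.0),
    crt_1yr=(252.0, 38.0),
    injections_year1=(2.4, 1.2),
    age=(60.9, 11.7),
    followup_months=(30.0, 22.7),
    logmar_baseline=(0.84, 0.60),
    logmar_1yr=(0.50, 0.49),
    p_male=30 / 47,
    p_od=26 / 47,
    p_brvo_major=30 / 47,
    p_cystoid=21 / 47,
    p_diffuse=24 / 47,
    p_serous=6 / 47,
)

REFRACTORY_MOMENTS = GroupMoments(
    mgv_parafoveal=(37.3, 22.1),
    mgv_perifoveal=(32.7, 15.0),
    crt_pre=(544.0, 183.0),
    crt_best_post=(275.0, 61.0),
    crt_1yr=(414.0, 146.0),
    injections_year1=(5.9, 1.6),
    age=(64.2, 9.8),
    followup_months=(34.3, 20.8),
    logmar_baseline=(0.93, 0.52),
    logmar_1yr=(0.72, 0.40),
    p_male=26 / 42,
    p_od=23 / 42,
    p_brvo_major=31 / 42,
    p_cystoid=26 / 42,
    p_diffuse=17 / 42,
    p_serous=7 / 42,
)

# grader replicate noise calibrated so the simulated inter-grader ICCs match
# the study's reported agreement (0.915 parafoveal, 0.968 perifoveal)
_DEFAULT_GRADER_SD_PARA = 6.4
_DEFAULT_GRADER_SD_PERI = 2.7


@dataclass(frozen=True)
class CohortParams:
    """Sampling plan for a synthetic treated-BRVO cohort."""

    n_responsive: int = 47
    n_refractory: int = 42
    responsive: GroupMoments = RESPONSIVE_MOMENTS
    refractory: GroupMoments = REFRACTORY_MOMENTS
    grader_noise_sd_para: float = _DEFAULT_GRADER_SD_PARA
    grader_noise_sd_peri: float = _DEFAULT_GRADER_SD_PERI
    p_persistent_refractory: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responsive < 2 or self.n_refractory < 2:
            raise ValueError("group sizes must be >= 2")
        for g in (self.responsive, self.refractory):
            for f in dataclasses.fields(GroupMoments):
                v = getattr(g, f.name)
                if isinstance(v, tuple) and v[1] <= 0:
                    raise ValueError(f"{f.name} sd must be > 0")
        if self.grader_noise_sd_para < 0 or self.grader_noise_sd_peri < 0:
            raise ValueError("grader noise sds must be >= 0")


COHORT_COLUMNS = [
    "eye_id", "group", "laterality", "sex", "age", "followup_months",
    "injections_year1", "persistent_after_3_monthly",
    "baseline_logmar", "logmar_1yr",
    "crt_pre", "crt_best_post", "crt_1yr",
    "brvo_type", "edema_cystoid", "edema_diffuse", "edema_serous",
    "parafoveal_mgv_true", "perifoveal_mgv_true",
    "parafoveal_mgv_grader1", "parafoveal_mgv_grader2",
    "perifoveal_mgv_grader1", "perifoveal_mgv_grader2",
    "parafoveal_mgv", "perifoveal_mgv",
]


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated below at zero."""
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_grader_pair(
    score, grader_noise_sd: float, seed=None
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Two independent noisy grader replicates of a true score.

    Scalar or vector ``score``; replicates are ``score + N(0, sd)`` with
    negative draws clamped to the score domain's floor of 0.  ``seed`` may
    be an int or a ``numpy.random.Generator``.
    """
    if grader_noise_sd < 0:
        raise ValueError("grader_noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = np.asarray(score, dtype=np.float64)
    a = np.maximum(s + rng.normal(0.0, grader_noise_sd, s.shape), 0.0)
    b = np.maximum(s + rng.normal(0.0, grader_noise_sd, s.shape), 0.0)
    if np.isscalar(score) or np.ndim(score) == 0:
        return float(a), float(b)
    return a, b


def grader_noise_for_icc(subject_sd: float, target_icc: float) -> float:
    """Grader noise sd giving a target single-measure ICC.

    For graders that differ from the subject's true score only by
    independent N(0, sd) error, ICC = sd_subjects^2 / (sd_subjects^2 +
    sd_error^2); invert for the error sd.
    """
    if not 0 < target_icc < 1:
        raise ValueError("target_icc must lie strictly in (0, 1)")
    if subject_sd <= 0:
        raise ValueError("subject_sd must be > 0")
    return subject_sd * np.sqrt((1.0 - target_icc) / target_icc)


def _group_frame(
    rng: np.random.Generator, g: GroupMoments, n: int, label: str,
    params: CohortParams, start_idx: int,
) -> pd.DataFrame:
    df = pd.DataFrame({
        "eye_id": [f"eye-{start_idx + i:03d}" for i in range(n)],
        "group": label,
        "laterality": np.where(rng.random(n) < g.p_od, "OD", "OS"),
        "sex": np.where(rng.random(n) < g.p_male, "M", "F"),
        "age": _trunc_normal(rng, *g.age, n),
        "followup_months": _trunc_normal(rng, *g.followup_months, n),
        "baseline_logmar": rng.normal(*g.logmar_baseline, n),
        "logmar_1yr": rng.normal(*g.logmar_1yr, n),
        "crt_pre": _trunc_normal(rng, *g.crt_pre, n),
        "crt_best_post": _trunc_normal(rng, *g.crt_best_post, n),
        "crt_1yr": _trunc_normal(rng, *g.crt_1yr, n),
        "brvo_type": np.where(rng.random(n) < g.p_brvo_major, "major", "macular"),
        "edema_cystoid": rng.random(n) < g.p_cystoid,
        "edema_diffuse": rng.random(n) < g.p_diffuse,
        "edema_serous": rng.random(n) < g.p_serous,
        "parafoveal_mgv_true": _trunc_normal(rng, *g.mgv_parafoveal, n),
        "perifoveal_mgv_true": _trunc_normal(rng, *g.mgv_perifoveal, n),
    })
    if label == "responsive":
        df["injections_year1"] = rng.integers(1, 5, n)
        df["persistent_after_3_monthly"] = False
    else:
        draws = np.round(_trunc_normal(rng, *g.injections_year1, n))
        df["injections_year1"] = np.maximum(draws, 5).astype(int)
        df["persistent_after_3_monthly"] = rng.random(n) < params.p_persistent_refractory
    return df


def generate_cohort(params: CohortParams = CohortParams()) -> pd.DataFrame:
    """Draw a synthetic cohort table with per-group study moments.

    Continuous covariates come from normals truncated at zero (logMAR is
    left untruncated — negative acuities are physically valid); injection
    counts follow the response-grouping rule by construction (responsive
    uniform on 1..4, refractory a rounded truncated normal floored at 5).
    Two noisy grader replicates of each true leakage score are included,
    plus their average in ``parafoveal_mgv`` / ``perifoveal_mgv`` (the
    columns downstream analyses use).
    """
    rng = np.random.default_rng(params.seed)
    resp = _group_frame(rng, params.responsive, params.n_responsive,
                        "responsive", params, 0)
    refr = _group_frame(rng, params.refractory, params.n_refractory,
                        "refractory", params, params.n_responsive)
    df = pd.concat([resp, refr], ignore_index=True)
    for region, sd in (("parafoveal", params.grader_noise_sd_para),
                       ("perifoveal", params.grader_noise_sd_peri)):
        g1, g2 = generate_grader_pair(df[f"{region}_mgv_true"].to_numpy(), sd, rng)
        df[f"{region}_mgv_grader1"] = g1
        df[f"{region}_mgv_grader2"] = g2
        df[f"{region}_mgv"] = (g1 + g2) / 2.0
    return df[COHORT_COLUMNS]


# --------------------------------------------------------------------------
# on-disk artefacts


def save_fa_pair(out_dir, pair: FAPair, truth: GroundTruth,
                 params: ScenarioParams, fmt: str = "tiff") -> Path:
    """Write a frame pair, its ground-truth mask and a JSON parameter sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "tiff":
        tifffile.imwrite(out / f"{pair.eye_id}_1min.tif", pair.frame_1min)
        tifffile.imwrite(out / f"{pair.eye_id}_5min.tif", pair.frame_5min)
    elif fmt == "png":
        iio.imwrite(out / f"{pair.eye_id}_1min.png", pair.frame_1min)
        iio.imwrite(out / f"{pair.eye_id}_5min.png", pair.frame_5min)
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    iio.imwrite(out / f"{pair.eye_id}_leakmask.png",
                (truth.leak_mask.astype(np.uint8) * 255))
    sidecar = {
        "eye_id": pair.eye_id,
        "fovea": list(truth.fovea),
        "true_transform": {
            "rotation_deg": truth.true_transform.rotation_deg,
            "translation": list(truth.true_transform.translation),
            "scale": truth.true_transform.scale,
        },
        "params": dataclasses.asdict(params),
        "distribution_note": (
            "normal blob/noise model; real per-eye score distributions are "
            "unknown beyond group mean +/- sd"
        ),
    }
    (out / f"{pair.eye_id}_params.json").write_text(json.dumps(sidecar, indent=2))
    return out


def save_cohort(out_dir, df: pd.DataFrame, params: CohortParams) -> Path:
    """Write the cohort CSV and a JSON sidecar of the sampling plan."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "cohort.csv", index=False)
    sidecar = dataclasses.asdict(params)
    sidecar["distribution_note"] = (
        "continuous covariates are zero-truncated normals at the stated "
        "group moments; the normal family is an assumption"
    )
    (out / "cohort_params.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return out
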