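"""Seeded generator of paired OCT-like volumes and longitudinal VF series.

The generator emulates, at desk scale, the statistical structure the
pipeline assumes: layered retinal volumes whose local inner-layer
thinning is coupled to visual-field sensitivity loss through a linear
structure-function gain, longitudinal VF series with non-positive
progression slopes and test-retest noise, unreliable tests, low-quality
scans, and injectable upper-eyelid artifacts.

Geometry conventions
--------------------
Volumes are arrays of shape (H, W, D): axis 0 en-face vertical with
superior retina at index 0, axis 1 en-face horizontal, axis 2 axial
depth.  The en-face frame spans +-ENFACE_EXTENT_DEG degrees so that
every 24-2 point maps inside the scan.  The retinal location of VF
point (x, y) is (x, -y): a superior field point reads the inferior
retina.  OS volumes are mirrored along the horizontal en-face axis and
OS exams are produced in the device (OS) frame, so ingest-side
laterality normalization is exercised.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .exams import (
    GHTResult,
    Laterality,
    PDCategory,
    VFExam,
    VFSeries,
    simplified_md,
)
from .grids import Pattern, build_grid, horizontal_flip_permutation

__all__ = [
    "GenConfig",
    "GroundTruthEye",
    "SyntheticDataset",
    "sample_eye",
    "render_volume",
    "simulate_vf_series",
    "make_dataset",
]

ENFACE_EXTENT_DEG = 28.0
BASE_THICKNESS = 100.0       # healthy inner-layer thickness, micron-like units
MIN_THICKNESS = 10.0
DISPLAY_MAX_DB = 33.0
BASE_DATE = _dt.date(2020, 1, 6)

# Per-row depression multipliers of an injected upper-eyelid artifact,
# superior rows top to bottom (y = +21, +15, +9, +3).  At injection
# depth 15 dB the nasal-mean row differences are (9.75, 7.5, 9.75) dB,
# clearing the 6/6/8 dB exclusion rule.
EYELID_PROFILE = (1.8, 1.15, 0.65, 0.0)


@dataclass(frozen=True)
class GenConfig:
    """Study conditions of the synthetic population."""

    n_patients: int = 20
    eyes_per_patient: int = 1
    volume_shape: tuple[int, int, int] = (64, 64, 32)
    n_layers: int = 3
    baseline_sensitivity_db: float = 33.0
    defect_prevalence: float = 0.7
    defect_depth_range: tuple[float, float] = (15.0, 70.0)   # thickness units
    progression_slope_mean: float = -0.6                     # dB/year
    progression_slope_sd: float = 0.5
    test_retest_sd_db: float = 1.5
    exams_per_eye: int = 5
    exam_interval_days: float = 180.0
    eyelid_artifact_rate: float = 0.0
    eyelid_artifact_depth_db: float = 15.0
    structure_function_gain: float = 0.5                     # dB per thickness unit
    volume_noise_sd: float = 0.05
    low_ssi_fraction: float = 0.05
    unreliable_fraction: float = 0.05
    oct_per_eye: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("defect_prevalence", "eyelid_artifact_rate",
                     "low_ssi_fraction", "unreliable_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.test_retest_sd_db < 0 or self.volume_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape extents must be positive")


@dataclass
class GroundTruthEye:
    """Latent state of one synthetic eye."""

    eye_id: str
    patient_id: str
    laterality: Laterality
    thickness_field: np.ndarray                  # (H, W) en-face map
    deficit_field: np.ndarray                    # (H, W), >= 0
    defect_regions: list[tuple[tuple[float, float], float, float]]
    true_sensitivity: dict                       # Pattern -> (n_points,) dB, OD frame
    true_slope: dict                             # Pattern -> (n_points,) dB/year <= 0


def _enface_grid(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Retinal (x, y) degree coordinates of each en-face pixel."""
    h, w = shape
    ys = np.linspace(ENFACE_EXTENT_DEG, -ENFACE_EXTENT_DEG, h)[:, None]
    xs = np.linspace(-ENFACE_EXTENT_DEG, ENFACE_EXTENT_DEG, w)[None, :]
    return np.broadcast_to(xs, (h, w)), np.broadcast_to(ys, (h, w))


def _vf_point_pixels(pattern: Pattern, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """En-face pixel (row, col) of each VF point's retinal location."""
    h, w = shape
    xy = build_grid(pattern).xy().astype(float)
    x_ret, y_ret = xy[:, 0], -xy[:, 1]          # vertical field/retina inversion
    col = np.round((x_ret + ENFACE_EXTENT_DEG) / (2 * ENFACE_EXTENT_DEG) * (w - 1))
    row = np.round((ENFACE_EXTENT_DEG - y_ret) / (2 * ENFACE_EXTENT_DEG) * (h - 1))
    return row.astype(np.intp), col.astype(np.intp)


def sample_eye(cfg: GenConfig, rng: np.random.Generator,
               eye_id: str = "eye0", patient_id: str = "p0",
               laterality: Laterality = Laterality.OD) -> GroundTruthEye:
    """Draw one eye: thickness map, defects, true sensitivities and slopes.

    The thickness field is a smooth base minus arcuate Gaussian bumps
    placed on superior and/or inferior arcs around the fovea; per-point
    sensitivity is baseline - gain x local thickness deficit, clamped to
    [0, baseline].  Progression is concentrated in defect regions.
    """
    h, w = cfg.volume_shape[:2]
    gx, gy = _enface_grid((h, w))
    r = np.hypot(gx, gy)
    base = BASE_THICKNESS + 8.0 * np.exp(-((r - 12.0) ** 2) / (2 * 8.0 ** 2))
    deficit = np.zeros((h, w))
    regions: list[tuple[tuple[float, float], float, float]] = []
    if rng.random() < cfg.defect_prevalence:
        n_defects = int(rng.integers(1, 3))
        for _ in range(n_defects):
            hemi = 1.0 if rng.random() < 0.5 else -1.0     # superior vs inferior retina
            ang = rng.uniform(0.25 * np.pi, 0.75 * np.pi)  # arcuate sector
            rad = rng.uniform(7.0, 16.0)
            cx, cy = rad * np.cos(ang) * rng.choice([-1, 1]), hemi * rad * np.sin(ang)
            sigma = rng.uniform(4.0, 9.0)
            depth = rng.uniform(*cfg.defect_depth_range)
            bump = depth * np.exp(-(((gx - cx) ** 2) + ((gy - cy) ** 2)) / (2 * sigma ** 2))
            deficit += bump
            regions.append(((cx, cy), sigma, depth))
    thickness = np.clip(base - deficit, MIN_THICKNESS, None)

    slope_eye = min(0.0, rng.normal(cfg.progression_slope_mean, cfg.progression_slope_sd))
    sens: dict = {}
    slopes: dict = {}
    for pattern in (Pattern.P24_2, Pattern.P10_2):
        rows, cols = _vf_point_pixels(pattern, (h, w))
        local_deficit = deficit[rows, cols]
        s = cfg.baseline_sensitivity_db - cfg.structure_function_gain * local_deficit
        sens[pattern] = np.clip(s, 0.0, cfg.baseline_sensitivity_db)
        # progression fastest where tissue is already compromised
        weight = 0.2 + 0.8 * np.clip(local_deficit / max(cfg.defect_depth_range[1], 1e-9), 0, 1)
        slopes[pattern] = slope_eye * weight
    return GroundTruthEye(eye_id, patient_id, laterality, thickness,
                          deficit, regions, sens, slopes)


def render_volume(eye: GroundTruthEye, cfg: GenConfig, rng: np.random.Generator,
                  force_low_ssi: bool | None = None) -> tuple[np.ndarray, dict]:
    """Render one OCT-like volume of the eye plus its metadata sidecar.

    The volume stacks ``n_layers`` bright horizontal bands; the first
    band's local axial extent follows the thickness field (the
    structure-function carrier), deeper bands are fixed anatomy.
    Speckle-like Gaussian noise is added on top.  OS volumes are
    mirrored along the horizontal en-face axis.
    """
    h, w, d = cfg.volume_shape
    zz = np.arange(d)[None, None, :]
    vol = np.full((h, w, d), 0.08, dtype=np.float32)

    top = max(1, d // 10)
    t_vox = (eye.thickness_field / (BASE_THICKNESS + 10.0)) * (0.55 * d)
    inner = (zz >= top) & (zz < top + t_vox[:, :, None])
    vol[inner] = 0.85
    # fixed deeper bands (outer retina / RPE analogues)
    for k in range(1, cfg.n_layers):
        z0 = d - 2 - 3 * k
        band = (zz >= z0) & (zz < z0 + 2)
        vol[np.broadcast_to(band, vol.shape)] = 0.7 - 0.1 * k
    if cfg.volume_noise_sd > 0:
        vol = vol + rng.normal(0.0, cfg.volume_noise_sd, size=vol.shape).astype(np.float32)
    if eye.laterality is Laterality.OS:
        vol = vol[:, ::-1, :]

    low = force_low_ssi if force_low_ssi is not None else (rng.random() < cfg.low_ssi_fraction)
    ssi = float(rng.uniform(4.0, 6.9)) if low else float(rng.uniform(7.0, 10.0))
    meta = {
        "patient_id": eye.patient_id,
        "eye_id": eye.eye_id,
        "laterality": eye.laterality.value,
        "ssi": ssi,
        "shape": (h, w, d),
    }
    return np.ascontiguousarray(vol), meta


def _pd_categories(loss: np.ndarray) -> np.ndarray:
    """Surrogate pattern-deviation categories from true pointwise loss (dB)."""
    cat = np.full(loss.shape, PDCategory.NS, dtype=np.intp)
    cat[loss >= 3] = PDCategory.P5
    cat[loss >= 6] = PDCategory.P2
    cat[loss >= 9] = PDCategory.P1
    cat[loss >= 12] = PDCategory.P05
    return cat


def _inject_eyelid(thr: np.ndarray, grid, depth_db: float) -> np.ndarray:
    """Depress the superior 24-2 rows with the lid occlusion profile."""
    out = thr.copy()
    xy = grid.xy()
    for mult, y in zip(EYELID_PROFILE, (21, 15, 9, 3)):
        idx = np.flatnonzero(xy[:, 1] == y)
        out[idx] = np.clip(out[idx] - mult * depth_db, 0.0, None)
    return out


def simulate_vf_series(
    eye: GroundTruthEye,
    pattern: Pattern,
    cfg: GenConfig,
    rng: np.random.Generator,
    start_date: _dt.date = BASE_DATE,
) -> VFSeries:
    """Longitudinal exams of one eye in its device frame.

    threshold(point, t) = clamp(true_sensitivity + true_slope * t +
    N(0, test_retest_sd), [0, 33]); reliability rates are mostly good
    with an ``unreliable_fraction`` of poor tests; MD is the simplified
    (unweighted) deficit mean; eyelid artifacts are injected into 24-2
    exams at the configured rate.
    """
    grid = build_grid(pattern)
    sens = eye.true_sensitivity[pattern]
    slope = eye.true_slope[pattern]
    hperm = horizontal_flip_permutation(grid)
    exams = []
    for k in range(cfg.exams_per_eye):
        t_years = k * cfg.exam_interval_days / 365.25
        date = start_date + _dt.timedelta(days=round(k * cfg.exam_interval_days))
        thr = sens + slope * t_years
        if cfg.test_retest_sd_db > 0:
            thr = thr + rng.normal(0.0, cfg.test_retest_sd_db, size=thr.shape)
        thr = np.clip(thr, 0.0, DISPLAY_MAX_DB)
        artifact = (
            pattern is Pattern.P24_2
            and rng.random() < cfg.eyelid_artifact_rate
        )
        if artifact:
            thr = _inject_eyelid(thr, grid, cfg.eyelid_artifact_depth_db)
        loss = cfg.baseline_sensitivity_db - (sens + slope * t_years)
        pd_prob = _pd_categories(loss)
        psd = PDCategory.P5 if np.any(loss >= 6) else PDCategory.NS
        xy = build_grid(pattern).xy()
        sup, inf = thr[xy[:, 1] > 0], thr[xy[:, 1] < 0]
        ght = (
            GHTResult.OUTSIDE_NORMAL
            if abs(float(np.mean(sup) - np.mean(inf))) > 2.0
            else GHTResult.WITHIN_NORMAL
        )
        if rng.random() < cfg.unreliable_fraction:
            rates = sorted(rng.uniform(0.0, 0.15, size=3))
            rates[int(rng.integers(0, 3))] = float(rng.uniform(0.33, 0.6))
        else:
            rates = list(rng.uniform(0.0, 0.15, size=3))
        if eye.laterality is Laterality.OS:
            thr = thr[hperm]
            pd_prob = pd_prob[hperm]
        exam = VFExam(
            patient_id=eye.patient_id,
            eye_id=eye.eye_id,
            laterality=eye.laterality,
            date=date,
            pattern=pattern,
            thresholds=thr,
            md=0.0,  # placeholder, set below from the realized thresholds
            fp_rate=float(rates[0]),
            fn_rate=float(rates[1]),
            fl_rate=float(rates[2]),
            pd_prob=pd_prob,
            psd_prob=psd,
            ght=ght,
        )
        exam = _dc_replace(
            exam, md=simplified_md(exam, cfg.baseline_sensitivity_db)
        )
        exams.append(exam)
    return VFSeries(eye_id=eye.eye_id, pattern=pattern, exams=exams)


@dataclass
class EyeRecord:
    eye: GroundTruthEye
    series_24_2: VFSeries
    series_10_2: VFSeries
    volumes: list            # list of (volume, metadata) tuples
    oct_dates: list


@dataclass
class SyntheticDataset:
    cfg: GenConfig
    eyes: list = field(default_factory=list)

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    def manifest(self):
        import pandas as pd

        rows = []
        for rec in self.eyes:
            for i, ((_, meta), date) in enumerate(zip(rec.volumes, rec.oct_dates)):
                rows.append({
                    "patient_id": rec.eye.patient_id,
                    "eye_id": rec.eye.eye_id,
                    "laterality": rec.eye.laterality.value,
                    "oct_index": i,
                    "oct_date": date.isoformat(),
                    "ssi": meta["ssi"],
                    "n_exams_24_2": rec.series_24_2.n_tests,
                    "n_exams_10_2": rec.series_10_2.n_tests,
                })
        return pd.DataFrame(rows)


def make_dataset(cfg: GenConfig) -> SyntheticDataset:
    """Generate the full synthetic population, reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    ds = SyntheticDataset(cfg=cfg)
    for p in range(cfg.n_patients):
        patient_id = f"P{p:04d}"
        for e in range(cfg.eyes_per_patient):
            laterality = Laterality.OD if rng.random() < 0.5 else Laterality.OS
            eye_id = f"{patient_id}_{laterality.value}{e}"
            eye = sample_eye(cfg, rng, eye_id=eye_id, patient_id=patient_id,
                             laterality=laterality)
            start = BASE_DATE + _dt.timedelta(days=int(rng.integers(0, 120)))
            s24 = simulate_vf_series(eye, Pattern.P24_2, cfg, rng, start_date=start)
            s10 = simulate_vf_series(eye, Pattern.P10_2, cfg, rng, start_date=start)
            volumes, dates = [], []
            span_days = cfg.exam_interval_days * max(cfg.exams_per_eye - 1, 1)
            for i in range(cfg.oct_per_eye):
                frac = (i + 1) / (cfg.oct_per_eye + 1)
                date = start + _dt.timedelta(
                    days=round(frac * span_days + rng.uniform(-30, 30))
                )
                volumes.append(render_volume(eye, cfg, rng))
                dates.append(date)
            ds.eyes.append(EyeRecord(eye, s24, s10, volumes, dates))
    return ds
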