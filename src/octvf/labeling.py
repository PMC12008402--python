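"""Regression-based label construction at the OCT acquisition date.

Perimetry is noisy test-to-test; to stabilise the target, every test
point of an eye's longitudinal series is summarised by an ordinary
least-squares line of threshold on time, evaluated at the OCT date.
Because glaucomatous loss is irreversible, positive (improving) fitted
slopes are treated as learning/retest effects and clamped to zero, in
which case the label is the series mean.  Thresholds are clamped to
[0, 33] dB and mean deviation to [-33, 0] dB.

A paired sample concatenates the 24-2 and 10-2 blocks into a single
122-value vector — 52 non-blind-spot 24-2 points, the 24-2 MD, 68
10-2 points, the 10-2 MD — with a parallel {0,1} mask (1 = absent)
that removes missing entries from every downstream loss and metric.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field

import numpy as np

from .exams import VFSeries
from .grids import Pattern, build_grid, vertical_flip_permutation

__all__ = [
    "LabelConfig",
    "PairedSample",
    "LABEL_LENGTH",
    "SLICE_24_2",
    "IDX_MD_24_2",
    "SLICE_10_2",
    "IDX_MD_10_2",
    "pointwise_regression_label",
    "validity_period_check",
    "assemble_paired_sample",
    "label_vector_vertical_permutation",
]

DAYS_PER_MONTH = 365.25 / 12.0
DAYS_PER_YEAR = 365.25

# Fixed layout of the combined label vector.
SLICE_24_2 = slice(0, 52)
IDX_MD_24_2 = 52
SLICE_10_2 = slice(53, 121)
IDX_MD_10_2 = 121
LABEL_LENGTH = 122


class ValidityReference(str, enum.Enum):
    """Which exam anchors the staleness check relative to the OCT date."""

    NEAREST = "nearest"    # exam date closest to the OCT date
    LATEST = "latest"      # chronologically last exam of the series


@dataclass(frozen=True)
class LabelConfig:
    validity_unit_months: float = 6.0
    single_exam_window_months: float = 6.0
    threshold_range_db: tuple[float, float] = (0.0, 33.0)
    md_range_db: tuple[float, float] = (-33.0, 0.0)
    mask_missing_value: int = 1
    validity_reference: ValidityReference = ValidityReference.NEAREST

    def __post_init__(self):
        if self.validity_unit_months <= 0 or self.single_exam_window_months <= 0:
            raise ValueError("window lengths must be positive")
        for lo, hi in (self.threshold_range_db, self.md_range_db):
            if lo >= hi:
                raise ValueError("clamping ranges must be ordered")
        object.__setattr__(
            self, "validity_reference", ValidityReference(self.validity_reference)
        )


class BlockSource(str, enum.Enum):
    REGRESSED = "regressed"
    SINGLE_EXAM = "single_exam"
    MISSING = "missing"


@dataclass
class PairedSample:
    """One OCT volume paired with its 122-value masked VF label vector."""

    patient_id: str
    eye_id: str
    oct_date: _dt.date
    volume_ref: object
    labels: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.labels.shape != (LABEL_LENGTH,) or self.mask.shape != (LABEL_LENGTH,):
            raise ValueError(f"labels and mask must have length {LABEL_LENGTH}")
        if not set(np.unique(self.mask)) <= {0.0, 1.0}:
            raise ValueError("mask entries must be 0 or 1")
        if not np.all(np.isfinite(self.labels[self.mask == 0])):
            raise ValueError("unmasked labels must be finite")


def _fit_at_date(
    dates: list[_dt.date], values: np.ndarray, oct_date: _dt.date
) -> float:
    """OLS value at the OCT date with the non-positive-slope constraint.

    Time is measured in years from the OCT date, so the fitted intercept
    is directly the label; the construction is therefore equivariant to
    shifting all dates by a constant.
    """
    t = np.array([(d - oct_date).days for d in dates], dtype=float) / DAYS_PER_YEAR
    v = np.asarray(values, dtype=float)
    if np.ptp(t) == 0.0:
        return float(np.mean(v))  # all same date: degenerate fit
    slope, intercept = np.polyfit(t, v, 1)
    if slope > 0:
        # irreversibility: re-fit under slope = 0, i.e. the series mean
        return float(np.mean(v))
    return float(intercept)


def pointwise_regression_label(
    series: VFSeries,
    point_index: int,
    oct_date: _dt.date,
    cfg: LabelConfig = LabelConfig(),
) -> float | None:
    """Label for one test point at the OCT date, or None when absent.

    With >= 2 exams carrying the point: OLS of threshold on time,
    positive slopes clamped to zero (label becomes the series mean),
    evaluated at the OCT date and clamped to the threshold range.  With
    exactly one exam: that exam's value iff the OCT date lies within the
    single-exam window, else None.  With none: None.
    """
    pairs = [
        (e.date, e.thresholds[point_index])
        for e in series
        if np.isfinite(e.thresholds[point_index])
    ]
    lo, hi = cfg.threshold_range_db
    if not pairs:
        return None
    if len(pairs) == 1:
        date, value = pairs[0]
        gap_months = abs((oct_date - date).days) / DAYS_PER_MONTH
        if gap_months > cfg.single_exam_window_months:
            return None
        return float(np.clip(value, lo, hi))
    dates, values = zip(*pairs)
    raw = _fit_at_date(list(dates), np.array(values), oct_date)
    return float(np.clip(raw, lo, hi))


def _md_regression_label(
    series: VFSeries, oct_date: _dt.date, cfg: LabelConfig
) -> float | None:
    pairs = [(e.date, e.md) for e in series if np.isfinite(e.md)]
    lo, hi = cfg.md_range_db
    if not pairs:
        return None
    if len(pairs) == 1:
        date, value = pairs[0]
        if abs((oct_date - date).days) / DAYS_PER_MONTH > cfg.single_exam_window_months:
            return None
        return float(np.clip(value, lo, hi))
    dates, values = zip(*pairs)
    raw = _fit_at_date(list(dates), np.array(values), oct_date)
    return float(np.clip(raw, lo, hi))


def validity_period_check(
    series: VFSeries, oct_date: _dt.date, cfg: LabelConfig = LabelConfig()
) -> bool:
    """Staleness gate: the OCT must fall within 6 months x n of the series.

    n is the number of exams; the anchoring exam is, by default, the one
    whose date is closest to the OCT date (configurable to the series'
    chronologically last exam).
    """
    if series.n_tests == 0:
        return False
    if cfg.validity_reference is ValidityReference.NEAREST:
        gap_days = min(abs((oct_date - e.date).days) for e in series)
    else:
        gap_days = abs((oct_date - max(e.date for e in series)).days)
    validity_months = cfg.validity_unit_months * series.n_tests
    return gap_days / DAYS_PER_MONTH <= validity_months


def _block_labels(
    series: VFSeries | None,
    pattern: Pattern,
    oct_date: _dt.date,
    cfg: LabelConfig,
) -> tuple[np.ndarray, np.ndarray, BlockSource]:
    """Labels and mask for one pattern block (points then MD)."""
    grid = build_grid(pattern)
    n = len(grid.non_blind_indices)
    labels = np.zeros(n + 1)
    mask = np.ones(n + 1)
    if series is None or series.n_tests == 0:
        return labels, mask, BlockSource.MISSING
    if not validity_period_check(series, oct_date, cfg):
        return labels, mask, BlockSource.MISSING
    for out_i, point_i in enumerate(grid.non_blind_indices):
        lab = pointwise_regression_label(series, int(point_i), oct_date, cfg)
        if lab is not None:
            labels[out_i] = lab
            mask[out_i] = 0.0
    md = _md_regression_label(series, oct_date, cfg)
    if md is not None:
        labels[n] = md
        mask[n] = 0.0
    source = BlockSource.SINGLE_EXAM if series.n_tests == 1 else BlockSource.REGRESSED
    if np.all(mask == 1.0):
        source = BlockSource.MISSING
    return labels, mask, source


def assemble_paired_sample(
    series_24_2: VFSeries | None,
    series_10_2: VFSeries | None,
    oct_record: dict,
    cfg: LabelConfig = LabelConfig(),
) -> PairedSample:
    """Pair one OCT volume with its combined 24-2 + 10-2 label vector.

    ``oct_record`` must carry ``patient_id``, ``eye_id``, ``date`` and a
    ``volume_ref``.  Pattern blocks that are absent or fail the validity
    period are fully masked (sentinel 0, mask 1); a sample with both
    blocks missing is rejected, mirroring the exclusion of OCT scans
    with no usable VF.
    """
    oct_date = oct_record["date"]
    lab24, mask24, src24 = _block_labels(series_24_2, Pattern.P24_2, oct_date, cfg)
    lab10, mask10, src10 = _block_labels(series_10_2, Pattern.P10_2, oct_date, cfg)
    if src24 is BlockSource.MISSING and src10 is BlockSource.MISSING:
        raise ValueError("no usable VF block for this OCT; sample rejected")
    labels = np.concatenate([lab24, lab10])
    mask = np.concatenate([mask24, mask10])
    return PairedSample(
        patient_id=str(oct_record["patient_id"]),
        eye_id=str(oct_record["eye_id"]),
        oct_date=oct_date,
        volume_ref=oct_record.get("volume_ref"),
        labels=labels,
        mask=mask,
        provenance={"24-2": src24, "10-2": src10},
    )


def label_vector_vertical_permutation() -> np.ndarray:
    """Length-122 permutation pairing each point with its y -> -y mirror.

    Applied to labels and masks when the volume is flipped along the
    superior-inferior axis; MD entries map to themselves.  Involution.
    """
    perm = np.arange(LABEL_LENGTH, dtype=np.intp)
    g24 = build_grid(Pattern.P24_2)
    full24 = vertical_flip_permutation(g24)
    nb = g24.non_blind_indices
    pos_in_vector = {int(p): i for i, p in enumerate(nb)}
    for i, p in enumerate(nb):
        perm[i] = pos_in_vector[int(full24[p])]
    g10 = build_grid(Pattern.P10_2)
    full10 = vertical_flip_permutation(g10)
    base = SLICE_10_2.start
    for i in range(g10.n_points):
        perm[base + i] = base + int(full10[i])
    return perm
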