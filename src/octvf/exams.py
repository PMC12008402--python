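"""Visual-field exam data model and pattern-level transforms.

A :class:`VFExam` stores one perimetry test in the order of its grid
(:mod:`octvf.grids`).  Missing thresholds are NaN.  All downstream code
assumes exams have been mapped into the OD frame with
:func:`normalize_laterality`.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import (
    Pattern,
    VFGrid,
    build_grid,
    horizontal_flip_permutation,
)

__all__ = [
    "Laterality",
    "PDCategory",
    "GHTResult",
    "VFExam",
    "VFSeries",
    "normalize_laterality",
    "trim_30_2_to_24_2",
    "simplified_md",
    "exams_to_frame",
    "frame_to_exams",
    "write_exams_csv",
    "read_exams_csv",
    "write_exams_json",
    "read_exams_json",
]

THRESHOLD_INPUT_RANGE = (0.0, 50.0)


class Laterality(str, enum.Enum):
    OD = "OD"
    OS = "OS"


class PDCategory(enum.IntEnum):
    """Pattern-deviation probability category, larger = more abnormal."""

    NS = 0        # not significant
    P5 = 1        # p < 5%
    P2 = 2        # p < 2%
    P1 = 3        # p < 1%
    P05 = 4       # p < 0.5%

    @classmethod
    def from_label(cls, label: str) -> "PDCategory":
        table = {"ns": cls.NS, "p<5%": cls.P5, "p<2%": cls.P2,
                 "p<1%": cls.P1, "p<0.5%": cls.P05}
        return table[str(label).strip().lower()]

    def to_label(self) -> str:
        return ["ns", "p<5%", "p<2%", "p<1%", "p<0.5%"][int(self)]


class GHTResult(str, enum.Enum):
    WITHIN_NORMAL = "within_normal"
    BORDERLINE = "borderline"
    OUTSIDE_NORMAL = "outside_normal"


@dataclass(frozen=True)
class VFExam:
    """One automated perimetry test.

    thresholds are dB sensitivities in grid order (NaN = not measured);
    reliability rates are fractions in [0, 1]; pd_prob is an optional
    per-point pattern-deviation probability category array; psd_prob an
    optional global PSD category; ght an optional hemifield-test result.
    """

    patient_id: str
    eye_id: str
    laterality: Laterality
    date: _dt.date
    pattern: Pattern
    thresholds: np.ndarray
    md: float
    fp_rate: float | None = None
    fn_rate: float | None = None
    fl_rate: float | None = None
    pd_prob: np.ndarray | None = None  # PDCategory codes, int array
    psd_prob: PDCategory | None = None
    ght: GHTResult | None = None

    def __post_init__(self):
        grid = build_grid(self.pattern)
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.shape != (grid.n_points,):
            raise ValueError(
                f"thresholds must have length {grid.n_points} for "
                f"{self.pattern.value}, got shape {thr.shape}"
            )
        finite = thr[np.isfinite(thr)]
        lo, hi = THRESHOLD_INPUT_RANGE
        if finite.size and (finite.min() < lo or finite.max() > hi):
            raise ValueError(f"thresholds outside [{lo}, {hi}] dB on input")
        object.__setattr__(self, "thresholds", thr)
        if not isinstance(self.date, _dt.date) or isinstance(self.date, _dt.datetime):
            raise ValueError("date must be a datetime.date")
        for name in ("fp_rate", "fn_rate", "fl_rate"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pd_prob is not None:
            pd_arr = np.asarray(self.pd_prob, dtype=np.intp)
            if pd_arr.shape != (grid.n_points,):
                raise ValueError("pd_prob length must match grid")
            object.__setattr__(self, "pd_prob", pd_arr)

    @property
    def grid(self) -> VFGrid:
        return build_grid(self.pattern)


def normalize_laterality(exam: VFExam, grid: VFGrid | None = None) -> VFExam:
    """Map an exam into the OD frame.

    OS exams have thresholds and probability maps re-indexed by the
    x -> -x permutation and are re-tagged OD-frame; OD exams are returned
    unchanged.  MD is a spatial mean and is unaffected.  Applying twice
    is the identity.
    """
    if exam.laterality is Laterality.OD:
        return exam
    grid = grid or exam.grid
    perm = horizontal_flip_permutation(grid)
    pd_prob = exam.pd_prob[perm] if exam.pd_prob is not None else None
    return replace(
        exam,
        laterality=Laterality.OD,
        thresholds=exam.thresholds[perm],
        pd_prob=pd_prob,
    )


def trim_30_2_to_24_2(exam: VFExam) -> VFExam:
    """Trim the peripheral 30-2 points down to the 24-2 point set.

    Each retained point's threshold (and pd category) is copied from the
    30-2 point with identical coordinates.  MD is kept as recorded; the
    device value is not recomputed for the reduced point set.

    OS exams are handled by mirroring into the OD frame, trimming, and
    mirroring back, so that trimming commutes with laterality
    normalization on the asymmetric nasal-extension rows.
    """
    if exam.pattern is not Pattern.P30_2:
        raise ValueError(f"expected a 30-2 exam, got {exam.pattern.value}")
    if exam.laterality is Laterality.OS:
        trimmed_od = trim_30_2_to_24_2(normalize_laterality(exam))
        perm = horizontal_flip_permutation(build_grid(Pattern.P24_2))
        pd_prob = trimmed_od.pd_prob[perm] if trimmed_od.pd_prob is not None else None
        return replace(
            trimmed_od,
            laterality=Laterality.OS,
            thresholds=trimmed_od.thresholds[perm],
            pd_prob=pd_prob,
        )
    g30 = build_grid(Pattern.P30_2)
    g24 = build_grid(Pattern.P24_2)
    src = np.array([g30.index_of(x, y) for x, y in g24.points], dtype=np.intp)
    pd_prob = exam.pd_prob[src] if exam.pd_prob is not None else None
    return replace(
        exam,
        pattern=Pattern.P24_2,
        thresholds=exam.thresholds[src],
        pd_prob=pd_prob,
    )


def simplified_md(exam: VFExam, baseline: float | np.ndarray) -> float:
    """Unweighted surrogate for the device mean deviation.

    Mean of (threshold - baseline) over non-blind-spot points.  The true
    HFA MD is an age-corrected, variance-weighted statistic computed
    against a normative database; this surrogate keeps only its role as
    a global deficit summary for the synthetic world.
    """
    grid = exam.grid
    idx = grid.non_blind_indices
    thr = exam.thresholds[idx]
    if not np.all(np.isfinite(thr)):
        raise ValueError("simplified_md requires thresholds at all analysed points")
    base = np.broadcast_to(np.asarray(baseline, dtype=float), exam.thresholds.shape)
    return float(np.mean(thr - base[idx]))


@dataclass
class VFSeries:
    """Date-ordered exams of one eye and pattern."""

    eye_id: str
    pattern: Pattern
    exams: list[VFExam] = field(default_factory=list)

    def __post_init__(self):
        for e in self.exams:
            if e.pattern is not self.pattern:
                raise ValueError("all exams in a series must share the pattern")
            if e.eye_id != self.eye_id:
                raise ValueError("all exams in a series must share the eye")
        self.exams = sorted(self.exams, key=lambda e: e.date)

    @property
    def n_tests(self) -> int:
        return len(self.exams)

    def __iter__(self):
        return iter(self.exams)

    def __len__(self):
        return len(self.exams)


# ---------------------------------------------------------------------------
# Tabular IO: one row per exam, per-point columns t_x{X}_y{Y} (signed ints),
# optional pd_x{X}_y{Y} category labels.  Missing threshold = empty cell.
# ---------------------------------------------------------------------------

_META_COLS = ["patient_id", "eye_id", "laterality", "date", "pattern",
              "md", "fp_rate", "fn_rate", "fl_rate", "psd_prob", "ght"]


def _point_col(x: int, y: int) -> str:
    return f"t_x{x}_y{y}"


def exams_to_frame(exams: Iterable[VFExam]) -> pd.DataFrame:
    rows = []
    for e in exams:
        grid = e.grid
        row: dict = {
            "patient_id": e.patient_id,
            "eye_id": e.eye_id,
            "laterality": e.laterality.value,
            "date": e.date.isoformat(),
            "pattern": e.pattern.value,
            "md": e.md,
            "fp_rate": e.fp_rate,
            "fn_rate": e.fn_rate,
            "fl_rate": e.fl_rate,
            "psd_prob": e.psd_prob.to_label() if e.psd_prob is not None else None,
            "ght": e.ght.value if e.ght is not None else None,
        }
        for i, (x, y) in enumerate(grid.points):
            v = e.thresholds[i]
            row[_point_col(x, y)] = v if np.isfinite(v) else None
        if e.pd_prob is not None:
            for i, (x, y) in enumerate(grid.points):
                row[f"pd_x{x}_y{y}"] = PDCategory(int(e.pd_prob[i])).to_label()
        rows.append(row)
    return pd.DataFrame(rows)


def _row_to_exam(row: pd.Series) -> VFExam:
    pattern = Pattern(row["pattern"])
    grid = build_grid(pattern)
    thr = np.full(grid.n_points, np.nan)
    for i, (x, y) in enumerate(grid.points):
        v = row.get(_point_col(x, y))
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            thr[i] = float(v)
    pd_prob = None
    if f"pd_x{grid.points[0][0]}_y{grid.points[0][1]}" in row.index:
        vals = [row.get(f"pd_x{x}_y{y}") for x, y in grid.points]
        if all(isinstance(v, str) for v in vals):
            pd_prob = np.array([PDCategory.from_label(v) for v in vals])

    def _opt(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    psd = _opt("psd_prob")
    ght = _opt("ght")
    return VFExam(
        patient_id=str(row["patient_id"]),
        eye_id=str(row["eye_id"]),
        laterality=Laterality(row["laterality"]),
        date=_dt.date.fromisoformat(str(row["date"])),
        pattern=pattern,
        thresholds=thr,
        md=float(row["md"]),
        fp_rate=_opt("fp_rate"),
        fn_rate=_opt("fn_rate"),
        fl_rate=_opt("fl_rate"),
        pd_prob=pd_prob,
        psd_prob=PDCategory.from_label(psd) if psd is not None else None,
        ght=GHTResult(ght) if ght is not None else None,
    )


def frame_to_exams(frame: pd.DataFrame) -> list[VFExam]:
    return [_row_to_exam(row) for _, row in frame.iterrows()]


def write_exams_csv(exams: Sequence[VFExam], path: str | Path) -> None:
    exams_to_frame(exams).to_csv(path, index=False)


def read_exams_csv(path: str | Path) -> list[VFExam]:
    return frame_to_exams(pd.read_csv(path))


def write_exams_json(exams: Sequence[VFExam], path: str | Path) -> None:
    frame = exams_to_frame(exams)
    records = json.loads(frame.to_json(orient="records"))
    Path(path).write_text(json.dumps(records, indent=1))


def read_exams_json(path: str | Path) -> list[VFExam]:
    records = json.loads(Path(path).read_text())
    return frame_to_exams(pd.DataFrame.from_records(records))
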