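"""Quality-control filters for visual-field exams and OCT volumes.

Four independent gates:

* reliability: reject tests whose false-positive, false-negative or
  fixation-loss rate reaches the cutoff (default 33%, inclusive);
* scan quality: reject OCT volumes with signal strength index below 7;
* upper-eyelid artifact: the row-difference heuristic on the nasal
  points of the four superior 24-2 rows;
* glaucoma eligibility: the Anderson-Patella reading of the pattern
  deviation map, PSD and glaucoma hemifield test.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .exams import GHTResult, Laterality, PDCategory, VFExam
from .grids import Pattern, VFGrid, build_grid

__all__ = [
    "QCConfig",
    "QCReason",
    "QCDecision",
    "reliability_filter",
    "ssi_filter",
    "eyelid_artifact_detect",
    "anderson_patella_eligible",
]


class CombineRule(str, enum.Enum):
    ALL = "all"
    ANY = "any"


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC gates; defaults follow the study protocol."""

    reliability_cutoff: float = 0.33
    ssi_min: float = 7.0
    eyelid_thresholds_db: tuple[float, float, float] = (6.0, 6.0, 8.0)
    eyelid_combine: CombineRule = CombineRule.ALL
    n_nasal_points: int = 3

    def __post_init__(self):
        if not (0.0 < self.reliability_cutoff <= 1.0):
            raise ValueError("reliability_cutoff must lie in (0, 1]")
        if any(t <= 0 for t in self.eyelid_thresholds_db):
            raise ValueError("eyelid thresholds must be positive")
        if self.n_nasal_points < 1:
            raise ValueError("n_nasal_points must be >= 1")
        object.__setattr__(self, "eyelid_combine", CombineRule(self.eyelid_combine))


class QCReason(str, enum.Enum):
    OK = "ok"
    UNRELIABLE = "unreliable"
    LOW_SSI = "low_ssi"
    EYELID_ARTIFACT = "eyelid_artifact"
    NOT_GLAUCOMA_ELIGIBLE = "not_glaucoma_eligible"


@dataclass(frozen=True)
class QCDecision:
    passed: bool
    reason: QCReason
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.passed != (self.reason is QCReason.OK):
            raise ValueError("reason must be 'ok' iff passed")

    def __bool__(self) -> bool:
        return self.passed


def reliability_filter(exam: VFExam, cfg: QCConfig = QCConfig()) -> QCDecision:
    """Fail iff any reliability rate reaches the cutoff (inclusive bound)."""
    rates = (exam.fp_rate, exam.fn_rate, exam.fl_rate)
    if any(r is None for r in rates):
        raise ValueError("cannot adjudicate reliability: a rate is missing")
    worst = max(rates)
    diag = {"fp_rate": exam.fp_rate, "fn_rate": exam.fn_rate,
            "fl_rate": exam.fl_rate, "worst_rate": worst}
    if worst >= cfg.reliability_cutoff:
        return QCDecision(False, QCReason.UNRELIABLE, diag)
    return QCDecision(True, QCReason.OK, diag)


def ssi_filter(volume_meta: dict, cfg: QCConfig = QCConfig()) -> QCDecision:
    """Fail iff the OCT signal strength index is below ``ssi_min``."""
    ssi = volume_meta.get("ssi")
    if ssi is None:
        raise ValueError("volume metadata carries no SSI")
    diag = {"ssi": float(ssi)}
    if ssi < cfg.ssi_min:
        return QCDecision(False, QCReason.LOW_SSI, diag)
    return QCDecision(True, QCReason.OK, diag)


def eyelid_artifact_detect(
    exam: VFExam, grid: VFGrid | None = None, cfg: QCConfig = QCConfig()
) -> QCDecision:
    """Detect an upper-eyelid artifact on a laterality-normalized 24-2 exam.

    For the four superior rows (y = +21, +15, +9, +3) take the mean of
    the ``n_nasal_points`` most nasal (smallest x) thresholds, m1..m4
    superior to inferior, and form the inter-row differences
    d_k = m_{k+1} - m_k, positive when the upper row is depressed (the
    eyelid direction).  The exam is flagged iff all three differences
    strictly exceed their thresholds (default 6, 6, 8 dB top to bottom;
    combination rule configurable).
    """
    if exam.pattern is not Pattern.P24_2:
        raise ValueError("eyelid artifact rule is defined on 24-2 exams")
    if exam.laterality is not Laterality.OD:
        raise ValueError("exam must be laterality-normalized (OD frame)")
    grid = grid or build_grid(Pattern.P24_2)
    xy = grid.xy()
    means = []
    for y in (21, 15, 9, 3):  # superior rows, top to bottom
        row_idx = np.flatnonzero(xy[:, 1] == y)
        order = row_idx[np.argsort(xy[row_idx, 0])]
        nasal = order[: cfg.n_nasal_points]
        vals = exam.thresholds[nasal]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"missing nasal thresholds in superior row y={y}")
        means.append(float(np.mean(vals)))
    diffs = tuple(means[k + 1] - means[k] for k in range(3))
    exceeded = [d > t for d, t in zip(diffs, cfg.eyelid_thresholds_db)]
    flagged = all(exceeded) if cfg.eyelid_combine is CombineRule.ALL else any(exceeded)
    diag = {"nasal_means": tuple(means), "d1": diffs[0], "d2": diffs[1], "d3": diffs[2]}
    if flagged:
        return QCDecision(False, QCReason.EYELID_ARTIFACT, diag)
    return QCDecision(True, QCReason.OK, diag)


def _pd_clusters(grid: VFGrid, significant: np.ndarray) -> list[list[int]]:
    """Connected components of significant points.

    Contiguity is one lattice step per axis (8-neighborhood), within a
    hemifield (clusters never cross the horizontal meridian); blind-spot
    points never participate.
    """
    step = grid.lattice_step
    xy = grid.xy()
    idx = [i for i in np.flatnonzero(significant) if i not in grid.blind_spot_indices]
    seen: set[int] = set()
    clusters = []
    idx_set = set(idx)
    for start in idx:
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            i = stack.pop()
            xi, yi = xy[i]
            for j in idx_set:
                if j in seen:
                    continue
                xj, yj = xy[j]
                if (yi > 0) != (yj > 0):
                    continue  # hemifield restriction
                dx, dy = abs(xi - xj), abs(yi - yj)
                if dx <= step and dy <= step and (dx or dy):
                    seen.add(j)
                    comp.append(j)
                    stack.append(j)
        clusters.append(comp)
    return clusters


def anderson_patella_eligible(
    exam: VFExam, grid: VFGrid | None = None
) -> QCDecision:
    """Anderson-Patella criteria for a glaucomatous field.

    Eligible iff any of:

    * a contiguous cluster of >= 3 points with pattern-deviation
      probability stricter than 5%, at least one stricter than 1%;
    * PSD significant at stricter than 5%;
    * glaucoma hemifield test outside normal limits.
    """
    if exam.pd_prob is None or exam.psd_prob is None or exam.ght is None:
        raise ValueError("pd_prob, psd_prob and ght are all required")
    grid = grid or exam.grid
    if exam.ght is GHTResult.OUTSIDE_NORMAL:
        return QCDecision(True, QCReason.OK, {"rule": "ght"})
    if exam.psd_prob >= PDCategory.P5:
        return QCDecision(True, QCReason.OK, {"rule": "psd"})
    sig5 = np.asarray(exam.pd_prob) >= PDCategory.P5
    sig1 = np.asarray(exam.pd_prob) >= PDCategory.P1
    for comp in _pd_clusters(grid, sig5):
        if len(comp) >= 3 and any(sig1[i] for i in comp):
            return QCDecision(
                True, QCReason.OK, {"rule": "cluster", "cluster": sorted(comp)}
            )
    return QCDecision(False, QCReason.NOT_GLAUCOMA_ELIGIBLE, {"rule": None})
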