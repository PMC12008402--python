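"""Agreement and error analysis for paired VF predictions and labels.

Conventions: error statistics are computed per pair (one OCT-VF pair =
one sample's block of points) and then averaged across pairs, so the
reported "mean +- sd" are across-pair moments; correlations pool all
unmasked (prediction, label) values unless per-point coefficients are
requested.  Masked entries never influence any statistic.
"""

from __future__ import annotations

import enum
import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grids import VFGrid

__all__ = [
    "EvalConfig",
    "Severity",
    "pairwise_rmse",
    "mae",
    "correlations",
    "bland_altman",
    "severity_strata",
    "pointwise_mae_map",
    "mann_whitney_u",
    "compare_groups",
    "severity_error_regression",
    "EvalReport",
    "evaluate_block",
]


@dataclass(frozen=True)
class EvalConfig:
    mild_bound_db: float = -6.0     # mild: MD > -6
    severe_bound_db: float = -12.0  # severe: MD <= -12
    loa_z: float = 1.96
    bonferroni_m: int = 6

    def __post_init__(self):
        if not self.severe_bound_db < self.mild_bound_db:
            raise ValueError("severity bounds must be ordered")
        if self.loa_z <= 0:
            raise ValueError("loa_z must be positive")


class Severity(str, enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


def classify_severity(md: float, cfg: EvalConfig = EvalConfig()) -> Severity:
    """mild: MD > -6; moderate: -12 < MD <= -6; severe: MD <= -12."""
    if md > cfg.mild_bound_db:
        return Severity.MILD
    if md > cfg.severe_bound_db:
        return Severity.MODERATE
    return Severity.SEVERE


def _per_pair_stat(preds, labels, masks, stat) -> tuple[float, float, np.ndarray]:
    preds, labels, masks = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (preds, labels, masks))
    vals = []
    for p, l, m in zip(preds, labels, masks):
        keep = m == 0
        if not keep.any():
            warnings.warn("pair with all entries masked excluded from statistic")
            continue
        vals.append(stat(p[keep], l[keep]))
    if not vals:
        raise ValueError("no usable pairs (all fully masked)")
    vals = np.asarray(vals)
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd, vals


def pairwise_rmse(preds, labels, masks) -> tuple[float, float]:
    """RMSE per pair over its unmasked points, then mean/sd across pairs."""
    m, s, _ = _per_pair_stat(
        preds, labels, masks, lambda p, l: math.sqrt(np.mean((p - l) ** 2))
    )
    return m, s


def mae(preds, labels, masks, per_pair: bool = True) -> tuple[float, float]:
    """Mean absolute error; per-pair-then-average by default."""
    if per_pair:
        m, s, _ = _per_pair_stat(
            preds, labels, masks, lambda p, l: float(np.mean(np.abs(p - l)))
        )
        return m, s
    preds, labels, masks = (np.asarray(a, dtype=float) for a in (preds, labels, masks))
    keep = masks == 0
    errs = np.abs(preds - labels)[keep]
    if errs.size == 0:
        raise ValueError("no unmasked entries")
    sd = float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0
    return float(np.mean(errs)), sd


def per_pair_abs_errors(preds, labels, masks) -> np.ndarray:
    """Per-pair MAE values (the unit of the group comparison)."""
    _, _, vals = _per_pair_stat(
        preds, labels, masks, lambda p, l: float(np.mean(np.abs(p - l)))
    )
    return vals


def correlations(preds, labels, masks, per_point: bool = False,
                 grid: VFGrid | None = None):
    """Pooled Pearson r and Spearman rho over unmasked (pred, label) pairs.

    With ``per_point=True`` returns per-output-column coefficient arrays
    instead of pooling.
    """
    preds, labels, masks = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (preds, labels, masks))
    if per_point:
        n_cols = preds.shape[1]
        r = np.full(n_cols, np.nan)
        rho = np.full(n_cols, np.nan)
        for j in range(n_cols):
            keep = masks[:, j] == 0
            if keep.sum() >= 3 and np.ptp(labels[keep, j]) > 0 and np.ptp(preds[keep, j]) > 0:
                r[j] = stats.pearsonr(preds[keep, j], labels[keep, j]).statistic
                rho[j] = stats.spearmanr(preds[keep, j], labels[keep, j]).statistic
        return r, rho
    keep = masks == 0
    p, l = preds[keep], labels[keep]
    if p.size < 3:
        raise ValueError("need at least 3 pooled unmasked values")
    if np.ptp(p) == 0 or np.ptp(l) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(p, l).statistic)
    rho = float(stats.spearmanr(p, l).statistic)
    return r, rho


def bland_altman(est, act, cfg: EvalConfig = EvalConfig()) -> dict:
    """Bias, 95% limits of agreement, and proportional-bias correlation.

    d = est - act; bias = mean(d); LoA = bias +- z * sd(d) (sample sd);
    proportional_r = Pearson correlation of the pair means with d.
    """
    est = np.asarray(est, dtype=float)
    act = np.asarray(act, dtype=float)
    if est.size < 3:
        raise ValueError("Bland-Altman requires at least 3 pairs")
    d = est - act
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    means = (est + act) / 2.0
    if np.ptp(means) > 0 and np.ptp(d) > 0:
        prop = float(stats.pearsonr(means, d).statistic)
    else:
        prop = 0.0
    return {
        "bias": bias,
        "loa_low": bias - cfg.loa_z * sd,
        "loa_high": bias + cfg.loa_z * sd,
        "proportional_r": prop,
    }


def severity_strata(preds, labels, masks, actual_md,
                    cfg: EvalConfig = EvalConfig()) -> dict:
    """Per-severity-stratum MAE and correlations, keyed by Severity."""
    preds, labels, masks = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (preds, labels, masks))
    actual_md = np.asarray(actual_md, dtype=float)
    out: dict = {}
    for sev in Severity:
        sel = np.array([classify_severity(v, cfg) is sev for v in actual_md])
        if not sel.any():
            out[sev] = None
            continue
        m, s = mae(preds[sel], labels[sel], masks[sel])
        try:
            r, rho = correlations(preds[sel], labels[sel], masks[sel])
        except ValueError:
            r = rho = float("nan")
        out[sev] = {"n": int(sel.sum()), "mae": m, "mae_sd": s,
                    "pearson_r": r, "spearman_rho": rho}
    return out


def pointwise_mae_map(preds, labels, masks, grid: VFGrid) -> dict:
    """MAE per analysed grid point over unmasked samples.

    Returns {point index in grid -> MAE}; blind-spot points are omitted,
    as is any point with zero unmasked samples.  Input columns follow
    the grid's non-blind-spot order.
    """
    preds, labels, masks = (np.atleast_2d(np.asarray(a, dtype=float))
                            for a in (preds, labels, masks))
    nb = grid.non_blind_indices
    if preds.shape[1] != len(nb):
        raise ValueError(
            f"expected {len(nb)} point columns for {grid.pattern.value}, "
            f"got {preds.shape[1]}"
        )
    out = {}
    for col, point_idx in enumerate(nb):
        keep = masks[:, col] == 0
        if not keep.any():
            continue
        out[int(point_idx)] = float(np.mean(np.abs(preds[keep, col] - labels[keep, col])))
    return out


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration of all group assignments when min(n) <= 8 and the
    pooled data are tie-free; otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if min(a.size, b.size) <= 8 and no_ties:
        ranks = stats.rankdata(pooled)
        n1 = a.size
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        mu = n1 * b.size / 2.0
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for comb in itertools.combinations(range(pooled.size), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
            total += 1
        return count / total
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def compare_groups(errors_a, errors_b, cfg: EvalConfig = EvalConfig()) -> dict:
    """Two-sided Mann-Whitney U with Bonferroni correction (capped at 1)."""
    p_raw = mann_whitney_u(errors_a, errors_b)
    return {"p_raw": p_raw, "p_corrected": min(1.0, p_raw * cfg.bonferroni_m)}


def severity_error_regression(actual_values, abs_errors) -> dict:
    """Quadratic least-squares fit of |error| on severity, plus Spearman rho.

    Returns coefficients (c0, c1, c2) of c0 + c1 x + c2 x^2.
    """
    x = np.asarray(actual_values, dtype=float)
    y = np.asarray(abs_errors, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct severity values")
    coeffs = np.polyfit(x, y, 2)[::-1]  # ascending order
    if np.ptp(y) == 0:
        raise ValueError("constant errors: rank correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    return {"coefficients": tuple(float(c) for c in coeffs), "spearman_rho": rho}


@dataclass
class EvalReport:
    """All agreement/error statistics of one evaluated block."""

    n_pairs: int
    rmse: tuple[float, float]
    mae: tuple[float, float]
    md_mae: float | None
    pearson_r: float
    spearman_rho: float
    md_pearson_r: float | None
    md_spearman_rho: float | None
    bland_altman_md: dict | None
    severity: dict = field(default_factory=dict)
    pointwise_mae: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _san(v):
            if isinstance(v, dict):
                return {str(getattr(k, "value", k)): _san(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [_san(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return {k: _san(v) for k, v in self.__dict__.items()}


def evaluate_block(point_preds, point_labels, point_masks,
                   md_preds=None, md_labels=None, md_masks=None,
                   grid: VFGrid | None = None,
                   cfg: EvalConfig = EvalConfig()) -> EvalReport:
    """Full report for one pattern block (points + optional MD column)."""
    r, rho = correlations(point_preds, point_labels, point_masks)
    rm = pairwise_rmse(point_preds, point_labels, point_masks)
    ma = mae(point_preds, point_labels, point_masks)
    md_mae_v = md_r = md_rho = None
    ba = None
    severity: dict = {}
    if md_preds is not None:
        md_preds = np.asarray(md_preds, dtype=float)
        md_labels = np.asarray(md_labels, dtype=float)
        md_keep = (np.asarray(md_masks) == 0 if md_masks is not None
                   else np.ones_like(md_preds, dtype=bool))
        mp, ml = md_preds[md_keep], md_labels[md_keep]
        if mp.size:
            md_mae_v = float(np.mean(np.abs(mp - ml)))
        if mp.size >= 3 and np.ptp(mp) > 0 and np.ptp(ml) > 0:
            md_r = float(stats.pearsonr(mp, ml).statistic)
            md_rho = float(stats.spearmanr(mp, ml).statistic)
            ba = bland_altman(mp, ml, cfg)
            severity = severity_strata(point_preds, point_labels, point_masks,
                                       md_labels, cfg)
    pw = pointwise_mae_map(point_preds, point_labels, point_masks, grid) if grid else {}
    return EvalReport(
        n_pairs=int(np.atleast_2d(point_preds).shape[0]),
        rmse=rm, mae=ma, md_mae=md_mae_v,
        pearson_r=r, spearman_rho=rho,
        md_pearson_r=md_r, md_spearman_rho=md_rho,
        bland_altman_md=ba, severity=severity, pointwise_mae=pw,
    )
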