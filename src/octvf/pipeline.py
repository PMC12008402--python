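"""End-to-end orchestration on synthetic data.

One call runs: generate -> QC -> label -> train -> evaluate -> compare.
Two training cohorts are built from the same population:

* curated ("glaucoma-specific" analog): eyes whose fields satisfy the
  Anderson-Patella criteria, artifact-flagged exams removed — the
  manually cleaned cohort;
* comprehensive: every QC-passing eye, with only the automatic
  eyelid-artifact rule filtering exams.

Both are trained under identical folds and hyperparameters and
evaluated on the same curated-eligible test subset, and their per-pair
error distributions are compared.  The contrast is structural — the
inclusion rules — not a claim that synthetic magnitudes mirror any
clinical cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exams import VFSeries, normalize_laterality
from .grids import Pattern, build_grid
from .labeling import (
    IDX_MD_10_2,
    IDX_MD_24_2,
    SLICE_10_2,
    SLICE_24_2,
    LabelConfig,
    assemble_paired_sample,
)
from .qc import (
    QCConfig,
    anderson_patella_eligible,
    eyelid_artifact_detect,
    reliability_filter,
    ssi_filter,
)
from .synth import GenConfig, SyntheticDataset, make_dataset
from .training import (
    SampleArrays,
    TrainConfig,
    normalize_volume_laterality,
    patient_wise_folds,
    preprocess_volume,
    train_fold,
)
from .evaluation import EvalConfig, compare_groups, evaluate_block, per_pair_abs_errors

log = logging.getLogger("octvf")

__all__ = ["PipelineConfig", "PreparedData", "prepare_samples", "run_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    gen: GenConfig = GenConfig()
    qc: QCConfig = QCConfig()
    label: LabelConfig = LabelConfig()
    train: TrainConfig = TrainConfig()
    eval: EvalConfig = EvalConfig()
    outdir: str | None = None
    folds_to_run: int = 1
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PreparedData:
    """QC-filtered, labeled, preprocessed arrays plus per-sample metadata."""

    samples: SampleArrays
    eligible: np.ndarray        # curated-cohort eligibility per sample
    eye_ids: np.ndarray
    n_rejected_ssi: int = 0
    n_artifact_exams: int = 0
    n_unreliable_exams: int = 0


def _filter_series(series: VFSeries, qc_cfg: QCConfig,
                   drop_artifacts: bool) -> tuple[VFSeries, int, int]:
    """Laterality-normalize, drop unreliable (and optionally artifact) exams."""
    kept, n_unrel, n_art = [], 0, 0
    for exam in series:
        exam = normalize_laterality(exam)
        if not reliability_filter(exam, qc_cfg):
            n_unrel += 1
            continue
        if drop_artifacts and exam.pattern is Pattern.P24_2:
            if not eyelid_artifact_detect(exam, cfg=qc_cfg):
                n_art += 1
                continue
        kept.append(exam)
    return VFSeries(series.eye_id, series.pattern, kept), n_unrel, n_art


def prepare_samples(ds: SyntheticDataset, qc_cfg: QCConfig = QCConfig(),
                    label_cfg: LabelConfig = LabelConfig(),
                    train_cfg: TrainConfig = TrainConfig()) -> PreparedData:
    """QC, label and preprocess the synthetic population into arrays.

    The eyelid-artifact rule is applied when building every label series
    (the automatic cleaning step); curated-cohort eligibility is the
    Anderson-Patella criterion on any reliability-passing 24-2 exam.
    """
    vols, labels, masks, pids, eids, elig = [], [], [], [], [], []
    n_ssi = n_art = n_unrel = 0
    for rec in ds.eyes:
        s24, u1, a1 = _filter_series(rec.series_24_2, qc_cfg, drop_artifacts=True)
        s10, u2, _ = _filter_series(rec.series_10_2, qc_cfg, drop_artifacts=False)
        n_unrel += u1 + u2
        n_art += a1
        eye_eligible = any(bool(anderson_patella_eligible(e)) for e in s24)
        for (volume, meta), date in zip(rec.volumes, rec.oct_dates):
            if not ssi_filter(meta, qc_cfg):
                n_ssi += 1
                continue
            record = {"patient_id": rec.eye.patient_id, "eye_id": rec.eye.eye_id,
                      "date": date, "volume_ref": None}
            try:
                sample = assemble_paired_sample(s24, s10, record, label_cfg)
            except ValueError:
                continue  # no usable VF for this OCT
            v = normalize_volume_laterality(volume, rec.eye.laterality)
            vols.append(preprocess_volume(v, train_cfg))
            labels.append(sample.labels)
            masks.append(sample.mask)
            pids.append(rec.eye.patient_id)
            eids.append(rec.eye.eye_id)
            elig.append(eye_eligible)
    if not vols:
        raise ValueError("no usable paired samples after QC")
    arrays = SampleArrays(
        volumes=np.stack(vols),
        labels=np.stack(labels),
        masks=np.stack(masks),
        patient_ids=np.array(pids),
    )
    return PreparedData(arrays, np.array(elig), np.array(eids),
                        n_rejected_ssi=n_ssi, n_artifact_exams=n_art,
                        n_unreliable_exams=n_unrel)


def _evaluate_cohort(result, test: SampleArrays, cfg: PipelineConfig) -> dict:
    preds = result.predict_db(test.volumes, tta=True)
    out = {}
    for name, sl, md_idx, pattern in (
        ("24-2", SLICE_24_2, IDX_MD_24_2, Pattern.P24_2),
        ("10-2", SLICE_10_2, IDX_MD_10_2, Pattern.P10_2),
    ):
        pm = test.masks[:, sl]
        if np.all(pm == 1):
            out[name] = None
            continue
        report = evaluate_block(
            preds[:, sl], test.labels[:, sl], pm,
            md_preds=preds[:, md_idx], md_labels=test.labels[:, md_idx],
            md_masks=test.masks[:, md_idx],
            grid=build_grid(pattern), cfg=cfg.eval,
        )
        out[name] = report.to_dict()
    out["_per_pair_mae_24_2"] = per_pair_abs_errors(
        preds[:, SLICE_24_2], test.labels[:, SLICE_24_2], test.masks[:, SLICE_24_2]
    )
    return out


def _cached(stage: str, cfg: PipelineConfig, compute):
    """Content-addressed stage cache keyed by the full config hash.

    Errors propagate annotated with the failing stage's name.
    """
    try:
        if cfg.outdir is None:
            return compute()
        cache = Path(cfg.outdir) / "cache"
        cache.mkdir(parents=True, exist_ok=True)
        path = cache / f"{stage}-{cfg.config_hash()}.pkl"
        if path.exists():
            log.info("stage %s: cache hit (%s)", stage, path.name)
            with open(path, "rb") as fh:
                return pickle.load(fh)
        result = compute()
        with open(path, "wb") as fh:
            pickle.dump(result, fh)
        return result
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc


def run_experiment(cfg: PipelineConfig) -> dict:
    """Run the full synthetic experiment; returns the report dict."""
    logging.basicConfig(level=cfg.log_level)
    ds = _cached("generate", cfg, lambda: make_dataset(cfg.gen))
    log.info("generated %d eyes", ds.n_eyes)
    prep = _cached(
        "prepare", cfg,
        lambda: prepare_samples(ds, cfg.qc, cfg.label, cfg.train),
    )
    data = prep.samples
    log.info("prepared %d paired samples (%d curated-eligible)",
             len(data), int(prep.eligible.sum()))

    folds = _cached(
        "folds", cfg, lambda: patient_wise_folds(data.patient_ids, cfg.train)
    )
    report: dict = {
        "config_hash": cfg.config_hash(),
        "n_samples": len(data),
        "n_eligible": int(prep.eligible.sum()),
        "n_rejected_ssi": prep.n_rejected_ssi,
        "n_artifact_exams": prep.n_artifact_exams,
        "n_unreliable_exams": prep.n_unreliable_exams,
        "folds": [],
    }
    all_idx = np.arange(len(data))
    for fold in folds[: cfg.folds_to_run]:
        fold_rec: dict = {"fold": fold.fold, "cohorts": {}}
        test_idx = all_idx[
            np.isin(data.patient_ids, sorted(fold.test)) & prep.eligible
        ]
        if test_idx.size == 0:
            fold_rec["skipped"] = "no curated-eligible test samples"
            report["folds"].append(fold_rec)
            continue
        test = data.subset(test_idx)
        errors = {}
        for cohort in ("curated", "comprehensive"):
            keep = prep.eligible if cohort == "curated" else np.ones(len(data), bool)
            cohort_idx = all_idx[keep]
            cohort_data = data.subset(cohort_idx)
            has_train = np.isin(cohort_data.patient_ids, sorted(fold.train)).any()
            has_val = np.isin(cohort_data.patient_ids, sorted(fold.val)).any()
            if not (has_train and has_val):
                fold_rec["cohorts"][cohort] = {
                    "skipped": "no train or validation samples in this cohort"
                }
                continue
            result = _cached(
                f"train-{cohort}-fold{fold.fold}", cfg,
                lambda cd=cohort_data, f=fold: train_fold(cd, f, cfg.train),
            )
            ev = _cached(
                f"eval-{cohort}-fold{fold.fold}", cfg,
                lambda r=result, t=test: _evaluate_cohort(r, t, cfg),
            )
            errors[cohort] = ev.pop("_per_pair_mae_24_2")
            ev["selected_epoch"] = result.selected_epoch
            ev["val_losses"] = [float(v) for v in result.val_losses]
            ev["n_train_samples"] = int(
                np.isin(cohort_data.patient_ids, sorted(fold.train)).sum()
            )
            fold_rec["cohorts"][cohort] = ev
        if set(errors) == {"curated", "comprehensive"}:
            fold_rec["comparison"] = compare_groups(
                errors["curated"], errors["comprehensive"], cfg.eval
            )
        report["folds"].append(fold_rec)
    if cfg.outdir is not None:
        out = Path(cfg.outdir) / "report.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(report, indent=1, default=float))
    return report
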