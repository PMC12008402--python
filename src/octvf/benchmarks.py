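"""End-to-end synthetic recovery benchmark.

Generates a population with strong structure-function coupling, trains
the small volumetric regressor on one patient-wise fold, and measures
held-out agreement between predicted and regression-label visual
fields.  Used both by the acceptance checks and as a convenient smoke
benchmark; all knobs flow from one seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .labeling import SLICE_24_2
from .pipeline import prepare_samples
from .synth import GenConfig, make_dataset
from .training import TrainConfig, patient_wise_folds, train_fold

__all__ = ["synthetic_recovery_benchmark"]


def synthetic_recovery_benchmark(seed: int = 11, n_patients: int = 150) -> dict:
    """Train on one fold of a synthetic population and score the test fold.

    Returns pooled pointwise Pearson r / MAE on the held-out 24-2 block,
    the MAE of a predict-the-training-mean baseline, and the MAE with
    and without test-time flip averaging.
    """
    gen = GenConfig(n_patients=n_patients, test_retest_sd_db=1.0, seed=seed)
    data = prepare_samples(make_dataset(gen)).samples
    tcfg = TrainConfig(seed=seed % (2**31 - 1))
    fold = patient_wise_folds(data.patient_ids, tcfg)[0]
    result = train_fold(data, fold, tcfg)

    test = data.subset(data.index_of_patients(set(fold.test)))
    train = data.subset(data.index_of_patients(set(fold.train)))
    pred_tta = result.predict_db(test.volumes, tta=True)
    pred_plain = result.predict_db(test.volumes, tta=False)

    sl = SLICE_24_2
    keep = test.masks[:, sl] == 0
    labels = test.labels[:, sl]
    r = float(stats.pearsonr(pred_tta[:, sl][keep], labels[keep]).statistic)
    mae_tta = float(np.mean(np.abs(pred_tta[:, sl] - labels)[keep]))
    mae_plain = float(np.mean(np.abs(pred_plain[:, sl] - labels)[keep]))

    train_keep = train.masks[:, sl] == 0
    col_mean = np.where(
        train_keep.sum(axis=0) > 0,
        np.nansum(np.where(train_keep, train.labels[:, sl], 0.0), axis=0)
        / np.maximum(train_keep.sum(axis=0), 1),
        0.0,
    )
    baseline = np.broadcast_to(col_mean, labels.shape)
    mae_baseline = float(np.mean(np.abs(baseline - labels)[keep]))

    return {
        "n_samples": len(data),
        "n_test_samples": len(test),
        "n_test_points": int(keep.sum()),
        "selected_epoch": result.selected_epoch,
        "val_losses": [float(v) for v in result.val_losses],
        "pearson_r": r,
        "mae_db": mae_tta,
        "mae_plain_db": mae_plain,
        "mae_train_mean_baseline_db": mae_baseline,
        "tta_mae_ratio": mae_tta / mae_plain,
    }
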