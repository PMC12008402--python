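"""Volume preprocessing, masked loss, cross-validation and model training.

The regressor maps a standardized OCT volume to the 122-value VF vector.
Targets are z-scored per output position using statistics of the
*unmasked training entries only*; the loss is a mean squared error in
which residuals are multiplied by (1 - mask) and normalized by the
count of unmasked entries, so missing VF data contributes neither loss
nor gradient.  Splits are patient-wise: all samples of a patient live
in exactly one of train/validation/test within each fold.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exams import Laterality
from .labeling import LABEL_LENGTH, label_vector_vertical_permutation
from .nn import Adam, VolumeRegressor

__all__ = [
    "TrainConfig",
    "NormStats",
    "SampleArrays",
    "FoldSplit",
    "preprocess_volume",
    "normalize_volume_laterality",
    "patient_wise_folds",
    "target_normalizer",
    "masked_mse",
    "lr_schedule",
    "augment_sample",
    "predict_tta",
    "train_fold",
    "TrainResult",
]


@dataclass(frozen=True)
class TrainConfig:
    input_shape: tuple[int, int, int] = (64, 64, 32)
    intensity_range: tuple[float, float] = (-1.0, 1.0)
    batch_size: int = 4
    lr_start: float = 6e-4
    lr_peak: float = 1e-3
    warmup_epochs: int = 3
    decay_epochs: int = 5
    dropout_head: float = 0.30
    n_folds: int = 10
    split_ratio: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0
    arch: str = "small3dcnn"
    flip_augment_prob: float = 0.5
    sd_floor: float = 1e-3

    def __post_init__(self):
        if sum(self.split_ratio) != self.n_folds:
            raise ValueError("split_ratio parts must sum to n_folds")
        if self.warmup_epochs < 1 or self.decay_epochs < 1:
            raise ValueError("schedule phases must be at least one epoch")

    @property
    def total_epochs(self) -> int:
        return self.warmup_epochs + self.decay_epochs


@dataclass
class SampleArrays:
    """Column-oriented paired dataset ready for training."""

    volumes: np.ndarray       # (N, H, W, D) preprocessed
    labels: np.ndarray        # (N, 122) dB
    masks: np.ndarray         # (N, 122) in {0, 1}; 1 = absent
    patient_ids: np.ndarray   # (N,) str

    def __post_init__(self):
        n = len(self.volumes)
        if not (len(self.labels) == len(self.masks) == len(self.patient_ids) == n):
            raise ValueError("all columns must have equal length")

    def __len__(self):
        return len(self.volumes)

    def subset(self, idx) -> "SampleArrays":
        return SampleArrays(self.volumes[idx], self.labels[idx],
                            self.masks[idx], self.patient_ids[idx])

    def index_of_patients(self, patients: set) -> np.ndarray:
        return np.flatnonzero(np.isin(self.patient_ids, sorted(patients)))


def preprocess_volume(volume: np.ndarray, cfg: TrainConfig = TrainConfig()) -> np.ndarray:
    """Resample to the model input shape, then min-max map to [-1, 1].

    Trilinear resampling; a constant volume maps to all zeros.
    """
    v = np.asarray(volume, dtype=np.float32)
    if v.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={v.ndim}")
    if v.shape != tuple(cfg.input_shape):
        factors = [t / s for t, s in zip(cfg.input_shape, v.shape)]
        v = ndimage.zoom(v, factors, order=1, grid_mode=True, mode="nearest")
        v = v.astype(np.float32)
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v)
    a, b = cfg.intensity_range
    return ((v - lo) / (hi - lo) * (b - a) + a).astype(np.float32)


def normalize_volume_laterality(volume: np.ndarray, laterality: Laterality) -> np.ndarray:
    """Mirror OS volumes along the horizontal en-face axis (axis 1)."""
    if Laterality(laterality) is Laterality.OS:
        return np.ascontiguousarray(volume[:, ::-1, :])
    return volume


@dataclass(frozen=True)
class FoldSplit:
    fold: int
    train: frozenset
    val: frozenset
    test: frozenset


def patient_wise_folds(patient_ids, cfg: TrainConfig = TrainConfig()) -> list[FoldSplit]:
    """Shuffle patients into n_folds parts; fold i tests part i.

    Fold i: test = part i, val = part (i+1 mod n), train = the rest
    (8:1:1 with the defaults).  Every patient appears in exactly one
    test set across folds, and the three sets of any fold are disjoint.
    """
    patients = sorted(set(map(str, patient_ids)))
    n = cfg.n_folds
    if len(patients) < n:
        raise ValueError(f"need at least {n} patients, got {len(patients)}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(patients))
    parts: list[list[str]] = [[] for _ in range(n)]
    for pos, pidx in enumerate(order):
        parts[pos % n].append(patients[pidx])
    n_test = cfg.split_ratio[2]
    n_val = cfg.split_ratio[1]
    folds = []
    for i in range(n):
        test_parts = [(i + k) % n for k in range(n_test)]
        val_parts = [(i + n_test + k) % n for k in range(n_val)]
        used = set(test_parts) | set(val_parts)
        train_parts = [j for j in range(n) if j not in used]
        folds.append(FoldSplit(
            fold=i,
            train=frozenset(p for j in train_parts for p in parts[j]),
            val=frozenset(p for j in val_parts for p in parts[j]),
            test=frozenset(p for j in test_parts for p in parts[j]),
        ))
    return folds


@dataclass(frozen=True)
class NormStats:
    """Per-output z-score statistics from unmasked training entries."""

    mean: np.ndarray
    sd: np.ndarray
    sd_floor: float

    def apply(self, labels: np.ndarray, masks: np.ndarray) -> np.ndarray:
        z = (labels - self.mean) / self.sd
        z = np.where(masks > 0, 0.0, z)  # masked sentinel: inert under the loss
        return z.astype(np.float32)

    def invert(self, z: np.ndarray) -> np.ndarray:
        return z * self.sd + self.mean


def target_normalizer(labels: np.ndarray, masks: np.ndarray,
                      cfg: TrainConfig = TrainConfig()) -> NormStats:
    """Fit per-position mean/sd over unmasked training entries.

    A position with no unmasked training entry cannot be normalized and
    is reported by index; a constant position gets the sd floor.
    """
    labels = np.asarray(labels, dtype=float)
    masks = np.asarray(masks, dtype=float)
    present = masks == 0
    counts = present.sum(axis=0)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"output positions fully masked in training: {empty.tolist()}")
    w = present.astype(float)
    mean = (labels * w).sum(axis=0) / counts
    var = (((labels - mean) ** 2) * w).sum(axis=0) / counts
    sd = np.maximum(np.sqrt(var), cfg.sd_floor)
    return NormStats(mean=mean, sd=sd, sd_floor=cfg.sd_floor)


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean squared error over unmasked entries (mask 1 = absent)."""
    pred, target, mask = (np.asarray(a, dtype=float) for a in (pred, target, mask))
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError("pred, target and mask must have identical shapes")
    keep = 1.0 - mask
    n = keep.sum()
    if n == 0:
        raise ValueError("all entries masked: loss undefined")
    resid = (pred - target) * keep
    return float((resid ** 2).sum() / n)


def _masked_mse_grad(pred, target, mask):
    keep = 1.0 - mask
    n = keep.sum()
    return (2.0 * (pred - target) * keep / n).astype(np.float32)


def lr_schedule(epoch: int, cfg: TrainConfig = TrainConfig()) -> float:
    """Linear warmup then linear decay, endpoints inclusive (1-based)."""
    total = cfg.total_epochs
    if not (1 <= epoch <= total):
        raise ValueError(f"epoch {epoch} outside schedule 1..{total}")
    if epoch <= cfg.warmup_epochs:
        if cfg.warmup_epochs == 1:
            return cfg.lr_peak
        frac = (epoch - 1) / (cfg.warmup_epochs - 1)
        return cfg.lr_start + frac * (cfg.lr_peak - cfg.lr_start)
    frac = (epoch - cfg.warmup_epochs) / cfg.decay_epochs
    return cfg.lr_peak + frac * (cfg.lr_start - cfg.lr_peak)


_VPERM = None


def _vertical_perm() -> np.ndarray:
    global _VPERM
    if _VPERM is None:
        _VPERM = label_vector_vertical_permutation()
    return _VPERM


def flip_sample_vertically(volume: np.ndarray, label: np.ndarray,
                           mask: np.ndarray):
    """Flip the volume along the superior-inferior axis and permute the
    label/mask vectors accordingly (MD entries stay fixed).  Involution."""
    perm = _vertical_perm()
    return np.ascontiguousarray(volume[::-1, :, :]), label[perm], mask[perm]


def augment_sample(volume, label, mask, rng: np.random.Generator,
                   flip_prob: float = 0.5):
    """Random vertical flip of volume + labels jointly.

    Horizontal (laterality) flips are applied deterministically at
    ingest, never as augmentation.
    """
    if rng.random() < flip_prob:
        return flip_sample_vertically(volume, label, mask)
    return volume, label, mask


def predict_tta(model, volumes: np.ndarray) -> np.ndarray:
    """Average the prediction of each volume and its vertical flip.

    Output = 0.5 * [f(v) + P^-1 f(flip(v))] where P is the vertical
    label permutation (an involution, so P^-1 = P).
    """
    volumes = np.asarray(volumes, dtype=np.float32)
    perm = _vertical_perm()
    plain = model(volumes)
    flipped = model(np.ascontiguousarray(volumes[:, ::-1, :, :]))
    return 0.5 * (plain + flipped[:, perm])


@dataclass
class TrainResult:
    model: VolumeRegressor
    norm: NormStats
    val_losses: list[float] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)
    selected_epoch: int = 0

    def predict_db(self, volumes: np.ndarray, tta: bool = True) -> np.ndarray:
        z = predict_tta(self.model, volumes) if tta else self.model(volumes)
        return self.norm.invert(z)


def train_fold(data: SampleArrays, fold: FoldSplit,
               cfg: TrainConfig = TrainConfig()) -> TrainResult:
    """Train the volumetric regressor on one fold.

    Adam, mini-batches of ``cfg.batch_size``, the warmup/decay LR
    schedule, masked MSE on z-scored targets, random vertical-flip
    augmentation; the state of the epoch with the lowest validation
    masked loss is returned.  Fully seeded and deterministic for a
    fixed thread configuration.
    """
    tr_idx = data.index_of_patients(set(fold.train))
    va_idx = data.index_of_patients(set(fold.val))
    if tr_idx.size == 0 or va_idx.size == 0:
        raise ValueError("empty train or validation set for this fold")
    train = data.subset(tr_idx)
    val = data.subset(va_idx)

    norm = target_normalizer(train.labels, train.masks, cfg)
    y_tr = norm.apply(train.labels, train.masks)
    y_va = norm.apply(val.labels, val.masks)

    model = VolumeRegressor(n_outputs=LABEL_LENGTH, arch=cfg.arch,
                            dropout=cfg.dropout_head, seed=cfg.seed)
    opt = Adam(model.layers, lr=cfg.lr_start)
    rng = np.random.default_rng(cfg.seed + 1)

    best_loss, best_state, best_epoch = np.inf, None, 0
    val_losses, train_losses = [], []
    n = len(train)
    for epoch in range(1, cfg.total_epochs + 1):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            vols, labs, msks = [], [], []
            for i in idx:
                v, l, m = augment_sample(
                    train.volumes[i], y_tr[i], train.masks[i], rng,
                    flip_prob=cfg.flip_augment_prob,
                )
                vols.append(v)
                labs.append(l)
                msks.append(m)
            vb = np.stack(vols)
            lb = np.stack(labs)
            mb = np.stack(msks)
            pred = model.forward(vb, train=True)
            loss = masked_mse(pred, lb, mb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            model.backward(_masked_mse_grad(pred, lb, mb))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        train_losses.append(epoch_loss / n_batches)

        val_pred = model.forward(val.volumes, train=False)
        v_loss = masked_mse(val_pred, y_va, val.masks)
        if not np.isfinite(v_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        val_losses.append(v_loss)
        if v_loss < best_loss:
            best_loss, best_epoch = v_loss, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(model=model, norm=norm, val_losses=val_losses,
                       train_losses=train_losses, selected_epoch=best_epoch)
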