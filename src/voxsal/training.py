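"""Seeded k-fold training of the residual classifier.

Hyperparameters default to the study's printed set: Adam, mini-batch 10,
20 epochs, static learning rate 3e-4, L2 regularization 5e-4, shuffling
each epoch, a 5x learning-rate multiplier on the fully connected head, and
inputs rescaled from [0, 255] to [0, 1].  Each training volume receives a
freshly drawn harmonization augmentation every epoch: Gaussian blur with a
uniform random standard deviation in [0, 1.5] voxels, a 2% overall
intensity drop, then per-voxel uniform noise in [0, 5].  The augmentation
injects randomness in exactly the domains where mixed-scanner MRI data
carries non-class-specific variation (blur, global intensity, noise floor),
discouraging the classifier from keying on acquisition artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from .model import ArchitectureSpec, ResidualClassifier3D, build_model, recalibrate_batchnorm
from .nn import Adam
from .types import CLASSES, CT, PD, SubjectRecord, VolumeGrid


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; defaults are the printed hyperparameter set."""

    batch_size: int = 10
    epochs: int = 20
    learning_rate: float = 3.0e-4
    l2: float = 5.0e-4
    shuffle_each_epoch: bool = True
    fc_lr_multiplier: float = 5.0
    rescale_input: bool = True
    augment: bool = True
    augment_reps: int = 1  # independently augmented copies of the training set per epoch
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("batch_size", "epochs", "learning_rate", "l2", "fc_lr_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FoldAssignment:
    k: int
    membership: dict[str, int]

    def test_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.membership.items() if f == fold]

    def train_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.membership.items() if f != fold]


class SingleClassError(ValueError):
    """Training requires both classes in the training partition."""


def assign_folds(
    subject_ids: Sequence[str],
    k: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
) -> FoldAssignment:
    """Randomly partition subjects into k folds, stratified by class.

    Fold sizes differ by at most one overall and per class.  With
    ``labels=None`` all subjects form one stratum (plain random folds).
    """
    n = len(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    if labels is None:
        labels = ["_"] * n
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(k)
    membership: dict[str, int] = {}
    cursor = 0
    for cls in sorted(set(labels)):
        ids = [sid for sid, lab in zip(subject_ids, labels) if lab == cls]
        for sid in rng.permutation(ids):
            membership[str(sid)] = int(fold_order[cursor % k])
            cursor += 1
    return FoldAssignment(k=k, membership=membership)


def augment(volume: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One harmonization draw: blur -> 2% intensity drop -> uniform noise.

    Operates on [0, 255] intensities.  The blur kernel radius at the maximal
    sd (1.5 voxels) stays well inside a 16-cubed window.
    """
    vol = np.asarray(volume, dtype=np.float64)
    sd = rng.uniform(0.0, 1.5)
    if sd > 0:
        vol = gaussian_filter(vol, sigma=sd)
    vol = vol * 0.98 + rng.uniform(0.0, 5.0, size=vol.shape)
    return np.clip(vol, 0.0, 255.0)


def _as_array(volumes: Sequence) -> np.ndarray:
    data = [v.data if isinstance(v, VolumeGrid) else np.asarray(v) for v in volumes]
    return np.stack(data).astype(np.float32)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train_fold(
    train_volumes: Sequence,
    train_labels: Sequence[str],
    config: TrainingConfig,
    spec: ArchitectureSpec,
) -> tuple[ResidualClassifier3D, list[float]]:
    """Train one classifier on one fold's training partition.

    Returns the trained model and the per-epoch mean cross-entropy trace.
    Every randomness source (init, shuffling, dropout, augmentation) derives
    from ``config.seed``, so the trace is bit-reproducible on one machine.
    """
    labels = list(train_labels)
    if len(set(labels)) < 2:
        raise SingleClassError(
            f"training partition contains a single class {set(labels)}; "
            "both classes are required"
        )
    x_raw = _as_array(train_volumes)
    y = np.array([CLASSES.index(lab) for lab in labels])

    rng = np.random.default_rng(config.seed)
    model = build_model(spec, seed=int(rng.integers(2**31)))
    model.dropout.rng = np.random.default_rng(int(rng.integers(2**31)))
    params = model.params()
    for p in params:
        if p.name.startswith("fc"):
            p.lr_mult = config.fc_lr_multiplier
    opt = Adam(params, lr=config.learning_rate, l2=config.l2)

    n = len(labels)
    trace: list[float] = []
    for _epoch in range(config.epochs):
        if config.augment:
            # each training volume contributes `augment_reps` independently
            # augmented copies per epoch, re-drawn every epoch
            x_epoch = np.stack(
                [augment(v, rng) for _ in range(config.augment_reps) for v in x_raw]
            ).astype(np.float32)
            y_epoch = np.tile(y, config.augment_reps)
        else:
            x_epoch, y_epoch = x_raw, y
        if config.rescale_input:
            x_epoch = x_epoch / 255.0
        m = len(y_epoch)
        order = rng.permutation(m) if config.shuffle_each_epoch else np.arange(m)
        losses = []
        for start in range(0, m, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x_epoch[idx][:, None]  # single channel
            yb = y_epoch[idx]
            logits = model.forward(xb, train=True)
            probs = _softmax(logits)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            glogits = probs.copy()
            glogits[np.arange(len(yb)), yb] -= 1.0
            glogits /= len(yb)
            opt.zero_grad()
            model.backward(glogits.astype(np.float32))
            opt.step()
            losses.append(float(loss))
        trace.append(float(np.mean(losses)))
    # exponential running averages lag the final weights after so few steps;
    # replace them with exact statistics over the clean training volumes
    x_ref = x_raw / 255.0 if config.rescale_input else x_raw
    recalibrate_batchnorm(model, x_ref[:, None], batch_size=max(config.batch_size, 15))
    return model, trace


def predict(
    model: ResidualClassifier3D,
    volumes: Sequence,
    rescale_input: bool = True,
    batch_size: int = 10,
) -> tuple[list[str], np.ndarray]:
    """Deterministic-eval class predictions and pre-softmax scores."""
    x = _as_array(volumes)
    if rescale_input:
        x = x / 255.0
    scores = []
    for start in range(0, len(x), batch_size):
        scores.append(model.predict_scores(x[start : start + batch_size][:, None]))
    scores = np.concatenate(scores)
    labels = [CLASSES[i] for i in scores.argmax(axis=1)]
    return labels, scores


@dataclass
class EvalSummary:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def evaluate(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> EvalSummary:
    """Binary classification metrics with the patient class as positive."""
    if len(true_labels) == 0 or len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must be non-empty and equal length")
    yt = [1 if lab == PD else 0 for lab in true_labels]
    yp = [1 if lab == PD else 0 for lab in predicted_labels]
    return EvalSummary(
        accuracy=float(accuracy_score(yt, yp)),
        precision=float(precision_score(yt, yp, zero_division=0)),
        recall=float(recall_score(yt, yp, zero_division=0)),
        f1=float(f1_score(yt, yp, zero_division=0)),
    )


def summarize_folds(per_fold: Sequence[EvalSummary]) -> dict[str, tuple[float, float]]:
    """Pooled summary: mean over folds with 1.96 * (sd / sqrt(k)) half-widths."""
    out = {}
    k = len(per_fold)
    for metric in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(s, metric) for s in per_fold])
        hw = 1.96 * vals.std(ddof=1) / np.sqrt(k) if k > 1 else 0.0
        out[metric] = (float(vals.mean()), float(hw))
    return out


def cross_validate(
    subjects: Sequence[SubjectRecord],
    volumes: Sequence,
    config: TrainingConfig,
    spec: ArchitectureSpec,
    k: int = 4,
) -> tuple[dict[int, ResidualClassifier3D], FoldAssignment, list[EvalSummary]]:
    """Full k-fold run: train per fold, predict each hold-out partition.

    Fold index and predicted class are recorded on every subject record.
    """
    ids = [s.id for s in subjects]
    labels = [s.true_class for s in subjects]
    folds = assign_folds(ids, k, seed=config.seed, labels=labels)
    by_id = {s.id: i for i, s in enumerate(subjects)}
    for s in subjects:
        s.fold = folds.membership[s.id]

    models: dict[int, ResidualClassifier3D] = {}
    summaries: list[EvalSummary] = []
    for fold in range(k):
        tr = folds.train_ids(fold)
        te = folds.test_ids(fold)
        fold_cfg = TrainingConfig(
            **{
                **config.__dict__,
                "seed": int(np.random.default_rng([config.seed, fold]).integers(2**31)),
            }
        )
        model, _ = train_fold(
            [volumes[by_id[i]] for i in tr],
            [subjects[by_id[i]].true_class for i in tr],
            fold_cfg,
            spec,
        )
        models[fold] = model
        preds, _scores = predict(
            model, [volumes[by_id[i]] for i in te], rescale_input=config.rescale_input
        )
        for sid, pred in zip(te, preds):
            subjects[by_id[sid]].predicted_class = pred
        summaries.append(
            evaluate([subjects[by_id[i]].true_class for i in te], preds)
        )
    return models, folds, summaries
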