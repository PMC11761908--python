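"""Cross-validated training protocol and test-set evaluation.

The protocol: the training split is partitioned into k stratified folds
(stratified by class x modality); for each fold a fresh classifier is
trained with Adam and categorical cross-entropy for a fixed number of
epochs on the other k-1 folds, one epoch record (train/validation loss and
accuracy) is logged per epoch, the weights at the best validation accuracy
are kept, and that checkpoint is evaluated on the single fixed held-out
test split.  Per-fold reports are aggregated by
:func:`dsunet.metrics.aggregate_folds`.  Weight initialization, fold
assignment, and batch order are all derived from one seed, so a rerun
reproduces identical histories bit for bit.

The full-scale protocol defaults (Adam at 1e-5, batch 16, 50 epochs, 5 folds)
live in :class:`TrainConfig`; desk-scale runs override them explicitly.
"""

from __future__ import annotations

import copy
import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import Adam, softmax_cross_entropy
from .dsconv_net import (DSUNetClassifier, ModelConfig, save_checkpoint)
from .errors import InvalidInputError, NumericError
from .io_preprocess import DatasetManifest, load_processed
from .metrics import CLASSES, MetricsReport, aggregate_folds

__all__ = [
    "TrainConfig",
    "EpochRecord",
    "FoldResult",
    "make_folds",
    "train_fold",
    "evaluate_on_test",
    "cross_validate",
]

_LABEL_INDEX = {c: i for i, c in enumerate(CLASSES)}


@dataclasses.dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the published protocol)."""

    learning_rate: float = 1e-5
    optimizer: str = "adam"
    batch_size: int = 16
    epochs: int = 50
    k_folds: int = 5
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self):
        if self.k_folds < 2:
            raise InvalidInputError("k_folds must be >= 2")
        if self.epochs < 1:
            raise InvalidInputError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise InvalidInputError("only the adam optimizer is supported")
        if self.loss != "categorical_cross_entropy":
            raise InvalidInputError("only categorical cross-entropy is supported")


@dataclasses.dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_loss: float
    val_acc: float


@dataclasses.dataclass
class FoldResult:
    fold: int
    history: list[EpochRecord]
    best_epoch: int
    best_state: dict
    test_report: MetricsReport | None = None

    @property
    def best_val_acc(self) -> float:
        return self.history[self.best_epoch - 1].val_acc


def make_folds(manifest: DatasetManifest, k: int, seed: int) -> pd.DataFrame:
    """Assign folds 1..k to the training split, stratified by class x modality.

    Returns a copy of the manifest frame with the ``fold`` column filled for
    training records (``none`` elsewhere).  Folds are disjoint, cover the
    training split, and are balanced within every class x modality cell.
    """
    frame = manifest.frame.copy()
    train_mask = frame["split"] == "train"
    rng = np.random.default_rng(seed)
    fold_col = frame["fold"].astype(str).copy()
    for (_, _), group in frame[train_mask].groupby(["label", "modality"]):
        if len(group) < k:
            raise InvalidInputError(
                "every class x modality cell needs at least k members")
        order = group.index.to_numpy()[rng.permutation(len(group))]
        for pos, idx in enumerate(order):
            fold_col.loc[idx] = str(pos % k + 1)
    frame["fold"] = fold_col
    return frame


def _load_batch(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Load preprocessed images as (N, C, H, W) float64 plus label indices."""
    xs, ys = [], []
    for rec in frame.itertuples(index=False):
        arr = load_processed(rec.path)
        xs.append(np.transpose(arr, (2, 0, 1)))
        ys.append(_LABEL_INDEX[rec.label])
    return np.asarray(xs, dtype=np.float64), np.asarray(ys, dtype=np.int64)


def _epoch_eval(model: DSUNetClassifier, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i:i + batch_size], y[i:i + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((np.argmax(logits, axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), 100.0 * correct / len(x)


def train_fold(fold: int, train_frame: pd.DataFrame, val_frame: pd.DataFrame,
               model_config: ModelConfig, train_config: TrainConfig) -> FoldResult:
    """Train one fold; checkpoint the epoch with the best validation accuracy."""
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=train_config.seed, spawn_key=(fold,)))
    model = DSUNetClassifier(model_config,
                             seed=int(rng.integers(2 ** 31)))
    opt = Adam(model.params(), lr=train_config.learning_rate)
    x_train, y_train = _load_batch(train_frame)
    x_val, y_val = _load_batch(val_frame)

    history: list[EpochRecord] = []
    best_epoch, best_acc, best_state = 0, -1.0, None
    bs = train_config.batch_size
    for epoch in range(1, train_config.epochs + 1):
        order = rng.permutation(len(x_train))
        ep_losses, correct = [], 0
        for i in range(0, len(order), bs):
            sel = order[i:i + bs]
            xb, yb = x_train[sel], y_train[sel]
            opt.zero_grad()
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise NumericError(f"non-finite loss at fold {fold}, epoch {epoch}")
            model.backward(dlogits)
            opt.step()
            ep_losses.append(loss * len(xb))
            correct += int((np.argmax(logits, axis=1) == yb).sum())
        train_loss = float(np.sum(ep_losses) / len(x_train))
        train_acc = 100.0 * correct / len(x_train)
        val_loss, val_acc = _epoch_eval(model, x_val, y_val, bs)
        history.append(EpochRecord(epoch, train_loss, train_acc, val_loss, val_acc))
        if val_acc > best_acc:
            best_epoch, best_acc = epoch, val_acc
            best_state = copy.deepcopy(model.state_dict())
    return FoldResult(fold=fold, history=history, best_epoch=best_epoch,
                      best_state=best_state)


def evaluate_on_test(model: DSUNetClassifier, test_frame: pd.DataFrame,
                     batch_size: int = 64, fold=None) -> MetricsReport:
    """Deterministic inference (running BN statistics) on the test split."""
    x, y = _load_batch(test_frame)
    preds = []
    for i in range(0, len(x), batch_size):
        preds.append(model.predict(x[i:i + batch_size]))
    preds = np.concatenate(preds)
    y_true = [CLASSES[i] for i in y]
    y_pred = [CLASSES[i] for i in preds]
    return MetricsReport.from_predictions(y_true, y_pred, fold=fold)


def cross_validate(manifest: DatasetManifest, model_config: ModelConfig,
                   train_config: TrainConfig,
                   out_dir: str | os.PathLike | None = None
                   ) -> tuple[list[FoldResult], MetricsReport]:
    """Full protocol: fold assignment, per-fold training, fixed-test
    evaluation, and aggregation.  Optionally writes histories (CSV),
    reports (JSON), and per-fold checkpoints under ``out_dir``."""
    frame = make_folds(manifest, train_config.k_folds, train_config.seed)
    test_frame = frame[frame["split"] == "test"]
    if len(test_frame) == 0:
        raise InvalidInputError("manifest has no test split")
    results: list[FoldResult] = []
    reports: list[MetricsReport] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for fold in range(1, train_config.k_folds + 1):
        train_mask = (frame["split"] == "train") & (frame["fold"] != str(fold))
        val_mask = (frame["split"] == "train") & (frame["fold"] == str(fold))
        result = train_fold(fold, frame[train_mask], frame[val_mask],
                            model_config, train_config)
        model = DSUNetClassifier(model_config)
        model.load_state_dict(result.best_state)
        result.test_report = evaluate_on_test(model, test_frame, fold=fold)
        results.append(result)
        reports.append(result.test_report)
        if out_dir is not None:
            save_checkpoint(model, out_dir / f"fold{fold}.npz",
                            seed=train_config.seed)
            result.test_report.to_json(out_dir / f"fold{fold}_report.json")
    aggregate = aggregate_folds(reports)
    if out_dir is not None:
        hist = pd.DataFrame([
            {"fold": r.fold, "epoch": e.epoch, "train_loss": e.train_loss,
             "train_acc": e.train_acc, "val_loss": e.val_loss, "val_acc": e.val_acc}
            for r in results for e in r.history])
        hist.to_csv(out_dir / "history.csv", index=False)
        aggregate.to_json(out_dir / "aggregate_report.json")
    return results, aggregate
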