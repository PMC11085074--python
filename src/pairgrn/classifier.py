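"""Convolutional pair-image classifier and evaluation metrics.

The classifier maps a pair image (the stacked joint-expression histogram
of a TF and a candidate target) to a score in [0, 1]; the closer to 1, the
more likely the TF regulates the candidate. The architecture is six 3x3
convolutions with max pooling after the 2nd, 4th and 6th, a flatten, two
dense hidden layers and a single sigmoid output unit, trained with Adam on
binary cross-entropy with early stopping on validation AUROC.

:class:`PairImageCNN` follows the scikit-learn estimator contract
(``fit``/``predict``/``predict_proba``/``get_params``) so it composes with
sklearn model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .featurize import HistogramConfig, PairImage, build_image_corpus, images_to_array
from .pairs import GenePairLabelSet, kfold_partitions

logger = logging.getLogger(__name__)


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation settings.

    The layer inventory is fixed (six convolutions, three pools, two dense
    hidden layers, one sigmoid unit); widths, kernel, learning rate and
    stopping rules are tunable.
    """

    input_shape: tuple[int, int] = (64, 32)
    conv_filters: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel_size: int = 3
    pool_after: tuple[int, ...] = (2, 4, 6)  # 1-based conv indices
    pool_size: int = 2
    dense_widths: tuple[int, ...] = (128, 64)
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    early_stop_patience: int = 5
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 6:
            raise ClassifierError("exactly 6 convolutional layers are required")
        if len(self.pool_after) != 3:
            raise ClassifierError("exactly 3 pooling positions are required")
        if len(self.dense_widths) != 2:
            raise ClassifierError("exactly 2 dense hidden layers are required")


def build_model(config: ModelConfig) -> _nn.Network:
    """Assemble the untrained network, validating pooling feasibility."""
    rng = np.random.default_rng(config.seed)
    h, w = config.input_shape
    pool_set = set(config.pool_after)
    layers: list[_nn.Layer] = []
    in_ch = 1
    for i, n_filters in enumerate(config.conv_filters, start=1):
        layers.append(_nn.Conv2D(in_ch, n_filters, config.kernel_size, rng))
        layers.append(_nn.ReLU())
        in_ch = n_filters
        if i in pool_set:
            h //= config.pool_size
            w //= config.pool_size
            if h < 1 or w < 1:
                raise ClassifierError(
                    f"pooling after convolution {i} reduces spatial dims to "
                    f"({h}, {w}); input {config.input_shape} is too small"
                )
            layers.append(_nn.MaxPool2D(config.pool_size))
    layers.append(_nn.Flatten())
    n_in = in_ch * h * w
    for width in config.dense_widths:
        layers.append(_nn.Dense(n_in, width, rng))
        layers.append(_nn.ReLU())
        n_in = width
    layers.append(_nn.Dense(n_in, 1, rng))  # sigmoid applied in the loss/head
    return _nn.Network(layers)


class PairImageCNN(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style convolutional classifier for pair images.

    Parameters mirror :class:`ModelConfig`; ``fit`` expects ``X`` of shape
    (n_images, rows, cols) and binary ``y``. Fully deterministic for a
    fixed ``seed``.
    """

    def __init__(
        self,
        conv_filters: tuple[int, ...] = (32, 32, 64, 64, 128, 128),
        kernel_size: int = 3,
        pool_after: tuple[int, ...] = (2, 4, 6),
        pool_size: int = 2,
        dense_widths: tuple[int, ...] = (128, 64),
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 50,
        early_stop_patience: int = 5,
        validation_fraction: float = 0.1,
        seed: int = 0,
        histogram_digest: str | None = None,
    ):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.pool_after = pool_after
        self.pool_size = pool_size
        self.dense_widths = dense_widths
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.histogram_digest = histogram_digest

    # -- estimator API ----------------------------------------------------

    def _make_config(self, input_shape: tuple[int, int]) -> ModelConfig:
        return ModelConfig(
            input_shape=input_shape,
            conv_filters=tuple(self.conv_filters),
            kernel_size=self.kernel_size,
            pool_after=tuple(self.pool_after),
            pool_size=self.pool_size,
            dense_widths=tuple(self.dense_widths),
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            validation_fraction=self.validation_fraction,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PairImageCNN":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 3:
            raise ClassifierError(
                f"X must be (n_images, rows, cols), got shape {X.shape}"
            )
        if X.shape[0] != y.shape[0]:
            raise ClassifierError("X and y lengths differ")
        classes = np.unique(y)
        if classes.size < 2:
            raise ClassifierError("training requires both classes present")
        if not np.isin(classes, (0.0, 1.0)).all():
            raise ClassifierError("labels must be binary 0/1")

        config = self._make_config(X.shape[1:])
        net = build_model(config)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

        n = X.shape[0]
        n_val = int(round(config.validation_fraction * n))
        if n_val > 0:
            val_idx = _stratified_sample(y, n_val, rng)
            train_mask = np.ones(n, dtype=bool)
            train_mask[val_idx] = False
            X_tr, y_tr = X[train_mask], y[train_mask]
            X_val, y_val = X[val_idx], y[val_idx]
            monitor_val = np.unique(y_val).size == 2
        else:
            X_tr, y_tr = X, y
            X_val = y_val = None
            monitor_val = False

        X_tr4 = X_tr[:, None, :, :]
        opt = _nn.Adam(net.parameters(), lr=config.learning_rate)
        history: list[dict] = []
        best_metric = -math.inf
        best_state = net.get_state()
        patience_left = config.early_stop_patience
        for epoch in range(1, config.max_epochs + 1):
            perm = rng.permutation(X_tr4.shape[0])
            epoch_loss = 0.0
            n_batches = 0
            for lo in range(0, perm.size, config.batch_size):
                idx = perm[lo : lo + config.batch_size]
                logits = net.forward(X_tr4[idx])
                loss, dlogits = _nn.bce_with_logits(logits, y_tr[idx])
                net.backward(dlogits)
                opt.step(net.gradients())
                epoch_loss += loss
                n_batches += 1
            epoch_loss /= max(n_batches, 1)
            record = {"epoch": epoch, "loss": epoch_loss}
            if monitor_val:
                val_scores = net.predict_proba(X_val[:, None, :, :])
                val_auroc = float(roc_auc_score(y_val, val_scores))
                record["val_auroc"] = val_auroc
                metric = val_auroc
            else:
                metric = -epoch_loss
            history.append(record)
            logger.info(
                "epoch %d: loss %.4f%s", epoch, epoch_loss,
                f", val AUROC {record['val_auroc']:.4f}" if monitor_val else "",
            )
            if metric > best_metric + 1e-9:
                best_metric = metric
                best_state = net.get_state()
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stop at epoch %d", epoch)
                    break
        net.set_state(best_state)

        self.net_ = net
        self.config_ = config
        self.history_ = history
        self.classes_ = np.array([0, 1])
        self.input_shape_ = tuple(X.shape[1:])
        return self

    def predict_scores(self, X: np.ndarray | Sequence[PairImage]) -> np.ndarray:
        """Regulation scores in [0, 1], one per image, order preserved."""
        check_is_fitted(self, "net_")
        if len(X) and isinstance(X[0], PairImage):
            X = images_to_array(X)
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] == 0:
            return np.empty(0)
        if X.shape[1:] != self.input_shape_:
            raise ClassifierError(
                f"image shape {X.shape[1:]} does not match the fitted "
                f"input shape {self.input_shape_}"
            )
        return self.net_.predict_proba(X[:, None, :, :])

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_scores(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_scores(X) > 0.5).astype(int)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters + configuration to a single ``.npz`` container."""
        check_is_fitted(self, "net_")
        meta = {
            "params": self.get_params(),
            "input_shape": list(self.input_shape_),
            "histogram_digest": self.histogram_digest,
        }
        arrays = {f"p{i}": p for i, p in enumerate(self.net_.parameters())}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta, default=list).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PairImageCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in meta["params"].items()
            }
            est = cls(**params)
            input_shape = tuple(meta["input_shape"])
            est.config_ = est._make_config(input_shape)
            est.net_ = build_model(est.config_)
            state = [data[f"p{i}"] for i in range(len(est.net_.parameters()))]
            est.net_.set_state(state)
            est.input_shape_ = input_shape
            est.history_ = []
            est.classes_ = np.array([0, 1])
        return est


def _stratified_sample(y: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a stratified sample of ~n records (at least 1 per class)."""
    chosen: list[int] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_cls = max(1, int(round(n * idx.size / y.size)))
        n_cls = min(n_cls, idx.size - 1) if idx.size > 1 else n_cls
        chosen.extend(rng.choice(idx, size=n_cls, replace=False).tolist())
    return np.array(sorted(chosen))


# -- functional wrappers over the estimator --------------------------------

def train(
    images: Sequence[PairImage],
    labels: Sequence[int] | None = None,
    config: ModelConfig | None = None,
) -> PairImageCNN:
    """Train a fresh classifier on labeled pair images."""
    config = config or ModelConfig()
    X = images_to_array(images)
    if labels is None:
        labels = [im.label for im in images]
        if any(l is None for l in labels):
            raise ClassifierError("images carry no labels and none were supplied")
    est = PairImageCNN(
        conv_filters=config.conv_filters,
        kernel_size=config.kernel_size,
        pool_after=config.pool_after,
        pool_size=config.pool_size,
        dense_widths=config.dense_widths,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        validation_fraction=config.validation_fraction,
        seed=config.seed,
    )
    return est.fit(X, np.asarray(labels))


def predict_scores(model: PairImageCNN, images: Sequence[PairImage]) -> np.ndarray:
    return model.predict_scores(images)


# -- metrics ---------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ClassifierError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    """Threshold metrics; ``None`` flags an undefined (0/0) quantity."""

    tpr: float | None
    fpr: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    auroc: float | None = None


def confusion_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Counts with predicted-positive defined by score strictly above threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ClassifierError("scores and labels lengths differ")
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """TPR, FPR, precision, recall and F1 from confusion counts.

    TPR = TP/(TP+FN), FPR = FP/(FP+TN), precision = TP/(TP+FP),
    recall = TPR, F1 = 2*precision*recall/(precision+recall). A 0/0 is
    flagged as ``None`` rather than raised or coerced to 0.
    """
    tpr = _ratio(counts.tp, counts.tp + counts.fn)
    fpr = _ratio(counts.fp, counts.fp + counts.tn)
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = tpr
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(tpr=tpr, fpr=fpr, precision=precision,
                                 recall=recall, f1=f1)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank formulation, ties counted half)."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ClassifierError("AUROC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def cross_validate(
    pairs: GenePairLabelSet,
    bulk,
    sc,
    hist_config: HistogramConfig | None = None,
    model_config: ModelConfig | None = None,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> dict:
    """Repeated k-fold cross-validation; a fresh model per partition.

    Returns per-partition AUROC values plus their mean and standard
    deviation.
    """
    hist_config = hist_config or HistogramConfig()
    model_config = model_config or ModelConfig()
    images, n_skipped = build_image_corpus(pairs, bulk, sc, hist_config)
    if n_skipped:
        raise ClassifierError(
            f"{n_skipped} pair(s) reference genes absent from the matrices"
        )
    X = images_to_array(images)
    y = pairs.labels
    results = []
    for rep, fold, train_idx, test_idx in kfold_partitions(pairs, k, repeats, seed):
        fold_seed = int(
            np.random.SeedSequence([seed, rep, fold]).generate_state(1)[0] % (2**31)
        )
        cfg = ModelConfig(**{**asdict(model_config),
                             "input_shape": X.shape[1:], "seed": fold_seed})
        est = train([images[i] for i in train_idx], y[train_idx], cfg)
        value = auroc(est.predict_scores(X[test_idx]), y[test_idx])
        results.append({"repeat": rep, "fold": fold, "auroc": value})
        logger.info("cv repeat %d fold %d: AUROC %.4f", rep, fold, value)
    values = np.array([r["auroc"] for r in results])
    return {
        "per_partition": results,
        "auroc_values": values,
        "mean_auroc": float(values.mean()),
        "sd_auroc": float(values.std(ddof=1)) if values.size > 1 else 0.0,
    }
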