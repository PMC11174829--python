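"""Experimental protocol: splits, training loop, metrics, cross-validation,
ablation suite, embedding export.

The canonical protocol is an 8:1:1 stratified train/validation/test split,
30 training epochs with Adam (lr 1e-3, batch 32) minimizing cross-entropy,
checkpoint selection by best validation accuracy, and evaluation by
accuracy / precision / recall / F1 from the binary confusion matrix
(positive class = ictal).  k-fold cross-validation rotates the test and
validation parts and averages fold accuracies arithmetically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import VARIANTS, DualStreamModel, ModelConfig, build_model
from .signal_features import FeaturizedDataset


@dataclass
class SplitSpec:
    ratios: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r <= 0):
            raise ValueError("split ratios must be positive")
        self.ratios = tuple(r / r.sum())


@dataclass
class EvalReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray           # rows = true class, cols = predicted
    degenerate: bool = False        # a zero-denominator metric was forced to 0
    per_fold_acc: Optional[list] = None
    embeddings: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1,
             "confusion": np.asarray(self.confusion).tolist(),
             "degenerate": self.degenerate}
        if self.per_fold_acc is not None:
            d["per_fold_acc"] = list(map(float, self.per_fold_acc))
        return d


# ---------------------------------------------------------------------------
# splitting

def _apportion(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items into len(ratios) parts."""
    quotas = np.asarray(ratios) * n
    base = np.floor(quotas).astype(int)
    short = n - base.sum()
    order = np.argsort(-(quotas - base))
    base[order[:short]] += 1
    return base.tolist()


def split_dataset(labels: np.ndarray, spec: SplitSpec):
    """Return (train_idx, val_idx, test_idx) index arrays.

    Stratified (default): each class is apportioned separately with the
    largest-remainder rule, so a balanced 1000-window set under 8:1:1 gives
    exactly 800/100/100.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 windows to split 8:1:1")
    rng = np.random.default_rng(spec.seed)
    parts = [[], [], []]
    if spec.stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            sizes = _apportion(idx.size, spec.ratios)
            if min(sizes) == 0:
                raise ValueError(
                    f"class {cls} (n={idx.size}) cannot cover all three "
                    "splits under stratification")
            bounds = np.cumsum(sizes)[:-1]
            for part, chunk in zip(parts, np.split(idx, bounds)):
                part.append(chunk)
    else:
        idx = rng.permutation(n)
        sizes = _apportion(n, spec.ratios)
        bounds = np.cumsum(sizes)[:-1]
        for part, chunk in zip(parts, np.split(idx, bounds)):
            part.append(chunk)
    train, val, test = (np.sort(np.concatenate(p)) for p in parts)
    return train, val, test


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int],
                    positive_class: int = 1) -> EvalReport:
    """Binary confusion matrix and accuracy/precision/recall/F1.

    Zero-denominator metrics are reported as 0 with ``degenerate=True``
    rather than raising, so degenerate folds do not abort a suite.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label sequences differ in length")
    for arr, name in ((y_true, "true"), (y_pred, "predicted")):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} labels outside {{0,1}}: {sorted(bad)}")
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[t, p] += 1
    pos = positive_class
    neg = 1 - pos
    tp, fp = conf[pos, pos], conf[neg, pos]
    fn, tn = conf[pos, neg], conf[neg, neg]
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    f1 = _ratio(2.0 * precision * recall, precision + recall)
    accuracy = (tp + tn) / y_true.size
    return EvalReport(accuracy, precision, recall, f1, conf, degenerate)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainResult:
    model: DualStreamModel
    history: pd.DataFrame
    best_epoch: int
    best_val_acc: float


def _predict(model: DualStreamModel, feats, specs, batch_size: int = 64):
    model.set_training(False)
    preds, fused = [], []
    for i in range(0, feats.shape[0], batch_size):
        out = model.forward(feats[i:i + batch_size],
                            specs[i:i + batch_size] if specs is not None else None)
        preds.append(out.probs.argmax(axis=1))
        fused.append(out.fused)
    return np.concatenate(preds), np.concatenate(fused)


def _eval_loss_acc(model, feats, specs, labels, batch_size: int = 64):
    from . import nn
    model.set_training(False)
    losses, correct = [], 0
    for i in range(0, feats.shape[0], batch_size):
        out = model.forward(feats[i:i + batch_size],
                            specs[i:i + batch_size] if specs is not None else None)
        yb = labels[i:i + batch_size]
        loss, _ = nn.cross_entropy(out.logits, yb)
        losses.append(loss * yb.size)
        correct += int((out.probs.argmax(axis=1) == yb).sum())
    return sum(losses) / labels.size, correct / labels.size


def train(model: DualStreamModel, train_data, val_data, epochs: int = 30,
          seed: int = 0, lr: float = 1e-3, batch_size: int = 32) -> TrainResult:
    """Minimize cross-entropy with Adam; keep the best-validation checkpoint.

    ``train_data``/``val_data`` are ``(features, spectrograms_or_None,
    labels)`` triples.  All randomness (batch order) flows from ``seed``.
    """
    from . import nn
    ftr, str_, ytr = train_data
    fva, sva, yva = val_data
    if ytr.size == 0 or yva.size == 0:
        raise ValueError("empty training or validation set")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    opt = nn.Adam(model.layers(), lr=lr)
    rng = np.random.default_rng(seed)
    rows = []
    best = (-1.0, 0, None)  # (val_acc, epoch, snapshot)
    for epoch in range(1, epochs + 1):
        model.set_training(True)
        order = rng.permutation(ytr.size)
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, order.size, batch_size):
            sel = order[i:i + batch_size]
            out = model.forward(ftr[sel], str_[sel] if str_ is not None else None)
            loss, dlogits = nn.cross_entropy(out.logits, ytr[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            model.backward(dlogits.astype(model.dtype), out)
            opt.step()
            ep_loss += loss * sel.size
            ep_correct += int((out.probs.argmax(axis=1) == ytr[sel]).sum())
        val_loss, val_acc = _eval_loss_acc(model, fva, sva, yva)
        rows.append({"epoch": epoch, "train_loss": ep_loss / ytr.size,
                     "train_acc": ep_correct / ytr.size,
                     "val_loss": val_loss, "val_acc": val_acc})
        if val_acc > best[0]:
            best = (val_acc, epoch, model.snapshot())
    if best[2] is not None:
        model.load_state(best[2])
    return TrainResult(model, pd.DataFrame(rows), best[1], best[0])


def evaluate(model: DualStreamModel, data) -> EvalReport:
    feats, specs, labels = data
    preds, fused = _predict(model, feats, specs)
    report = compute_metrics(labels, preds)
    report.embeddings = fused
    return report


# ---------------------------------------------------------------------------
# higher-level protocols

def _take(ds: FeaturizedDataset, idx: np.ndarray, use_specs: bool):
    specs = ds.spectrograms[idx][:, None] if use_specs else None
    return ds.features[idx], specs, ds.labels[idx]


def run_experiment(ds: FeaturizedDataset, cfg: ModelConfig | None = None,
                   epochs: int = 30, seed: int = 0, lr: float = 1e-3,
                   batch_size: int = 32, split: SplitSpec | None = None):
    """Split 8:1:1, train, evaluate on the held-out test set.

    Returns ``(TrainResult, EvalReport, (train_idx, val_idx, test_idx))``.
    """
    cfg = cfg or ModelConfig()
    split = split or SplitSpec(seed=seed)
    tr, va, te = split_dataset(ds.labels, split)
    model = build_model(cfg, seed=seed)
    use2d = cfg.use_2d
    result = train(model, _take(ds, tr, use2d), _take(ds, va, use2d),
                   epochs=epochs, seed=seed, lr=lr, batch_size=batch_size)
    report = evaluate(result.model, _take(ds, te, use2d))
    return result, report, (tr, va, te)


def fold_mean(per_fold_acc: Sequence[float]) -> float:
    """Cross-validated accuracy: the arithmetic mean of fold accuracies."""
    return float(np.mean(np.asarray(per_fold_acc, dtype=float)))


def cross_validate(ds: FeaturizedDataset, n_folds: int = 10,
                   cfg: ModelConfig | None = None, epochs: int = 30,
                   seed: int = 0, lr: float = 1e-3, batch_size: int = 32):
    """Rotating k-fold protocol: fold i tests, fold i+1 validates, rest train.

    A fresh seeded model is built per fold.  Returns an EvalReport whose
    ``per_fold_acc`` holds each fold's test accuracy and whose scalar
    metrics are computed over the pooled fold predictions.
    """
    if n_folds < 3:
        raise ValueError("n_folds must be >= 3 (test, val and train parts)")
    cfg = cfg or ModelConfig()
    labels = ds.labels
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} windows < {n_folds} folds")
        rng.shuffle(idx)
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].append(chunk)
    folds = [np.sort(np.concatenate(f)) for f in folds]
    use2d = cfg.use_2d
    accs, pooled_true, pooled_pred = [], [], []
    for i in range(n_folds):
        test_idx = folds[i]
        val_idx = folds[(i + 1) % n_folds]
        train_idx = np.concatenate(
            [folds[j] for j in range(n_folds) if j not in (i, (i + 1) % n_folds)])
        model = build_model(cfg, seed=seed + i)
        train(model, _take(ds, train_idx, use2d), _take(ds, val_idx, use2d),
              epochs=epochs, seed=seed + i, lr=lr, batch_size=batch_size)
        preds, _ = _predict(model, ds.features[test_idx],
                            ds.spectrograms[test_idx][:, None] if use2d else None)
        accs.append(float((preds == labels[test_idx]).mean()))
        pooled_true.append(labels[test_idx])
        pooled_pred.append(preds)
    report = compute_metrics(np.concatenate(pooled_true),
                             np.concatenate(pooled_pred))
    report.per_fold_acc = accs
    return report


def indices_digest(idx: np.ndarray) -> str:
    """Stable hash of a split's membership, for protocol assertions."""
    return hashlib.sha256(np.sort(np.asarray(idx, dtype=np.int64))
                          .tobytes()).hexdigest()


def run_ablation_suite(ds: FeaturizedDataset, epochs: int = 30, seed: int = 0,
                       lr: float = 1e-3, batch_size: int = 32,
                       base_cfg: ModelConfig | None = None):
    """Train and evaluate all four variants on identical splits and seeds.

    Returns ``(reports, table, test_digest)``: a variant->EvalReport dict,
    a tidy metrics DataFrame, and the SHA-256 digest of the shared test
    membership.
    """
    base_cfg = base_cfg or ModelConfig()
    split = SplitSpec(seed=seed)
    tr, va, te = split_dataset(ds.labels, split)
    digest = indices_digest(te)
    reports = {}
    for variant in VARIANTS:
        cfg = ModelConfig(**{**base_cfg.__dict__, "variant": variant})
        model = build_model(cfg, seed=seed)
        use2d = cfg.use_2d
        train(model, _take(ds, tr, use2d), _take(ds, va, use2d),
              epochs=epochs, seed=seed, lr=lr, batch_size=batch_size)
        reports[variant] = evaluate(model, _take(ds, te, use2d))
    table = pd.DataFrame([
        {"variant": v, "accuracy": r.accuracy, "precision": r.precision,
         "recall": r.recall, "f1": r.f1}
        for v, r in reports.items()])
    return reports, table, digest


def export_embeddings(model: DualStreamModel, data) -> np.ndarray:
    """Fused pre-classifier vectors, one row per window, in input order."""
    feats, specs, _ = data
    _, fused = _predict(model, feats, specs)
    return fused
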