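"""Cross-validated evaluation: k-fold splits, ROC-AUC, F1, sensitivity runs.

Evaluation is always at the subject level — folds never split a subject's
samples across train and validation — and the study protocol is 10-fold
cross-validation with the held-out fold serving as the validation set
(no separate test partition).  Multi-class AUC is macro one-vs-rest,
multi-class F1 is macro; multi-label mode averages per-label scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .longio import LongitudinalCohort, PaddedBatch, pad_at_end, pad_in_sequence

__all__ = [
    "ConfusionCounts", "FoldMetrics", "kfold_split", "f1", "macro_f1",
    "roc_auc", "score_predictions", "cross_validate", "summarize_folds",
    "evaluate_last_timepoint", "sensitivity_over_history",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class FoldMetrics:
    fold: int
    auc: float
    f1: float
    n_eval: int

    def __post_init__(self):
        if np.isfinite(self.auc) and not (0.0 <= self.auc <= 1.0):
            raise ValueError("auc out of [0, 1]")
        if np.isfinite(self.f1) and not (0.0 <= self.f1 <= 1.0):
            raise ValueError("f1 out of [0, 1]")


def kfold_split(labels: np.ndarray | list, k: int = 10, seed: int = 0,
                stratified: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-level folds: disjoint, covering, sizes within one subject.

    ``labels`` is one entry per subject (tuples in multi-label mode are
    stratified on their joint pattern).  Stratification falls back to plain
    splitting with a warning when a class has fewer members than k.
    """
    labels = np.asarray([str(l) for l in labels])
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds number of subjects {n}")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            warnings.warn(
                f"smallest class has {counts.min()} subjects < k={k}; "
                "falling back to unstratified folds", stacklevel=2)
            stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(n), labels))
        for tr, _ in folds:
            if len(np.unique(labels[tr])) < len(np.unique(labels)):
                warnings.warn("a class is absent from some training fold",
                              stacklevel=2)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(n)))
    return [(tr, va) for tr, va in folds]


def f1(counts: ConfusionCounts) -> float:
    """tp / (tp + (fp + fn)/2); defined as 0 (with a warning) when no
    positive decisions or labels exist."""
    denom = counts.tp + 0.5 * (counts.fp + counts.fn)
    if denom == 0:
        warnings.warn("F1 undefined (tp+fp+fn == 0); returning 0", stacklevel=2)
        return 0.0
    return counts.tp / denom


def macro_f1(y_true: np.ndarray, y_pred: np.ndarray,
             classes: np.ndarray | None = None) -> float:
    """Unweighted mean of per-class one-vs-rest F1 scores."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    scores = []
    for c in classes:
        t, p = y_true == c, y_pred == c
        counts = ConfusionCounts(
            tp=int((t & p).sum()), fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(f1(counts))
    return float(np.mean(scores))


def roc_auc(scores: np.ndarray, labels: np.ndarray, mode: str = "binary") -> float:
    """Rank-based AUC (ties counted half).

    binary: ``scores`` is (n,) positive-class scores, labels 0/1.
    macro_ovr: ``scores`` is (n, C) probabilities, labels class indices;
    unweighted mean of one-vs-rest AUCs (classes absent from ``labels`` are
    skipped with a warning).
    per_label_mean: ``scores`` is (n, L), labels (n, L) binary; mean of
    per-label AUCs.  Degenerate single-class inputs yield NaN, not 0.5.
    """
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    if mode == "binary":
        if len(np.unique(labels)) < 2:
            warnings.warn("single-class labels: AUC undefined", stacklevel=2)
            return float("nan")
        return float(roc_auc_score(labels.astype(int), scores))
    if mode == "macro_ovr":
        aucs = []
        for c in range(scores.shape[1]):
            mask = labels == c
            if mask.all() or not mask.any():
                warnings.warn(f"class {c} absent or exhaustive; skipped",
                              stacklevel=2)
                continue
            aucs.append(roc_auc_score(mask.astype(int), scores[:, c]))
        return float(np.mean(aucs)) if aucs else float("nan")
    if mode == "per_label_mean":
        aucs = []
        for j in range(scores.shape[1]):
            col = labels[:, j]
            if len(np.unique(col)) < 2:
                warnings.warn(f"label {j} single-class; skipped", stacklevel=2)
                continue
            aucs.append(roc_auc_score(col.astype(int), scores[:, j]))
        return float(np.mean(aucs)) if aucs else float("nan")
    raise ValueError(f"unknown mode {mode!r}")


def score_predictions(probs: np.ndarray, labels: np.ndarray,
                      classes: np.ndarray, multi_label: bool,
                      fold: int = 0) -> FoldMetrics:
    """Fold metrics from predicted probabilities.

    Exclusive-class mode: macro one-vs-rest AUC + macro F1 of the argmax.
    Multi-label mode: mean per-label AUC + mean per-label F1 at 0.5.
    """
    probs = np.asarray(probs)
    if multi_label:
        y = np.asarray([list(l) for l in labels], dtype=int)
        auc = roc_auc(probs, y, mode="per_label_mean")
        f1s = []
        for j in range(y.shape[1]):
            pred = (probs[:, j] >= 0.5).astype(int)
            t = y[:, j].astype(bool)
            p = pred.astype(bool)
            counts = ConfusionCounts(int((t & p).sum()), int((~t & p).sum()),
                                     int((t & ~p).sum()), int((~t & ~p).sum()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f1s.append(f1(counts))
        return FoldMetrics(fold, auc, float(np.mean(f1s)), len(labels))
    idx = np.asarray([np.where(classes == l)[0][0] for l in labels])
    if probs.shape[1] == 2:
        auc = roc_auc(probs[:, 1], (idx == 1).astype(int), mode="binary")
    else:
        auc = roc_auc(probs, idx, mode="macro_ovr")
    preds = probs.argmax(axis=1)
    return FoldMetrics(fold, auc, macro_f1(idx, preds,
                                           classes=np.arange(len(classes))),
                       len(labels))


def summarize_folds(folds: list[FoldMetrics]) -> dict[str, float]:
    aucs = np.asarray([m.auc for m in folds], dtype=float)
    f1s = np.asarray([m.f1 for m in folds], dtype=float)
    return {
        "auc_mean": float(np.nanmean(aucs)),
        "auc_sd": float(np.nanstd(aucs, ddof=1)) if len(folds) > 1 else 0.0,
        "f1_mean": float(np.nanmean(f1s)),
        "f1_sd": float(np.nanstd(f1s, ddof=1)) if len(folds) > 1 else 0.0,
        "n_folds": len(folds),
    }


def cross_validate(model_factory, cohort: LongitudinalCohort,
                   strategy: str = "pad_in_sequence", k: int = 10,
                   seed: int = 0, train_config=None, scheme: str = "none",
                   pca_components: int | None = None,
                   stratified: bool = True,
                   multi_label: bool = False) -> tuple[list[FoldMetrics], dict]:
    """Train/evaluate ``model_factory`` across k subject-level folds.

    ``model_factory(n_features, n_outputs, fold_seed)`` builds a fresh model
    per fold.  PCA, when requested, is fit on the training fold's observed
    rows only and applied to both sides (no leakage).  Returns per-fold
    metrics plus the mean/sd summary.
    """
    from .distill import TrainConfig, encode_targets, train
    from .longio import apply_pca, fit_pca

    train_config = train_config or TrainConfig()
    padder = pad_in_sequence if strategy == "pad_in_sequence" else pad_at_end
    batch = padder(cohort)
    _, classes = encode_targets(batch.labels, multi_label)
    n_outputs = len(classes)
    use_mask = (train_config.use_mask if train_config.use_mask is not None
                else batch.strategy_tag == "pad_at_end")

    folds = kfold_split(cohort.labels, k=k, seed=seed, stratified=stratified)
    metrics = []
    for fi, (tr, va) in enumerate(folds):
        tr_batch, va_batch = batch.subset(tr), batch.subset(va)
        if pca_components is not None:
            obs_rows = tr_batch.values[tr_batch.mask.astype(bool)]
            mapping = fit_pca(obs_rows, n_components=pca_components)
            tr_batch = apply_pca(mapping, tr_batch)
            va_batch = apply_pca(mapping, va_batch)
        model = model_factory(tr_batch.n_features, n_outputs, seed + 1000 * fi)
        train(model, tr_batch, scheme=scheme, config=train_config,
              classes=None if multi_label else classes)
        probs = model.predict_proba(va_batch.values, va_batch.mask,
                                    use_mask=use_mask)
        metrics.append(score_predictions(probs, va_batch.labels, classes,
                                         multi_label, fold=fi))
    return metrics, summarize_folds(metrics)


def evaluate_last_timepoint(model, batch: PaddedBatch, classes: np.ndarray,
                            protocol: str = "last_available",
                            multi_label: bool = False) -> FoldMetrics:
    """Score subjects at their final time point under one of two protocols.

    ``padded_last_slot`` keeps only subjects observed at the final canonical
    slot and reads the prediction there (no masking); ``last_available``
    keeps everyone and predicts from each subject's last observed slot.
    """
    if protocol == "padded_last_slot":
        keep = np.where(batch.mask[:, -1] == 1)[0]
        if len(keep) == 0:
            raise ValueError("no subject observed at the final canonical slot")
        sub = batch.subset(keep)
        probs = model.predict_proba(sub.values, sub.mask, use_mask=False)
        labels = sub.labels
    elif protocol == "last_available":
        probs = model.predict_proba(batch.values, batch.mask, use_mask=True)
        labels = batch.labels
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return score_predictions(probs, labels, classes, multi_label)


def sensitivity_over_history(model_factory, cohort: LongitudinalCohort,
                             horizons: list[int], strategy: str = "pad_in_sequence",
                             k: int = 10, seed: int = 0, train_config=None,
                             scheme: str = "none", multi_label: bool = False):
    """Truncate each subject to its first h observed time points for each
    horizon h, re-pad, run full CV; returns one summary row per horizon."""
    max_len = max(len(s) for s in cohort.sequences)
    rows = []
    for h in horizons:
        if h < 1:
            raise ValueError("horizon must be >= 1")
        if h > max_len:
            raise ValueError(f"horizon {h} exceeds max sequence length {max_len}")
        truncated = cohort.truncated(h)
        _, summary = cross_validate(model_factory, truncated, strategy=strategy,
                                    k=k, seed=seed, train_config=train_config,
                                    scheme=scheme, multi_label=multi_label)
        rows.append({"horizon": h, **summary})
    return rows
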