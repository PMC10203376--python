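"""Self-knowledge distillation: loss functions, schedules, and the trainer.

Two schemes regularize the sequence classifiers:

``fd`` (branch distillation)
    Shallow auxiliary classifiers branch off intermediate layers.  Each
    branch is trained with (i) hard-label cross-entropy, (ii) a KL
    divergence pulling its predictive distribution toward the
    gradient-detached main classifier, and (iii) an L2 penalty matching its
    penultimate-layer weights to the main head's.  Only the main classifier
    is used at inference.

``sd`` (progressive self-distillation)
    The model's own previous-epoch predictions act as soft targets:

        loss_t = (1 - alpha_t) * CE(y, p_t) + alpha_t * CE(p_{t-1}, p_t),
        alpha_t = alpha_T * t / T,

    so the self-teacher's influence ramps up linearly as it becomes
    trustworthy.  Teacher predictions are cached per sample at each epoch
    boundary and detached from gradient flow.

Probabilities inside every loss are clamped to [eps, 1-eps] with
eps = 1e-7; a perfectly confident correct prediction therefore incurs a
loss of at most ~1.2e-7 rather than exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .longio import PaddedBatch
from .nets import SequenceClassifier
from .optim import Adam

__all__ = [
    "EPS", "LossInputs", "DistillSchedule", "TeacherCache", "TrainConfig",
    "TrainResult", "cross_entropy", "binary_cross_entropy", "kl_divergence",
    "feature_l2", "first_distillation_loss", "alpha_at", "psk_loss",
    "encode_targets", "train", "train_autoencoder",
]

EPS = 1e-7


@dataclass
class LossInputs:
    """Ground truth + predictions for a loss evaluation."""

    y: np.ndarray          # (m, C) one-hot / binary indicator rows
    y_hat: Tensor          # (m, C) predicted probabilities
    @property
    def m(self) -> int:
        return self.y.shape[0]


def _clamp(p: Tensor) -> Tensor:
    return p.clip(EPS, 1.0 - EPS)


def cross_entropy(y: np.ndarray | Tensor, y_hat: Tensor) -> Tensor:
    """-(1/m) sum_i sum_c y_ic log(p_ic); y may be one-hot or soft targets."""
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    if y_arr.shape[0] == 0:
        raise ValueError("cross entropy over zero samples")
    yt = ad.Tensor(y_arr)  # targets never receive gradients
    return -((yt * _clamp(y_hat).log()).sum()) / y_arr.shape[0]


def binary_cross_entropy(y: np.ndarray, y_hat: Tensor) -> Tensor:
    """Per-label Bernoulli cross-entropy, used in multi-label (allergy) mode."""
    y_arr = np.asarray(y, dtype=np.float64)
    if y_arr.shape[0] == 0:
        raise ValueError("cross entropy over zero samples")
    p = _clamp(y_hat)
    yt = ad.Tensor(y_arr)
    ll = yt * p.log() + (1.0 - yt) * (1.0 - p).log()
    return -(ll.sum()) / y_arr.shape[0]


def kl_divergence(p: Tensor | np.ndarray, q: Tensor | np.ndarray) -> Tensor:
    """Mean over samples of sum_c p_c log(p_c / q_c), both rows clamped and
    renormalized.  Non-negative by Gibbs' inequality; callers detach the
    teacher distribution."""
    pt = p if isinstance(p, Tensor) else ad.Tensor(np.asarray(p, dtype=np.float64))
    qt = q if isinstance(q, Tensor) else ad.Tensor(np.asarray(q, dtype=np.float64))
    if pt.shape != qt.shape:
        raise ValueError(f"shape mismatch {pt.shape} vs {qt.shape}")
    pc = _clamp(pt)
    qc = _clamp(qt)
    pc = pc / pc.sum(axis=-1, keepdims=True)
    qc = qc / qc.sum(axis=-1, keepdims=True)
    m = pt.shape[0] if pt.ndim > 1 else 1
    return ((pc * (pc.log() - qc.log())).sum()) / m


def feature_l2(w_main: Tensor | np.ndarray, w_shallow: Tensor | np.ndarray) -> Tensor:
    """Mean squared elementwise difference between penultimate weight matrices."""
    wm = w_main if isinstance(w_main, Tensor) else ad.Tensor(w_main)
    ws = w_shallow if isinstance(w_shallow, Tensor) else ad.Tensor(w_shallow)
    if wm.shape != ws.shape:
        raise ValueError(
            f"penultimate weight shapes differ: {wm.shape} vs {ws.shape}")
    d = wm - ws
    return (d * d).sum() / d.data.size


def first_distillation_loss(main_probs: Tensor, branch_probs: list[Tensor],
                            y: np.ndarray, w_main: Tensor,
                            w_branches: list[Tensor],
                            weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                            multi_label: bool = False,
                            ) -> tuple[Tensor, dict[str, float]]:
    """Main hard-label loss plus the three per-branch auxiliary terms.

    Branch terms are summed across branches.  The KL teacher (the main
    classifier's distribution) is gradient-detached so distillation shapes
    only the branches, not the teacher.
    """
    if len(branch_probs) != len(w_branches):
        raise ValueError("one penultimate weight tensor per branch required")
    w_ce, w_kl, w_feat = weights
    ce_fn = binary_cross_entropy if multi_label else cross_entropy
    total = ce_fn(y, main_probs)
    report = {"main_ce": total.item()}
    main_detached = main_probs.detach()
    for bi, (bp, wb) in enumerate(zip(branch_probs, w_branches)):
        ce_b = ce_fn(y, bp)
        kl_b = kl_divergence(bp, main_detached)
        l2_b = feature_l2(w_main.detach(), wb)
        total = total + w_ce * ce_b + w_kl * kl_b + w_feat * l2_b
        report[f"branch{bi}_ce"] = ce_b.item()
        report[f"branch{bi}_kl"] = kl_b.item()
        report[f"branch{bi}_feat_l2"] = l2_b.item()
    return total, report


@dataclass
class DistillSchedule:
    """Linear soft-target ramp alpha_t = alpha_T * t / T."""

    alpha_T: float = 0.8
    total_epochs: int = 100

    def __post_init__(self):
        if not (0.0 <= self.alpha_T <= 1.0):
            raise ValueError("alpha_T must be in [0, 1]")


def alpha_at(schedule: DistillSchedule, t: int) -> float:
    if not (0 <= t <= schedule.total_epochs):
        raise ValueError(f"epoch {t} outside [0, {schedule.total_epochs}]")
    return schedule.alpha_T * t / schedule.total_epochs


class TeacherCache:
    """Per-sample previous-epoch predictions, detached from gradients."""

    def __init__(self):
        self._probs: dict[int, np.ndarray] = {}
        self.epoch: int = -1

    def update(self, indices: np.ndarray, probs: np.ndarray, epoch: int) -> None:
        for i, p in zip(np.asarray(indices).tolist(), np.asarray(probs)):
            self._probs[int(i)] = p.copy()
        self.epoch = epoch

    def get(self, indices: np.ndarray) -> np.ndarray:
        out = []
        for i in np.asarray(indices).tolist():
            if int(i) not in self._probs:
                raise KeyError(f"teacher cache missing sample index {i}")
            out.append(self._probs[int(i)])
        return np.asarray(out)


def psk_loss(y: np.ndarray, y_hat: Tensor, teacher_probs: np.ndarray,
             alpha_t: float, multi_label: bool = False) -> Tensor:
    """(1-alpha) * CE(hard) + alpha * CE(soft previous-epoch targets)."""
    ce_fn = binary_cross_entropy if multi_label else cross_entropy
    hard = ce_fn(y, y_hat)
    soft = ce_fn(np.asarray(teacher_probs, dtype=np.float64), y_hat)
    return (1.0 - alpha_t) * hard + alpha_t * soft


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Trainer knobs; batch size and epoch count follow the study protocol
    (64 / 100), everything else is a package default."""

    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    alpha_T: float = 0.8
    branch_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_balanced: bool = False
    validation_fraction: float = 0.0
    use_mask: bool | None = None   # None = infer from padding strategy


@dataclass
class TrainResult:
    trace: list[dict]                     # per-epoch records
    best_state: dict[str, np.ndarray]
    final_state: dict[str, np.ndarray]
    best_epoch: int

    def losses(self, split: str = "train") -> np.ndarray:
        return np.asarray([r["loss"] for r in self.trace if r["split"] == split])

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as f:
            w = csv.DictWriter(f, fieldnames=["epoch", "split", "term", "value"])
            w.writeheader()
            for r in self.trace:
                for term, value in r.items():
                    if term in ("epoch", "split"):
                        continue
                    w.writerow({"epoch": r["epoch"], "split": r["split"],
                                "term": term, "value": value})


def encode_targets(labels: np.ndarray, multi_label: bool,
                   classes: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Labels -> (m, C) target rows: one-hot for exclusive classes, the
    binary indicator matrix itself in multi-label mode."""
    labels = np.asarray(labels)
    if multi_label:
        return labels.astype(np.float64), np.arange(labels.shape[1])
    if classes is None:
        classes = np.unique(labels)
    index = {c: i for i, c in enumerate(classes)}
    y = np.zeros((len(labels), len(classes)))
    for r, lab in enumerate(labels):
        y[r, index[lab]] = 1.0
    return y, classes


def _infer_use_mask(batch: PaddedBatch) -> bool:
    # pad-at-end is the pad-and-mask arm; pad-in-sequence trains on the raw
    # zero-filled sequence without loss-level masking
    return batch.strategy_tag == "pad_at_end"


def train(model: SequenceClassifier, batch: PaddedBatch,
          scheme: str = "none", config: TrainConfig | None = None,
          val_batch: PaddedBatch | None = None,
          layer_lrs: list[float] | None = None,
          unfreeze: bool = False,
          classes: np.ndarray | None = None) -> TrainResult:
    """Mini-batch gradient descent under the selected distillation scheme.

    scheme: "none" (hard labels only), "fd" (branch distillation; the model
    must have branches) or "sd" (progressive self-distillation).  ``layer_lrs``
    + ``unfreeze`` switch on the fine-tuning regime used by transfer: per-block
    discriminative learning rates and gradual unfreezing from the last block.
    Returns the loss trace plus final and best-validation parameter states.
    """
    if scheme not in ("none", "fd", "sd"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "fd" and not model.branches:
        raise ValueError("fd scheme requires a model with branch classifiers")
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    multi = model.multi_label
    use_mask = config.use_mask if config.use_mask is not None else _infer_use_mask(batch)

    y_all, classes = encode_targets(batch.labels, multi, classes=classes)
    if y_all.shape[1] != model.n_outputs:
        raise ValueError(f"model has {model.n_outputs} outputs but targets "
                         f"have {y_all.shape[1]} columns")

    n = batch.n_subjects
    if val_batch is None and config.validation_fraction > 0:
        n_val = max(1, int(round(config.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        val_batch = batch.subset(val_idx)
        batch = batch.subset(tr_idx)
        y_all = y_all[tr_idx]
        n = batch.n_subjects
    y_val = None
    if val_batch is not None:
        y_val, _ = encode_targets(val_batch.labels, multi, classes=None if multi else classes)

    sample_weights = None
    if config.class_balanced and not multi:
        freq = y_all.sum(axis=0)
        freq[freq == 0] = 1.0
        inv = y_all @ (1.0 / freq)
        sample_weights = inv / inv.mean()

    params = model.parameters()
    if layer_lrs is not None:
        blocks = model.layer_blocks()
        if len(layer_lrs) != len(blocks):
            raise ValueError("one learning rate per layer block required")
        opt = Adam([(b, lr) for b, lr in zip(blocks, layer_lrs)])
    else:
        opt = Adam.single_group(params, config.lr)

    schedule = DistillSchedule(config.alpha_T, config.epochs)
    cache = TeacherCache()
    if scheme == "sd":
        probs0 = model.predict_proba(batch.values, batch.mask, use_mask=use_mask)
        cache.update(np.arange(n), probs0, epoch=0)

    ce_fn = binary_cross_entropy if multi else cross_entropy
    trace: list[dict] = []
    best_state, best_loss, best_epoch = model.state_dict(), np.inf, 0

    for epoch in range(1, config.epochs + 1):
        if unfreeze and layer_lrs is not None:
            from .transfer import unfreeze_schedule
            open_blocks = unfreeze_schedule(len(opt.param_groups), epoch)
            opt.set_frozen(set(range(len(opt.param_groups))) - open_blocks)
        alpha_t = alpha_at(schedule, epoch) if scheme == "sd" else 0.0

        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        term_sums: dict[str, float] = {}
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            vb, mb, yb = batch.values[idx], batch.mask[idx], y_all[idx]
            out = model.forward(vb, mb, use_mask=use_mask,
                                with_branches=(scheme == "fd"))
            if scheme == "fd":
                loss, terms = first_distillation_loss(
                    out.probs, out.branch_probs, yb,
                    model.head.penultimate_weights,
                    [br.penultimate_weights for br in model.branches],
                    weights=config.branch_weights, multi_label=multi)
                for k, v in terms.items():
                    term_sums[k] = term_sums.get(k, 0.0) + v
            elif scheme == "sd":
                loss = psk_loss(yb, out.probs, cache.get(idx), alpha_t,
                                multi_label=multi)
            else:
                if sample_weights is not None:
                    w = sample_weights[idx][:, None]
                    p = out.probs.clip(EPS, 1 - EPS)
                    loss = -((ad.Tensor(yb * w) * p.log()).sum()) / len(idx)
                else:
                    loss = ce_fn(yb, out.probs)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        record = {"epoch": epoch, "split": "train",
                  "loss": epoch_loss / n_batches, "alpha": alpha_t}
        for k, v in term_sums.items():
            record[k] = v / n_batches
        trace.append(record)

        if scheme == "sd":
            probs = model.predict_proba(batch.values, batch.mask, use_mask=use_mask)
            cache.update(np.arange(n), probs, epoch=epoch)

        if val_batch is not None:
            with ad.no_grad():
                vp = model.forward(val_batch.values, val_batch.mask,
                                   use_mask=use_mask).probs
                vloss = ce_fn(y_val, vp).item()
            trace.append({"epoch": epoch, "split": "val", "loss": vloss,
                          "alpha": alpha_t})
            if vloss < best_loss:
                best_loss, best_state, best_epoch = vloss, model.state_dict(), epoch
        else:
            if record["loss"] < best_loss:
                best_loss, best_state, best_epoch = record["loss"], model.state_dict(), epoch

    return TrainResult(trace=trace, best_state=best_state,
                       final_state=model.state_dict(), best_epoch=best_epoch)


def train_autoencoder(autoencoder, x: np.ndarray, ae_config=None,
                      epochs: int = 50, batch_size: int = 64, lr: float = 1e-3,
                      seed: int = 0) -> list[float]:
    """Fit the sparse autoencoder on observed abundance rows.

    Minimizes reconstruction MSE + L2 weight penalty + Bernoulli-KL sparsity
    (see ``nets.autoencoder_loss``); returns the per-epoch loss trace.
    """
    from .nets import AutoencoderConfig, autoencoder_loss

    ae_config = ae_config or AutoencoderConfig()
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = Adam.single_group(autoencoder.parameters(), lr)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(len(x))
        total, nb = 0.0, 0
        for start in range(0, len(x), batch_size):
            xb = x[order[start:start + batch_size]]
            x_hat, latent = autoencoder(ad.Tensor(xb))
            loss = autoencoder_loss(ae_config, xb, x_hat,
                                    autoencoder.weight_tensors(), latent)
            if not np.isfinite(loss.item()):
                raise FloatingPointError("non-finite autoencoder loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item()
            nb += 1
        losses.append(total / nb)
    return losses
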