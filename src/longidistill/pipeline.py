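"""Experiment driver: configuration, end-to-end runs, and the model grid.

``run_experiment`` ties the pipeline together — load or generate a cohort,
pad, optionally PCA-reduce, train under the chosen distillation scheme,
cross-validate — and writes a reproducible results directory: per-fold CSV,
summary JSON, the verbatim config, and a log file.  The sparse-autoencoder
LSTM (``ulstm``) baseline runs the two-stage variant: an unsupervised
encoder fit on the training fold's observed rows, then an LSTM classifier
over the frozen latent codes.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .distill import TrainConfig, encode_targets, train, train_autoencoder
from .evalkit import (cross_validate, kfold_split, score_predictions,
                      summarize_folds)
from .longio import (LongitudinalCohort, apply_pca, assemble_cohort, fit_pca,
                     load_abundance_table, load_metadata, pad_at_end,
                     pad_in_sequence)
from .nets import SequenceClassifier, SparseAutoencoder
from .synthgen import SynthConfig, generate_cohort

logger = logging.getLogger("longidistill")

__all__ = ["RunConfig", "run_experiment", "run_ulstm_baseline", "run_grid",
           "load_config", "ulstm_cross_validate"]

MODELS = ("lstm", "cnnlstm", "rnn", "ulstm")
SCHEMES = ("none", "fd", "sd")
STRATEGIES = ("pad_in_sequence", "pad_at_end")


@dataclass
class RunConfig:
    """Full description of one experiment cell."""

    # data: either file paths or a synthetic config
    abundance_path: str | None = None
    metadata_path: str | None = None
    canonical_grid: list[int] | None = None
    synth: dict | None = None

    strategy: str = "pad_in_sequence"
    pca: bool = False
    pca_components: int = 300
    model: str = "cnnlstm"
    distillation: str = "none"
    multi_label: bool = False

    hidden: int = 128
    head_hidden: int = 64
    conv_channels: tuple[int, ...] = (32, 32)
    kernel_size: int = 5
    stride: int = 2
    state_squash: str = "tanh"

    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-3
    alpha_T: float = 0.8
    branch_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)

    ae_latent: int = 32
    ae_lam: float = 1e-4
    ae_beta: float = 0.1
    ae_p: float = 0.05
    ae_epochs: int = 50

    cv_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.distillation not in SCHEMES:
            raise ValueError(f"distillation must be one of {SCHEMES}")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.model == "ulstm" and self.distillation != "none":
            raise ValueError("ulstm baseline does not support distillation branches")
        if self.model == "rnn" and self.distillation == "fd":
            # the branch set is defined on the LSTM-family body
            raise ValueError("fd branches are defined for lstm/cnnlstm models")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = RunConfig(**raw)
    return cfg


def _resolve_cohort(config: RunConfig) -> LongitudinalCohort:
    if config.synth is not None:
        synth = SynthConfig(**{**config.synth, "seed": config.synth.get("seed", config.seed)})
        cohort, _ = generate_cohort(synth)
        return cohort
    if not config.abundance_path or not config.metadata_path:
        raise ValueError("either synth config or abundance+metadata paths required")
    table = load_abundance_table(config.abundance_path)
    meta = load_metadata(config.metadata_path)
    grid = config.canonical_grid or sorted(set(meta.sample_to_time.values()))
    return assemble_cohort(table, meta, grid)


def _model_factory(config: RunConfig):
    n_branches = 0
    if config.distillation == "fd":
        n_branches = 2 if config.model == "cnnlstm" else 1

    def factory(n_features: int, n_outputs: int, seed: int) -> SequenceClassifier:
        return SequenceClassifier(
            n_features, n_outputs, arch=config.model, hidden=config.hidden,
            head_hidden=config.head_hidden, conv_channels=config.conv_channels,
            kernel_size=config.kernel_size, stride=config.stride,
            multi_label=config.multi_label, state_squash=config.state_squash,
            n_branches=n_branches, seed=seed)

    return factory


def _train_config(config: RunConfig) -> TrainConfig:
    return TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                       lr=config.lr, seed=config.seed, alpha_T=config.alpha_T,
                       branch_weights=config.branch_weights)


def ulstm_cross_validate(config: RunConfig, cohort: LongitudinalCohort):
    """Two-stage CV: per-fold sparse autoencoder -> frozen codes -> LSTM."""
    from .nets import AutoencoderConfig

    padder = pad_in_sequence if config.strategy == "pad_in_sequence" else pad_at_end
    batch = padder(cohort)
    _, classes = encode_targets(batch.labels, config.multi_label)
    use_mask = batch.strategy_tag == "pad_at_end"
    folds = kfold_split(cohort.labels, k=config.cv_folds, seed=config.seed,
                        stratified=config.stratified)
    ae_cfg = AutoencoderConfig(lam=config.ae_lam, beta=config.ae_beta, p=config.ae_p)
    metrics = []
    for fi, (tr, va) in enumerate(folds):
        tr_b, va_b = batch.subset(tr), batch.subset(va)
        ae = SparseAutoencoder(batch.n_features, config.ae_latent,
                               seed=config.seed + 1000 * fi)
        obs_rows = tr_b.values[tr_b.mask.astype(bool)]
        train_autoencoder(ae, obs_rows, ae_cfg, epochs=config.ae_epochs,
                          batch_size=config.batch_size, lr=config.lr,
                          seed=config.seed + fi)

        def encode_batch(b):
            from . import autodiff as ad
            out = np.zeros((b.n_subjects, b.n_slots, config.ae_latent))
            obs = b.mask.astype(bool)
            if obs.any():
                with ad.no_grad():
                    out[obs] = ae.encode(ad.Tensor(b.values[obs])).data
            from .longio import PaddedBatch
            return PaddedBatch(out, b.mask.copy(), b.labels, b.strategy_tag,
                               list(b.canonical_grid), list(b.subject_ids))

        tr_e, va_e = encode_batch(tr_b), encode_batch(va_b)
        model = SequenceClassifier(config.ae_latent, len(classes), arch="lstm",
                                   hidden=config.hidden,
                                   head_hidden=config.head_hidden,
                                   multi_label=config.multi_label,
                                   seed=config.seed + 1000 * fi)
        train(model, tr_e, scheme="none", config=_train_config(config),
              classes=None if config.multi_label else classes)
        probs = model.predict_proba(va_e.values, va_e.mask, use_mask=use_mask)
        metrics.append(score_predictions(probs, va_e.labels, classes,
                                         config.multi_label, fold=fi))
    return metrics, summarize_folds(metrics)


def _write_results(out_dir: Path, config: RunConfig, metrics, summary) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as f:
        # json round-trip turns tuples into YAML-safe lists
        yaml.safe_dump(json.loads(json.dumps(asdict(config))), f)
    with open(out_dir / "folds.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["fold", "auc", "f1", "n_eval"])
        for m in metrics:
            w.writerow([m.fold, m.auc, m.f1, m.n_eval])
    with open(out_dir / "summary.json", "w") as f:
        json.dump({**summary, "seed": config.seed, "model": config.model,
                   "strategy": config.strategy, "distillation": config.distillation,
                   "pca": config.pca}, f, indent=2)
    return out_dir


def run_experiment(config: RunConfig, out_dir: str | Path) -> dict:
    """Generate/load -> preprocess -> train (chosen scheme) -> evaluate.

    Writes folds.csv, summary.json, config.yaml and run.log into ``out_dir``
    and returns the summary dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        logger.info("stage=data model=%s strategy=%s scheme=%s seed=%d",
                    config.model, config.strategy, config.distillation, config.seed)
        cohort = _resolve_cohort(config)
        logger.info("cohort: %d subjects, %d features, grid %s",
                    cohort.n_subjects, cohort.n_features, cohort.canonical_grid)
        if config.model == "ulstm":
            metrics, summary = ulstm_cross_validate(config, cohort)
        else:
            metrics, summary = cross_validate(
                _model_factory(config), cohort, strategy=config.strategy,
                k=config.cv_folds, seed=config.seed,
                train_config=_train_config(config),
                scheme=config.distillation,
                pca_components=config.pca_components if config.pca else None,
                stratified=config.stratified, multi_label=config.multi_label)
        logger.info("summary: %s", summary)
        _write_results(out_dir, config, metrics, summary)
        return summary
    except Exception:
        logger.exception("stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def run_ulstm_baseline(config: RunConfig, out_dir: str | Path) -> dict:
    """Explicit entry point for the autoencoder-LSTM baseline."""
    config.model = "ulstm"
    return run_experiment(config, out_dir)


def run_grid(base_config: RunConfig, out_root: str | Path,
             models=("lstm", "cnnlstm"), strategies=STRATEGIES,
             pca_options=(False, True)) -> dict[str, dict]:
    """Drive the model x padding x PCA grid; one results directory per cell."""
    out_root = Path(out_root)
    results = {}
    for model in models:
        for strategy in strategies:
            for pca in pca_options:
                cell = RunConfig(**{**asdict(base_config), "model": model,
                                    "strategy": strategy, "pca": pca})
                name = f"{model}_{strategy}_{'pca' if pca else 'nopca'}"
                results[name] = run_experiment(cell, out_root / name)
    return results
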