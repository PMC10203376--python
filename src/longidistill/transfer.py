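"""Cross-study transfer: taxonomy harmonization and fine-tuning schedules.

Two 16S studies rarely share an OTU space, but they do share names at a
coarse taxonomic rank.  Features are therefore aggregated to a common rank
(phylum by default — fine enough to carry signal, coarse enough to overlap),
the two studies' rank-level feature sets are intersected, and a model
trained on the source study is fine-tuned on the target with the standard
ULMFiT-style toolkit: discriminative per-layer learning rates, gradual
unfreezing from the last layer backwards, and concat pooling of the hidden
sequence (mean ++ max ++ last) as the classifier input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .longio import AbundanceTable

__all__ = [
    "TaxonomyMap",
    "HarmonizationReport",
    "load_taxonomy",
    "aggregate_to_rank",
    "harmonize",
    "discriminative_lrs",
    "unfreeze_schedule",
    "concat_pool",
    "transfer_fit",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

_GREENGENES_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


@dataclass
class TaxonomyMap:
    """feature_id -> ordered 6-rank lineage (kingdom .. genus)."""

    lineages: dict[str, tuple[str, ...]]

    def rank_name(self, feature_id: str, rank: str) -> str:
        try:
            lineage = self.lineages[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} missing from taxonomy map") from None
        return lineage[RANKS.index(rank)]

    def groups_at(self, feature_ids, rank: str) -> set[str]:
        return {self.rank_name(f, rank) for f in feature_ids}


def load_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV (feature_id, semicolon-delimited lineage).

    Greengenes-style rank prefixes (``p__Firmicutes``) are stripped.
    Comment lines starting with '#' are skipped.
    """
    lineages = {}
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("feature_id\t"):
                continue
            fid, lineage_str = line.split("\t", 1)
            parts = [p.strip() for p in lineage_str.split(";")]
            cleaned = []
            for p in parts:
                for pref in _GREENGENES_PREFIXES:
                    if p.startswith(pref):
                        p = p[len(pref):]
                        break
                cleaned.append(p)
            if len(cleaned) < len(RANKS):
                cleaned += [""] * (len(RANKS) - len(cleaned))
            lineages[fid] = tuple(cleaned[: len(RANKS)])
    return TaxonomyMap(lineages)


@dataclass
class HarmonizationReport:
    rank: str
    groups_a: set[str]
    groups_b: set[str]
    overlap: set[str]
    retained: list[str]  # sorted shared column order applied to both studies
    dropped_a: set[str]
    dropped_b: set[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(
                {
                    "rank": self.rank,
                    "groups_a": sorted(self.groups_a),
                    "groups_b": sorted(self.groups_b),
                    "overlap": sorted(self.overlap),
                    "retained": self.retained,
                    "dropped_a": sorted(self.dropped_a),
                    "dropped_b": sorted(self.dropped_b),
                },
                f,
                indent=2,
            )


def aggregate_to_rank(table: AbundanceTable, tax: TaxonomyMap, rank: str) -> AbundanceTable:
    """Sum member abundances within each rank-level group (row sums preserved)."""
    groups: dict[str, list[int]] = {}
    for j, fid in enumerate(table.feature_ids):
        name = tax.rank_name(fid, rank)  # raises on unmapped feature
        groups.setdefault(name, []).append(j)
    names = sorted(groups)
    values = np.zeros((table.n_samples, len(names)))
    for g, name in enumerate(names):
        values[:, g] = table.values[:, groups[name]].sum(axis=1)
    return AbundanceTable(list(table.sample_ids), names, values)


def harmonize(groups_a: set[str], groups_b: set[str], rank: str = "phylum") -> HarmonizationReport:
    """Intersect two studies' rank-level group names.

    The retained columns are the sorted intersection, giving a deterministic
    shared feature order for both studies; an empty intersection means no
    transfer is possible and raises.
    """
    groups_a, groups_b = set(groups_a), set(groups_b)
    if not groups_a or not groups_b:
        raise ValueError("group sets must be non-empty")
    overlap = groups_a & groups_b
    if not overlap:
        raise ValueError(f"no overlapping {rank}-level groups; transfer impossible")
    return HarmonizationReport(
        rank=rank,
        groups_a=groups_a,
        groups_b=groups_b,
        overlap=overlap,
        retained=sorted(overlap),
        dropped_a=groups_a - overlap,
        dropped_b=groups_b - overlap,
    )


def discriminative_lrs(base_lr: float, n_layers: int, decay: float = 2.6) -> list[float]:
    """Geometric per-layer learning rates, largest at the last layer."""
    if decay <= 1.0:
        raise ValueError("decay must be > 1")
    return [base_lr / decay ** (n_layers - 1 - k) for k in range(n_layers)]


def unfreeze_schedule(n_layers: int, epoch: int) -> set[int]:
    """Layer indices trainable at ``epoch`` (1-based): the last
    min(epoch, n_layers) layers."""
    if epoch < 1:
        raise ValueError("epoch must be >= 1")
    n_open = min(epoch, n_layers)
    return set(range(n_layers - n_open, n_layers))


def concat_pool(hidden: ad.Tensor, mask: np.ndarray) -> ad.Tensor:
    """[mean ++ max ++ last] over the observed steps of a hidden sequence.

    hidden: (B, T, H); mask: (B, T) with at least one observed step per row.
    Output: (B, 3H).
    """
    mask = np.asarray(mask, dtype=np.float64)
    if (mask.sum(axis=1) < 1).any():
        raise ValueError("every subject needs at least one observed step")
    m = ad.Tensor(mask[:, :, None])
    counts = ad.Tensor(mask.sum(axis=1, keepdims=True))
    mean = (hidden * m).sum(axis=1) / counts
    neg_inf = ad.Tensor((1.0 - mask[:, :, None]) * -1e30)
    mx = (hidden + neg_inf).max(axis=1)
    last_idx = mask.shape[1] - 1 - np.argmax(mask[:, ::-1], axis=1)
    last = hidden[np.arange(mask.shape[0]), last_idx]
    return ad.concatenate([mean, mx, last], axis=1)


@dataclass
class FineTuneConfig:
    """Knobs for target-study fine-tuning."""

    base_lr: float = 1e-3
    decay: float = 2.6
    epochs: int = 20
    batch_size: int = 64
    use_concat_pool: bool = True
    seed: int = 0
    validation_fraction: float = 0.0


def transfer_fit(source_checkpoint, target_batch, n_target_outputs: int,
                 config: FineTuneConfig | None = None, multi_label: bool = False):
    """Fine-tune a source-trained model on a harmonized target batch.

    Loads the body weights from the checkpoint, reinitializes the head for
    the target label dimension (switching to a concat-pool head by default),
    and trains under gradual unfreezing with discriminative learning rates.
    Returns (model, per-epoch loss trace).
    """
    from .distill import train, TrainConfig
    from .nets import load_model, rebuild_head

    config = config or FineTuneConfig()
    model = load_model(source_checkpoint)
    if model.n_features != target_batch.n_features:
        raise ValueError(
            f"feature dimension mismatch: source model expects "
            f"{model.n_features}, target batch has {target_batch.n_features} "
            "(harmonize both studies to the same rank first)"
        )
    rebuild_head(model, n_target_outputs, multi_label=multi_label,
                 use_concat_pool=config.use_concat_pool, seed=config.seed)

    blocks = model.layer_blocks()
    lrs = discriminative_lrs(config.base_lr, len(blocks), config.decay)
    tcfg = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                       lr=config.base_lr, seed=config.seed,
                       validation_fraction=config.validation_fraction)
    result = train(model, target_batch, scheme="none", config=tcfg,
                   layer_lrs=lrs, unfreeze=True)
    return model, result
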