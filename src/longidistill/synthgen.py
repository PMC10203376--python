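"""Synthetic longitudinal compositional cohorts with known class signal.

Every subject gets a baseline composition drawn from a Dirichlet, and the
outcome classes differ only through a log-linear temporal drift applied to a
designated subset of "signal" taxa: at grid position ``t`` (0-indexed) the
signal taxa of a subject in class ``c`` are multiplied by
``exp(effect_size * t * direction_c)`` before renormalization, where the
class directions are spread evenly over [-1, 1].  The drift therefore
accumulates over time — a model has to integrate the trajectory, not just
read a single time point, which is exactly the regime the recurrent
classifiers target.  Missingness is missing-at-random over non-initial time
points.  All randomness flows from a single seed, so generated tables are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .longio import AbundanceTable, SampleMetadata
from .transfer import TaxonomyMap

__all__ = ["SynthConfig", "generate", "generate_cohort", "make_paired_studies", "write_tsv_trio"]

_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


@dataclass
class SynthConfig:
    """Study-condition knobs for the generator.

    effect_size is the per-time-step log-abundance drift on signal taxa;
    missing_rate the per-(subject, non-initial timepoint) drop probability;
    concentration the symmetric Dirichlet base concentration for baseline
    compositions.
    """

    n_subjects: int = 200
    n_features: int = 100
    n_timepoints: int = 4
    n_classes: int = 2
    multi_label: bool = False
    n_labels: int = 3
    signal_taxa_fraction: float = 0.2
    effect_size: float = 0.5
    missing_rate: float = 0.2
    class_weights: tuple[float, ...] | None = None
    concentration: float = 0.8
    n_phyla: int = 12
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        n_signal = max(1, int(round(self.signal_taxa_fraction * self.n_features)))
        if n_signal > self.n_features:
            raise ValueError("signal taxa count exceeds n_features")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("class_weights must sum to 1")


def _random_taxonomy(rng: np.random.Generator, feature_ids: list[str],
                     n_phyla: int, phylum_names: list[str] | None = None) -> TaxonomyMap:
    """Consistent 6-rank lineages: a tree where each feature hangs off a
    genus that deterministically chains up to one of ``n_phyla`` phyla."""
    if phylum_names is None:
        phylum_names = [f"Phylum{p:02d}" for p in range(n_phyla)]
    lineages = {}
    for fid in feature_ids:
        p = int(rng.integers(n_phyla))
        phylum = phylum_names[p]
        lineages[fid] = (
            "Bacteria",
            phylum,
            f"{phylum}_c{int(rng.integers(2))}",
            f"{phylum}_o{int(rng.integers(3))}",
            f"{phylum}_f{int(rng.integers(4))}",
            f"g_{fid}",
        )
    return TaxonomyMap(lineages)


def generate(config: SynthConfig) -> tuple[AbundanceTable, SampleMetadata, TaxonomyMap]:
    """Draw a full synthetic study: abundance table, metadata, taxonomy."""
    rng = np.random.default_rng(config.seed)
    n_signal = max(1, int(round(config.signal_taxa_fraction * config.n_features)))
    signal_idx = rng.choice(config.n_features, size=n_signal, replace=False)

    if config.multi_label:
        n_out = config.n_labels
        # per-label signal sub-blocks and directions
        blocks = np.array_split(signal_idx, n_out)
        label_probs = np.full(n_out, 0.35)
    else:
        n_out = config.n_classes
        directions = (
            np.linspace(-1.0, 1.0, n_out) if n_out > 1 else np.array([0.0])
        )
        weights = (
            np.asarray(config.class_weights, dtype=float)
            if config.class_weights is not None
            else np.full(n_out, 1.0 / n_out)
        )

    feature_ids = [f"OTU{j:04d}" for j in range(config.n_features)]
    tax = _random_taxonomy(rng, feature_ids, config.n_phyla)

    sample_ids, rows = [], []
    sample_to_subject, sample_to_time, labels = {}, {}, {}
    for s in range(config.n_subjects):
        subj = f"S{s:04d}"
        base = rng.dirichlet(np.full(config.n_features, config.concentration))
        if config.multi_label:
            lab = tuple(int(rng.random() < p) for p in label_probs)
        else:
            cls = int(rng.choice(n_out, p=weights))
            lab = f"class{cls}"
        # first time point never dropped
        kept = [0] + [
            t for t in range(1, config.n_timepoints)
            if rng.random() >= config.missing_rate
        ]
        for t in kept:
            drift = np.zeros(config.n_features)
            if config.multi_label:
                for li, block in enumerate(blocks):
                    if lab[li]:
                        drift[block] = config.effect_size * t
            else:
                drift[signal_idx] = config.effect_size * t * directions[cls]
            comp = base * np.exp(drift)
            comp = comp / comp.sum()
            sid = f"{subj}_t{t:02d}"
            sample_ids.append(sid)
            rows.append(comp)
            sample_to_subject[sid] = subj
            sample_to_time[sid] = t
            labels[sid] = lab
    table = AbundanceTable(sample_ids, feature_ids, np.asarray(rows))
    meta = SampleMetadata(sample_to_subject, sample_to_time, labels)
    return table, meta, tax


def generate_cohort(config: SynthConfig):
    """Convenience: generate and assemble on the implied canonical grid."""
    from .longio import assemble_cohort

    table, meta, tax = generate(config)
    cohort = assemble_cohort(table, meta, list(range(config.n_timepoints)))
    return cohort, tax


def make_paired_studies(config_a: SynthConfig, config_b: SynthConfig,
                        shared_phyla: int):
    """Two studies whose taxonomies share exactly ``shared_phyla`` phylum names.

    Emulates the cross-study setting where feature spaces only align after
    aggregation to a common taxonomic rank.
    """
    if shared_phyla > min(config_a.n_phyla, config_b.n_phyla):
        raise ValueError("shared_phyla exceeds a study's phylum count")
    shared = [f"SharedPhylum{p:02d}" for p in range(shared_phyla)]
    own_a = [f"StudyA_Phylum{p:02d}" for p in range(config_a.n_phyla - shared_phyla)]
    own_b = [f"StudyB_Phylum{p:02d}" for p in range(config_b.n_phyla - shared_phyla)]

    out = []
    for cfg, names in ((config_a, shared + own_a), (config_b, shared + own_b)):
        rng = np.random.default_rng(cfg.seed)
        table, meta, _ = generate(cfg)
        # regenerate taxonomy over the study-specific phylum inventory,
        # guaranteeing every phylum name is actually used
        tax_rng = np.random.default_rng(cfg.seed + 1)
        lineages = {}
        n_feat = len(table.feature_ids)
        assignment = np.concatenate([
            np.arange(len(names)),
            tax_rng.integers(len(names), size=max(0, n_feat - len(names))),
        ])[:n_feat]
        tax_rng.shuffle(assignment)
        for fid, p in zip(table.feature_ids, assignment):
            phylum = names[int(p)]
            lineages[fid] = ("Bacteria", phylum, f"{phylum}_c0", f"{phylum}_o0",
                             f"{phylum}_f0", f"g_{fid}")
        out.append((table, meta, TaxonomyMap(lineages)))
    return out[0], out[1]


def write_tsv_trio(table: AbundanceTable, meta: SampleMetadata, tax: TaxonomyMap,
                   out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write the abundance/metadata/taxonomy TSV files longio consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header_note = f"# seed={seed}\n" if seed is not None else ""

    ab_path = out_dir / "abundance.tsv"
    with open(ab_path, "w") as f:
        f.write("sample_id\t" + "\t".join(table.feature_ids) + "\n")
        for sid, row in zip(table.sample_ids, table.values):
            f.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    md_path = out_dir / "metadata.tsv"
    first = next(iter(meta.labels.values()))
    multi = isinstance(first, tuple)
    with open(md_path, "w") as f:
        if multi:
            label_cols = [f"label{j}" for j in range(len(first))]
            f.write("sample_id\tsubject_id\ttime_point\t" + "\t".join(label_cols) + "\n")
            for sid in table.sample_ids:
                lab = meta.labels[sid]
                f.write(f"{sid}\t{meta.sample_to_subject[sid]}\t"
                        f"{meta.sample_to_time[sid]}\t"
                        + "\t".join(str(x) for x in lab) + "\n")
        else:
            f.write("sample_id\tsubject_id\ttime_point\tlabel\n")
            for sid in table.sample_ids:
                f.write(f"{sid}\t{meta.sample_to_subject[sid]}\t"
                        f"{meta.sample_to_time[sid]}\t{meta.labels[sid]}\n")

    tax_path = out_dir / "taxonomy.tsv"
    with open(tax_path, "w") as f:
        f.write(header_note)
        f.write("feature_id\tlineage\n")
        for fid, lineage in tax.lineages.items():
            f.write(fid + "\t" + ";".join(lineage) + "\n")
    return {"abundance": ab_path, "metadata": md_path, "taxonomy": tax_path}
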