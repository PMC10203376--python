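"""Longitudinal abundance I/O: tables, cohorts, padding, PCA reduction.

The data model mirrors how longitudinal 16S studies are distributed: a
sample-by-taxon relative-abundance matrix, a metadata table mapping each
sample to a subject, a time point on the study's canonical grid, and a
subject-level outcome.  Subjects rarely have samples at every scheduled
visit, so two padding strategies turn ragged per-subject sequences into a
dense rank-3 batch:

``pad_in_sequence``
    each observed sample sits at its canonical time slot; missing slots are
    zero-filled (temporal alignment preserved).
``pad_at_end``
    observed samples are compacted to the leading slots in time order and
    the suffix is zero-filled (a prefix observation mask).

Both carry an explicit binary observation mask so downstream recurrent
models can skip state updates at padded slots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "LongitudinalCohort",
    "PaddedBatch",
    "PCAMapping",
    "load_abundance_table",
    "load_metadata",
    "assemble_cohort",
    "pad_in_sequence",
    "pad_at_end",
    "fit_pca",
    "apply_pca",
    "save_batch",
    "load_batch",
]

ROW_SUM_TOL = 1e-3


@dataclass
class AbundanceTable:
    """Sample-by-taxon relative abundance matrix.

    Rows are samples, columns are OTUs/taxa, values are unitless fractions.
    Rows are expected to sum to 1; deviations beyond ``ROW_SUM_TOL`` trigger
    a warning rather than an error since published tables are pre-normalized
    and occasionally truncated.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n_samples, n_features)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample id in abundance table")
        if self.values.size and self.values.min() < 0:
            raise ValueError("relative abundances must be non-negative")
        if self.values.size:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > ROW_SUM_TOL
            if bad.any():
                i = int(np.argmax(bad))
                warnings.warn(
                    f"{bad.sum()} row(s) deviate from unit sum "
                    f"(e.g. sample {self.sample_ids[i]!r} sums to {sums[i]:.5g})",
                    stacklevel=2,
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


@dataclass
class SampleMetadata:
    """Per-sample records: subject, canonical time point, outcome label(s).

    ``labels`` is a mapping sample_id -> label; a label is a string in
    single-outcome (severity) mode or a tuple of 0/1 ints in multi-label
    (allergy) mode.  Outcomes are subject-level in both study designs, so
    conflicting labels within a subject are rejected at assembly.
    """

    sample_to_subject: dict[str, str]
    sample_to_time: dict[str, int]
    labels: dict[str, object]

    def __post_init__(self):
        pairs = {}
        for sid, subj in self.sample_to_subject.items():
            key = (subj, self.sample_to_time[sid])
            if key in pairs:
                raise ValueError(
                    f"duplicate (subject, time_point) {key}: samples "
                    f"{pairs[key]!r} and {sid!r}"
                )
            pairs[key] = sid


@dataclass
class LongitudinalCohort:
    """Per-subject ordered sequences of abundance vectors plus labels."""

    subject_ids: list[str]
    sequences: list[list[tuple[int, np.ndarray]]]  # per subject: [(time, vector)]
    labels: list[object]
    canonical_grid: list[int]
    n_features: int

    def __post_init__(self):
        for subj, seq in zip(self.subject_ids, self.sequences):
            times = [t for t, _ in seq]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"subject {subj!r}: time points not strictly increasing")
            if any(t not in self.canonical_grid for t in times):
                raise ValueError(f"subject {subj!r}: time point off canonical grid")
            if any(len(v) != self.n_features for _, v in seq):
                raise ValueError(f"subject {subj!r}: feature vector length mismatch")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def truncated(self, horizon: int) -> "LongitudinalCohort":
        """Keep each subject's first ``horizon`` observed time points."""
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        return LongitudinalCohort(
            subject_ids=list(self.subject_ids),
            sequences=[seq[:horizon] for seq in self.sequences],
            labels=list(self.labels),
            canonical_grid=list(self.canonical_grid),
            n_features=self.n_features,
        )


@dataclass
class PaddedBatch:
    """Dense rank-3 batch: (n_subjects, T_slots, n_features) + observation mask."""

    values: np.ndarray
    mask: np.ndarray  # (n_subjects, T_slots), 1 = observed
    labels: np.ndarray
    strategy_tag: str
    canonical_grid: list[int] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.strategy_tag not in ("pad_in_sequence", "pad_at_end"):
            raise ValueError(f"unknown strategy_tag {self.strategy_tag!r}")
        off = self.values[self.mask == 0]
        if off.size and np.abs(off).sum() != 0.0:
            raise ValueError("padded (mask==0) slots must be exactly zero")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_slots(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def subset(self, idx: Sequence[int]) -> "PaddedBatch":
        idx = np.asarray(idx)
        return PaddedBatch(
            self.values[idx], self.mask[idx], self.labels[idx],
            self.strategy_tag, list(self.canonical_grid),
            [self.subject_ids[i] for i in idx] if self.subject_ids else [],
        )


def load_abundance_table(path: str | Path, delimiter: str | None = None) -> AbundanceTable:
    """Read a delimited abundance matrix: header row of feature ids, first
    column sample ids.  Delimiter is sniffed from the extension when not given.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw!r} at sample {df.index[i]!r}, "
                    f"feature {col!r} in {path.name}"
                ) from None
    return AbundanceTable(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=values,
    )


def load_metadata(path: str | Path, delimiter: str | None = None,
                  label_columns: Sequence[str] | None = None) -> SampleMetadata:
    """Read sample metadata with columns sample_id, subject_id, time_point and
    either a single ``label`` column or one 0/1 column per outcome label."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=delimiter, dtype={"sample_id": str, "subject_id": str})
    for col in ("sample_id", "subject_id", "time_point"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    if label_columns is None:
        label_columns = ["label"] if "label" in df.columns else [
            c for c in df.columns if c not in ("sample_id", "subject_id", "time_point")
        ]
    labels: dict[str, object] = {}
    for _, row in df.iterrows():
        if len(label_columns) == 1:
            labels[row["sample_id"]] = row[label_columns[0]]
        else:
            labels[row["sample_id"]] = tuple(int(row[c]) for c in label_columns)
    return SampleMetadata(
        sample_to_subject=dict(zip(df["sample_id"], df["subject_id"])),
        sample_to_time={s: int(t) for s, t in zip(df["sample_id"], df["time_point"])},
        labels=labels,
    )


def assemble_cohort(table: AbundanceTable, meta: SampleMetadata,
                    canonical_grid: Sequence[int]) -> LongitudinalCohort:
    """Group samples by subject, sort by time point, attach subject labels.

    Raises when a sample's time point is off-grid or a subject carries
    conflicting labels across its samples.
    """
    grid = list(canonical_grid)
    by_subject: dict[str, list[tuple[int, np.ndarray]]] = {}
    subj_labels: dict[str, object] = {}
    for i, sid in enumerate(table.sample_ids):
        if sid not in meta.sample_to_subject:
            raise ValueError(f"sample {sid!r} has no metadata entry")
        subj = meta.sample_to_subject[sid]
        t = meta.sample_to_time[sid]
        if t not in grid:
            raise ValueError(
                f"sample {sid!r} (subject {subj!r}) at time point {t} "
                f"not on canonical grid {grid}"
            )
        lab = meta.labels.get(sid)
        if subj in subj_labels and subj_labels[subj] != lab:
            raise ValueError(
                f"subject {subj!r} has conflicting labels "
                f"{subj_labels[subj]!r} vs {lab!r}"
            )
        subj_labels[subj] = lab
        by_subject.setdefault(subj, []).append((t, table.values[i]))
    subject_ids = sorted(by_subject)
    sequences = [sorted(by_subject[s], key=lambda tv: tv[0]) for s in subject_ids]
    return LongitudinalCohort(
        subject_ids=subject_ids,
        sequences=sequences,
        labels=[subj_labels[s] for s in subject_ids],
        canonical_grid=grid,
        n_features=table.n_features,
    )


def _encode_labels(labels: list[object]) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    if arr.size and isinstance(arr.reshape(-1)[0], tuple):
        return np.asarray([list(l) for l in labels], dtype=np.int64)
    return np.asarray(labels)


def pad_in_sequence(cohort: LongitudinalCohort) -> PaddedBatch:
    """Place each observation at its canonical slot; zero-fill missing slots."""
    grid = cohort.canonical_grid
    if not grid:
        raise ValueError("canonical grid is empty")
    slot = {t: k for k, t in enumerate(grid)}
    values = np.zeros((cohort.n_subjects, len(grid), cohort.n_features))
    mask = np.zeros((cohort.n_subjects, len(grid)), dtype=np.int8)
    for s, seq in enumerate(cohort.sequences):
        for t, vec in seq:
            values[s, slot[t]] = vec
            mask[s, slot[t]] = 1
    return PaddedBatch(values, mask, _encode_labels(cohort.labels),
                       "pad_in_sequence", list(grid), list(cohort.subject_ids))


def pad_at_end(cohort: LongitudinalCohort, force_grid_length: bool = False) -> PaddedBatch:
    """Compact each subject's observations to the leading slots, zero suffix.

    T_slots defaults to the maximum observed count across the cohort;
    ``force_grid_length`` pins it to the canonical grid length instead.
    """
    if not cohort.canonical_grid:
        raise ValueError("canonical grid is empty")
    n_obs = [len(seq) for seq in cohort.sequences]
    t_slots = len(cohort.canonical_grid) if force_grid_length else max(n_obs, default=0)
    values = np.zeros((cohort.n_subjects, t_slots, cohort.n_features))
    mask = np.zeros((cohort.n_subjects, t_slots), dtype=np.int8)
    for s, seq in enumerate(cohort.sequences):
        for k, (_, vec) in enumerate(seq):
            values[s, k] = vec
            mask[s, k] = 1
    return PaddedBatch(values, mask, _encode_labels(cohort.labels),
                       "pad_at_end", list(cohort.canonical_grid),
                       list(cohort.subject_ids))


@dataclass
class PCAMapping:
    """Fitted principal-component projection for observed abundance rows."""

    pca: PCA
    n_components: int


def fit_pca(train_values: np.ndarray, n_components: int = 300) -> PCAMapping:
    """Fit PCA on training-fold observed rows (time slots as independent rows).

    Fitting must see only mask==1 rows of training subjects to avoid fold
    leakage; callers pass those rows explicitly.
    """
    train_values = np.asarray(train_values, dtype=np.float64)
    bound = min(train_values.shape)
    if n_components > bound:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {bound} "
            f"(n_rows={train_values.shape[0]}, n_features={train_values.shape[1]})"
        )
    pca = PCA(n_components=n_components, svd_solver="full" if n_components == min(train_values.shape) else "auto")
    pca.fit(train_values)
    return PCAMapping(pca=pca, n_components=n_components)


def apply_pca(mapping: PCAMapping, batch: PaddedBatch) -> PaddedBatch:
    """Project observed rows onto the components; padded rows stay all-zero."""
    n, t, _ = batch.values.shape
    out = np.zeros((n, t, mapping.n_components))
    obs = batch.mask.astype(bool)
    if obs.any():
        out[obs] = mapping.pca.transform(batch.values[obs])
    return PaddedBatch(out, batch.mask.copy(), batch.labels,
                       batch.strategy_tag, list(batch.canonical_grid),
                       list(batch.subject_ids))


def save_batch(batch: PaddedBatch, path: str | Path) -> None:
    """Serialize a padded batch to HDF5 (datasets values/mask/labels)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=batch.values)
        f.create_dataset("mask", data=batch.mask)
        labels = np.asarray(batch.labels)
        if labels.dtype.kind in ("U", "O"):
            labels = labels.astype("S")
        f.create_dataset("labels", data=labels)
        f.attrs["strategy_tag"] = batch.strategy_tag
        f.attrs["canonical_grid"] = batch.canonical_grid
        if batch.subject_ids:
            f.create_dataset("subject_ids",
                             data=np.asarray(batch.subject_ids, dtype="S"))


def load_batch(path: str | Path) -> PaddedBatch:
    with h5py.File(path, "r") as f:
        labels = f["labels"][:]
        if labels.dtype.kind == "S":
            labels = labels.astype(str)
        subject_ids = (
            [s.decode() for s in f["subject_ids"][:]] if "subject_ids" in f else []
        )
        return PaddedBatch(
            f["values"][:], f["mask"][:], labels,
            f.attrs["strategy_tag"], list(f.attrs["canonical_grid"]),
            subject_ids,
        )
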