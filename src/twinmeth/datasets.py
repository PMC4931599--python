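"""Core containers and TSV I/O for discordant-twin methylation cohorts.

The central objects are a feature x sample matrix of log-normalized
methylation levels (:class:`MethylationDataset`), per-sample metadata
(:class:`SampleMetadata`) recording twin-pair membership, study region
(the batch) and affection status, and the validated combination of the
two (:class:`LabeledDataset`).

Every twin pair must be *discordant*: exactly one affected and one
unaffected member, both drawn from the same region.  The pair, not the
individual sample, is the unit of resampling downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

AFFECTED = "affected"
UNAFFECTED = "unaffected"
STATUSES = (AFFECTED, UNAFFECTED)


class ValidationError(ValueError):
    """A dataset or metadata invariant was violated."""


@dataclass(frozen=True)
class SampleMetadata:
    """One sample: its id, twin-pair id, region (batch) and status."""

    sample_id: str
    pair_id: str
    batch_id: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(
                f"sample {self.sample_id!r}: status must be one of {STATUSES}, "
                f"got {self.status!r}"
            )


@dataclass
class MethylationDataset:
    """A G x N matrix of log-normalized methylation values with ids."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        g, n = self.values.shape
        if g == 0 or n == 0:
            raise ValidationError("degenerate dataset: empty feature or sample axis")
        if len(self.feature_ids) != g:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {g} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if len(set(self.feature_ids)) != g:
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        in_unit = np.mean((self.values >= 0.0) & (self.values <= 1.0))
        if in_unit > 0.99:
            warnings.warn(
                "more than 99% of values lie in [0, 1]; these look like beta "
                "values, but the pipeline expects log-normalized levels",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledDataset:
    """A methylation matrix plus aligned per-sample metadata."""

    dataset: MethylationDataset
    metadata: list[SampleMetadata]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids_meta = [m.sample_id for m in self.metadata]
        if ids_meta != self.dataset.sample_ids:
            raise ValidationError(
                "metadata sample order does not match matrix columns"
            )
        by_pair: dict[str, list[SampleMetadata]] = {}
        for m in self.metadata:
            by_pair.setdefault(m.pair_id, []).append(m)
        for pair_id, members in by_pair.items():
            if len(members) != 2:
                raise ValidationError(
                    f"pair {pair_id!r} has {len(members)} samples, expected 2"
                )
            statuses = sorted(m.status for m in members)
            if statuses != [AFFECTED, UNAFFECTED]:
                raise ValidationError(
                    f"pair {pair_id!r} is not discordant "
                    f"(statuses {statuses})"
                )
            if members[0].batch_id != members[1].batch_id:
                raise ValidationError(
                    f"pair {pair_id!r} spans batches "
                    f"{members[0].batch_id!r} and {members[1].batch_id!r}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return self.dataset.values

    @property
    def feature_ids(self) -> list[str]:
        return self.dataset.feature_ids

    @property
    def sample_ids(self) -> list[str]:
        return self.dataset.sample_ids

    @property
    def n_features(self) -> int:
        return self.dataset.n_features

    @property
    def n_samples(self) -> int:
        return self.dataset.n_samples

    def labels(self) -> np.ndarray:
        """0/1 label vector, 1 = affected."""
        return np.array([1 if m.status == AFFECTED else 0 for m in self.metadata])

    def batch_ids(self) -> list[str]:
        return [m.batch_id for m in self.metadata]

    def pair_ids(self) -> list[str]:
        return [m.pair_id for m in self.metadata]

    def batches(self) -> list[str]:
        """Batch labels in order of first appearance."""
        seen: dict[str, None] = {}
        for m in self.metadata:
            seen.setdefault(m.batch_id, None)
        return list(seen)

    def subset_samples(self, index: np.ndarray) -> "LabeledDataset":
        """Column subset (samples) by integer index; pairs must stay intact."""
        index = np.asarray(index)
        ds = MethylationDataset(
            self.values[:, index],
            list(self.feature_ids),
            [self.sample_ids[i] for i in index],
        )
        return LabeledDataset(ds, [self.metadata[i] for i in index])

    def subset_features(self, feature_ids: list[str]) -> "LabeledDataset":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        ds = MethylationDataset(
            self.values[idx, :], list(feature_ids), list(self.sample_ids)
        )
        return LabeledDataset(ds, list(self.metadata))

    def with_values(self, values: np.ndarray) -> "LabeledDataset":
        """Same ids/metadata with a replaced value matrix."""
        ds = MethylationDataset(
            np.asarray(values, dtype=float),
            list(self.feature_ids),
            list(self.sample_ids),
        )
        return LabeledDataset(ds, list(self.metadata))

    def split_by_batch(self) -> list["LabeledDataset"]:
        """One single-region dataset per batch, batches in first-appearance order."""
        out = []
        batch_arr = np.array(self.batch_ids())
        for b in self.batches():
            out.append(self.subset_samples(np.flatnonzero(batch_arr == b)))
        return out

    def copy(self) -> "LabeledDataset":
        return self.with_values(self.values.copy())


def read_labeled_dataset(matrix_path, metadata_path) -> LabeledDataset:
    """Read matrix + metadata TSVs and return a validated dataset.

    The matrix file has feature ids in the first column and one column
    per sample; the metadata file has columns sample_id, pair_id,
    batch_id, status.  Samples are reordered so the metadata follows the
    matrix column order.
    """
    mat = pd.read_csv(
        matrix_path, sep="\t", index_col=0, dtype={0: str},
        float_precision="round_trip",
    )
    for col in mat.columns:
        if not pd.api.types.is_numeric_dtype(mat[col]):
            bad = mat.index[pd.to_numeric(mat[col], errors="coerce").isna()][0]
            raise ValidationError(
                f"non-numeric cell at feature {bad!r}, sample {col!r}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = ["sample_id", "pair_id", "batch_id", "status"]
    missing_cols = [c for c in required if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing columns {missing_cols}")
    meta_ids = set(meta["sample_id"])
    mat_ids = set(map(str, mat.columns))
    for sid in sorted(mat_ids - meta_ids):
        raise ValidationError(f"sample {sid!r} present in matrix but not metadata")
    for sid in sorted(meta_ids - mat_ids):
        raise ValidationError(f"sample {sid!r} present in metadata but not matrix")
    meta = meta.set_index("sample_id").loc[[str(c) for c in mat.columns]]
    metadata = [
        SampleMetadata(str(sid), row["pair_id"], row["batch_id"], row["status"])
        for sid, row in meta.iterrows()
    ]
    dataset = MethylationDataset(
        mat.to_numpy(dtype=float),
        [str(f) for f in mat.index],
        [str(c) for c in mat.columns],
    )
    return LabeledDataset(dataset, metadata)


def write_labeled_dataset(data: LabeledDataset, matrix_path, metadata_path) -> None:
    """Write the TSV pair read back by :func:`read_labeled_dataset`.

    Values are written with ``repr`` precision so the round-trip is
    lossless for float64.
    """
    mat = pd.DataFrame(
        data.values, index=data.feature_ids, columns=data.sample_ids
    )
    mat.index.name = "feature_id"
    mat.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in data.metadata],
            "pair_id": [m.pair_id for m in data.metadata],
            "batch_id": [m.batch_id for m in data.metadata],
            "status": [m.status for m in data.metadata],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def merge_regions(datasets: list[LabeledDataset]) -> LabeledDataset:
    """Concatenate region datasets over the common feature panel.

    Features are restricted to the intersection of the inputs' feature
    sets, kept in the first input's order; samples are concatenated in
    input order.  Batch ids and pair ids must be disjoint across inputs.
    """
    if len(datasets) < 2:
        raise ValidationError("merge_regions needs at least 2 datasets")
    common = set(datasets[0].feature_ids)
    for d in datasets[1:]:
        common &= set(d.feature_ids)
    if not common:
        raise ValidationError("empty feature intersection across regions")
    features = [f for f in datasets[0].feature_ids if f in common]

    seen_batches: set[str] = set()
    seen_pairs: set[str] = set()
    seen_samples: set[str] = set()
    for d in datasets:
        b = set(d.batch_ids())
        p = set(d.pair_ids())
        s = set(d.sample_ids)
        if seen_batches & b:
            raise ValidationError(
                f"batch ids {sorted(seen_batches & b)} appear in multiple regions"
            )
        if seen_pairs & p:
            raise ValidationError(
                f"pair ids {sorted(seen_pairs & p)} appear in multiple regions"
            )
        if seen_samples & s:
            raise ValidationError(
                f"duplicate sample ids {sorted(seen_samples & s)} across regions"
            )
        seen_batches |= b
        seen_pairs |= p
        seen_samples |= s

    blocks = []
    metadata: list[SampleMetadata] = []
    sample_ids: list[str] = []
    for d in datasets:
        pos = {f: i for i, f in enumerate(d.feature_ids)}
        blocks.append(d.values[[pos[f] for f in features], :])
        metadata.extend(d.metadata)
        sample_ids.extend(d.sample_ids)
    merged = MethylationDataset(np.hstack(blocks), features, sample_ids)
    return LabeledDataset(merged, metadata)
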