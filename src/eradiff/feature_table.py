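"""Genus-level count table: IO, filtering, and compositional transforms.

The table is a samples x taxa matrix of non-negative integer counts with
per-sample metadata (patient, era, admission day, collection day).  All
abundance statistics downstream operate on the centered log-ratio (clr)
scale; Aitchison distance is Euclidean distance between clr rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ERA_VALUES = ("pre", "covid")

METADATA_COLUMNS = ("patient_id", "era", "admission_day", "collection_day")


class InputError(ValueError):
    """Malformed or inconsistent input tables."""


class EmptyResultError(ValueError):
    """A filter removed every sample."""


@dataclass
class CountTable:
    """Samples x taxa counts joined with per-sample metadata.

    ``counts`` is indexed by sample id with taxon labels as columns;
    ``metadata`` is indexed by sample id with columns
    ``patient_id, era, admission_day, collection_day``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise InputError(f"duplicate sample ids: {dupes}")
        if (self.counts.values < 0).any():
            raise InputError("negative counts in table")
        missing = self.counts.index.difference(self.metadata.index)
        if len(missing) > 0:
            raise InputError(f"samples without metadata: {sorted(missing)}")
        self.metadata = self.metadata.loc[self.counts.index]
        bad_era = set(self.metadata["era"]) - set(ERA_VALUES)
        if bad_era:
            raise InputError(f"era values must be one of {ERA_VALUES}, got {sorted(bad_era)}")
        if (self.metadata["collection_day"] < self.metadata["admission_day"]).any():
            bad = self.metadata.index[
                self.metadata["collection_day"] < self.metadata["admission_day"]
            ].tolist()
            raise InputError(f"collection day before admission day for samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]


@dataclass
class ClrMatrix:
    """clr-transformed abundances; rows sum to zero."""

    values: pd.DataFrame
    pseudocount: float
    source: CountTable | None = field(default=None, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise sample distances."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.ids):
            raise InputError("distance matrix shape does not match ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def read_count_table(table_path, metadata_path) -> CountTable:
    """Read a count TSV and a metadata TSV and join them.

    The count table may be taxa-major (BIOM-style TSV export, first header
    cell ``#OTU ID`` or starting with ``#``, taxa as rows) or sample-major
    (samples as rows); the orientation is auto-detected from the header
    sentinel.  Metadata must contain the columns
    ``sample_id, patient_id, era, admission_day, collection_day``.
    """
    counts = pd.read_csv(table_path, sep="\t", index_col=0, comment=None)
    if str(counts.index.name or "").startswith("#"):
        counts = counts.T  # taxa-major export: transpose to samples x taxa
    counts.index = counts.index.astype(str).rename("sample_id")
    counts.columns = pd.Index([str(c) for c in counts.columns], name=None)
    try:
        counts = counts.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise InputError(f"count table is not integer-valued: {exc}") from exc

    metadata = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing_cols = set(("sample_id",) + METADATA_COLUMNS) - set(metadata.columns)
    if missing_cols:
        raise InputError(f"metadata missing required columns: {sorted(missing_cols)}")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in metadata: {dupes}")
    metadata = metadata.set_index("sample_id")[list(METADATA_COLUMNS)]
    metadata["admission_day"] = metadata["admission_day"].astype(int)
    metadata["collection_day"] = metadata["collection_day"].astype(int)
    return CountTable(counts=counts, metadata=metadata)


def filter_table(
    table: CountTable,
    min_sample_reads: int = 500,
    min_taxon_frac: float = 0.0001,
    sample_filter_first: bool = True,
) -> CountTable:
    """Drop low-depth samples, then rare taxa.

    Samples with total reads strictly below ``min_sample_reads`` are removed;
    then taxa whose total count across the retained samples is strictly below
    ``min_taxon_frac`` of the grand total are removed (a taxon sitting exactly
    on the threshold is retained).  ``sample_filter_first=False`` swaps the
    order of the two steps for sensitivity checks.
    """

    def _drop_samples(counts: pd.DataFrame) -> pd.DataFrame:
        keep = counts.sum(axis=1) >= min_sample_reads
        return counts.loc[keep]

    def _drop_taxa(counts: pd.DataFrame) -> pd.DataFrame:
        grand_total = counts.values.sum()
        if grand_total == 0:
            return counts
        keep = counts.sum(axis=0) >= min_taxon_frac * grand_total
        return counts.loc[:, keep]

    counts = table.counts
    if sample_filter_first:
        counts = _drop_taxa(_drop_samples(counts))
    else:
        counts = _drop_samples(_drop_taxa(counts))
    if counts.shape[0] == 0:
        raise EmptyResultError(
            f"all samples removed by the depth filter (min_sample_reads={min_sample_reads})"
        )
    return CountTable(counts=counts.copy(), metadata=table.metadata.loc[counts.index].copy())


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform of pseudocounted counts.

    Per sample: ``x_i = log(c_i + pseudocount) - mean_j log(c_j + pseudocount)``.
    Each output row sums to zero.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise InputError("cannot clr-transform an empty table")
    counts = table.counts.values.astype(float)
    if pseudocount <= 0 and (counts == 0).any():
        raise ValueError("pseudocount must be > 0 when the table contains zero counts")
    logs = np.log(counts + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    values = pd.DataFrame(clr, index=table.counts.index, columns=table.counts.columns)
    return ClrMatrix(values=values, pseudocount=pseudocount, source=table)


def aitchison_distance(matrix: ClrMatrix) -> DistanceMatrix:
    """Pairwise Aitchison distance: Euclidean distance between clr rows."""
    x = matrix.values.values
    if x.shape[0] < 2:
        raise InputError("need at least 2 samples for a distance matrix")
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.clip(d2, 0.0, None, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(values=d, ids=matrix.sample_ids)
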