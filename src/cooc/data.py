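"""Count and presence/absence tables, binarization and 2x2 contingency extraction.

The unit of analysis throughout the package is a taxon-by-sample binary
occupancy matrix.  Raw read-count tables are binarized with a read-count
threshold (a taxon counts as present in a sample only when its read count
strictly exceeds the threshold; the conventional cutoff for shotgun
classifier output is 100 reads).  Each unordered taxon pair then reduces to
a 2x2 contingency table over samples:

    a  co-presence        b  only taxon i present
    c  only taxon j       d  co-absence

with a + b + c + d = number of samples.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "PresenceAbsenceMatrix",
    "ContingencyTable",
    "read_count_table",
    "read_presence_absence",
    "write_table",
    "threshold_counts",
    "contingency_for_pair",
    "prevalence",
    "coabsent_percent_summary",
]


class TableFormatError(ValueError):
    """Malformed input table (bad cell value, duplicate labels, ...)."""


def _check_labels(labels: list[str], axis: str) -> None:
    if len(set(labels)) != len(labels):
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise TableFormatError(f"duplicate {axis} label: {lab!r}")
            seen.add(lab)


@dataclass
class CountTable:
    """Taxon-by-sample matrix of nonnegative integer read counts."""

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        _check_labels(self.taxon_ids, "taxon")
        _check_labels(self.sample_ids, "sample")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise TableFormatError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(
            taxon_ids=[str(t) for t in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
        )


@dataclass
class PresenceAbsenceMatrix:
    """Taxon-by-sample binary occupancy; 1 = present."""

    taxon_ids: list[str]
    sample_ids: list[str]
    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy)
        if self.occupancy.ndim != 2:
            raise TableFormatError("occupancy must be a 2-D matrix")
        if self.occupancy.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise TableFormatError("occupancy shape does not match label lists")
        _check_labels(self.taxon_ids, "taxon")
        _check_labels(self.sample_ids, "sample")
        vals = np.unique(self.occupancy)
        if not np.all(np.isin(vals, (0, 1))):
            raise TableFormatError("occupancy entries must be 0 or 1")
        self.occupancy = self.occupancy.astype(np.uint8)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy, index=self.taxon_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceAbsenceMatrix":
        return cls(
            taxon_ids=[str(t) for t in df.index],
            sample_ids=[str(s) for s in df.columns],
            occupancy=df.to_numpy(),
        )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 per-pair cell counts: a co-present, b/c exclusive, d co-absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n_sites(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """The same pair with species roles exchanged (b and c swap)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _resolve_delimiter(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_count_table(path: str, delimiter: str | None = None) -> CountTable:
    """Read a delimited taxon-by-sample count table.

    Row 1 holds sample labels, column 1 taxon labels.  The delimiter is
    inferred from the extension (.csv -> comma, otherwise tab) unless given.
    """
    sep = _resolve_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                v = int(str(cell).strip())
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"non-integer count {cell!r} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r} in {path}"
                ) from None
            if v < 0:
                raise TableFormatError(
                    f"negative count {v} at taxon {df.index[i]!r}, "
                    f"sample {df.columns[j]!r} in {path}"
                )
            values[i, j] = v
    return CountTable(
        taxon_ids=[str(t) for t in df.index],
        sample_ids=[str(s) for s in df.columns],
        counts=values,
    )


def read_presence_absence(path: str, delimiter: str | None = None) -> PresenceAbsenceMatrix:
    """Read a delimited binary occupancy matrix (same layout as counts)."""
    table = read_count_table(path, delimiter)
    if table.counts.size and table.counts.max() > 1:
        raise TableFormatError(
            f"{path} contains values > 1; binarize it first (threshold_counts)"
        )
    return PresenceAbsenceMatrix(table.taxon_ids, table.sample_ids, table.counts)


def write_table(obj: CountTable | PresenceAbsenceMatrix, path: str,
                delimiter: str | None = None) -> None:
    """Write a table in the same delimited layout the readers accept."""
    sep = _resolve_delimiter(path, delimiter)
    obj.to_frame().to_csv(path, sep=sep)


def threshold_counts(table: CountTable, min_reads: int = 100) -> PresenceAbsenceMatrix:
    """Binarize counts: present iff count > min_reads (strictly greater)."""
    if min_reads < 0:
        raise ValueError(f"min_reads must be nonnegative, got {min_reads}")
    return PresenceAbsenceMatrix(
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        occupancy=(table.counts > min_reads).astype(np.uint8),
    )


def contingency_for_pair(pa: PresenceAbsenceMatrix, i: int, j: int) -> ContingencyTable:
    """2x2 contingency table for taxa i and j over all samples."""
    if i == j:
        raise ValueError("contingency_for_pair requires two distinct taxa")
    xi = pa.occupancy[i].astype(np.int64)
    xj = pa.occupancy[j].astype(np.int64)
    a = int(np.sum(xi & xj))
    b = int(np.sum(xi) - a)
    c = int(np.sum(xj) - a)
    d = pa.n_sites - a - b - c
    return ContingencyTable(a, b, c, d)


def prevalence(pa: PresenceAbsenceMatrix, i: int) -> float:
    """Fraction of sites occupied by taxon i."""
    if pa.n_sites == 0:
        raise ValueError("prevalence undefined for a matrix with zero samples")
    return float(pa.occupancy[i].sum()) / pa.n_sites


def coabsent_percent_summary(pa: PresenceAbsenceMatrix) -> float:
    """Median over all unordered taxon pairs of 100*d/N_sites."""
    if pa.n_taxa < 2:
        raise ValueError("need at least 2 taxa to form pairs")
    if pa.n_sites < 1:
        raise ValueError("need at least 1 sample")
    x = pa.occupancy.astype(np.int64)
    co_present = x @ x.T
    row = x.sum(axis=1)
    # d = N - (s_i + s_j - a) for each pair
    d = pa.n_sites - (row[:, None] + row[None, :] - co_present)
    iu = np.triu_indices(pa.n_taxa, k=1)
    return float(np.median(100.0 * d[iu] / pa.n_sites))
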