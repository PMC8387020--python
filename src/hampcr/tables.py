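"""Shared data model: count tables, amplicon maps, sample metadata.

The counting unit is the ASV (amplicon sequence variant, a.k.a. zOTU): an
exact denoised amplicon sequence.  A host+microbe amplicon experiment yields
one count table in which at least one ASV derives from a low-copy host gene
(e.g. *GIGANTEA*, *PolA1*, *LD*, *csq-1*) and the rest from microbial marker
amplicons (16S rDNA variable regions, ITS1, a pathogen actin gene, ...).
The amplicon map records which ASV is which; everything downstream (loads,
QC, remix reconstruction) consumes these two objects.

Counts stay integers on disk and in memory: sequencing counts are auditable
raw data, and every derived fractional quantity (relative abundance, load)
lives in its own real-valued table.  Identifiers are case-sensitive opaque
strings and are never normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HOST_CLASS",
    "CountTable",
    "AmpliconMap",
    "SampleMetadata",
    "TableFormatError",
    "read_count_table",
    "write_count_table",
    "read_amplicon_map",
    "write_amplicon_map",
    "read_metadata",
    "write_metadata",
    "aggregate_by_taxon",
]

#: Amplicon class label reserved for host-derived ASVs.
HOST_CLASS = "host"


class TableFormatError(ValueError):
    """A file or in-memory table violates the data-model invariants."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]
    if dups:
        raise TableFormatError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass(frozen=True)
class CountTable:
    """Non-negative integer ASV x sample matrix.

    Parameters
    ----------
    counts
        DataFrame with ASV identifiers on the index and sample identifiers
        on the columns.  Entries must be non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "asv_id")
        _check_unique(df.columns, "sample_id")
        values = df.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise TableFormatError("counts must be numeric")
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise TableFormatError(
                    f"negative count at asv {df.index[r]!r}, sample {df.columns[c]!r}"
                )
            if not np.allclose(values, np.round(values)):
                r, c = np.argwhere(values != np.round(values))[0]
                raise TableFormatError(
                    f"non-integer count at asv {df.index[r]!r}, sample {df.columns[c]!r}"
                )
        object.__setattr__(self, "counts", df.astype(np.int64))

    @classmethod
    def from_arrays(
        cls, counts, asv_ids: Iterable[str], sample_ids: Iterable[str]
    ) -> "CountTable":
        return cls(pd.DataFrame(np.asarray(counts), index=list(asv_ids),
                                columns=list(sample_ids)))

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.counts.equals(other.counts)


@dataclass(frozen=True)
class AmpliconMap:
    """Assignment of every ASV to an amplicon class.

    Each ASV belongs either to the ``host`` class or to a named microbial
    marker (e.g. ``"16S-V4"``, ``"ITS1"``, ``"Hpa-actin"``).  An optional
    taxon label supports aggregation, and an optional per-ASV copy number
    (default 1) supports rDNA copy-number normalization and multi-copy host
    genes.
    """

    table: pd.DataFrame  # index asv_id; columns amplicon_class, taxon_label, copy_number

    def __post_init__(self) -> None:
        df = self.table.copy()
        _check_unique(df.index, "asv_id")
        if "amplicon_class" not in df.columns:
            raise TableFormatError("amplicon map needs an amplicon_class column")
        if "taxon_label" not in df.columns:
            df["taxon_label"] = df.index
        df["taxon_label"] = df["taxon_label"].fillna(pd.Series(df.index, index=df.index))
        if "copy_number" not in df.columns:
            df["copy_number"] = 1.0
        df["copy_number"] = pd.to_numeric(df["copy_number"]).fillna(1.0)
        if (df["copy_number"] <= 0).any():
            bad = df.index[df["copy_number"] <= 0].tolist()
            raise TableFormatError(f"copy_number must be > 0, offending ASVs: {bad}")
        object.__setattr__(self, "table", df[["amplicon_class", "taxon_label", "copy_number"]])

    @classmethod
    def from_dict(cls, classes: dict[str, str],
                  taxa: dict[str, str] | None = None,
                  copy_numbers: dict[str, float] | None = None) -> "AmpliconMap":
        idx = list(classes)
        df = pd.DataFrame({"amplicon_class": pd.Series(classes)}, index=idx)
        if taxa:
            df["taxon_label"] = pd.Series(taxa)
        if copy_numbers:
            df["copy_number"] = pd.Series(copy_numbers)
        return cls(df)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.table.index)

    def amplicon_class(self, asv_id: str) -> str:
        return str(self.table.at[asv_id, "amplicon_class"])

    def copy_number(self, asv_id: str) -> float:
        return float(self.table.at[asv_id, "copy_number"])

    def host_asvs(self) -> list[str]:
        mask = self.table["amplicon_class"] == HOST_CLASS
        return list(self.table.index[mask])

    def microbial_asvs(self) -> list[str]:
        mask = self.table["amplicon_class"] != HOST_CLASS
        return list(self.table.index[mask])

    def validate_against(self, table: CountTable, require_host: bool = False) -> None:
        """Check that every ASV in *table* is mapped (and a host exists)."""
        missing = [a for a in table.asv_ids if a not in self.table.index]
        if missing:
            raise TableFormatError(f"unmapped ASVs: {missing}")
        if require_host:
            hosts = set(self.host_asvs()) & set(table.asv_ids)
            if not hosts:
                raise TableFormatError(
                    "no ASV of class 'host' present in the count table; "
                    "load operations need a host denominator"
                )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: group, reference flag, replicate, titration volumes."""

    table: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        df = self.table.copy()
        _check_unique(df.index, "sample_id")
        if "is_reference" not in df.columns:
            df["is_reference"] = False
        df["is_reference"] = df["is_reference"].map(_parse_bool)
        if "group" not in df.columns:
            df["group"] = ""
        object.__setattr__(self, "table", df)

    @classmethod
    def from_reference_flags(cls, flags: dict[str, bool]) -> "SampleMetadata":
        return cls(pd.DataFrame({"is_reference": pd.Series(flags)}))

    def reference_samples(self) -> list[str]:
        return list(self.table.index[self.table["is_reference"]])

    def non_reference_samples(self) -> list[str]:
        return list(self.table.index[~self.table["is_reference"]])

    def validate_against(self, table: CountTable) -> None:
        missing = [s for s in self.table.index if s not in set(table.sample_ids)]
        if missing:
            raise TableFormatError(f"metadata references unknown samples: {missing}")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f", "", "nan"}:
        return False
    raise TableFormatError(f"cannot interpret {v!r} as a boolean")


# ---------------------------------------------------------------------------
# TSV I/O.  Canonical on-disk form: UTF-8 TSV, first header cell "asv_id",
# one column per sample.  Plain TSV matches USEARCH-style upstream tables.
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Read a TSV count table (first column = ASV ids, header = sample ids).

    ``dialect="biom-style tsv"`` additionally tolerates a leading
    ``# Constructed from biom file`` comment line and an ``#OTU ID`` header
    cell, as emitted by classic BIOM TSV exports.
    """
    path = Path(path)
    if dialect not in {"tsv", "biom-style tsv"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    kwargs = {"sep": "\t", "index_col": 0, "dtype": str}
    if dialect == "biom-style tsv":
        kwargs["comment"] = None
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        if first.startswith("# "):
            kwargs["skiprows"] = 1
    try:
        raw = pd.read_csv(path, **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows: pandas reports the line
        raise TableFormatError(f"{path}: {exc}") from exc
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    try:
        numeric = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric count cell ({exc})") from exc
    return CountTable(numeric)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write *table* as UTF-8 TSV, losslessly round-trippable by ``read_count_table``."""
    df = table.counts.copy()
    df.index.name = "asv_id"
    df.to_csv(Path(path), sep="\t", encoding="utf-8")


def read_amplicon_map(path: str | Path) -> AmpliconMap:
    df = pd.read_csv(Path(path), sep="\t", index_col="asv_id", dtype=str)
    return AmpliconMap(df)


def write_amplicon_map(amap: AmpliconMap, path: str | Path) -> None:
    df = amap.table.copy()
    df.index.name = "asv_id"
    df.to_csv(Path(path), sep="\t", encoding="utf-8")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(Path(path), sep="\t", index_col="sample_id", dtype=str)
    for col in ("titration_a_ul", "titration_b_ul"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(Path(path), sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate_by_taxon(
    table: CountTable,
    amap: AmpliconMap,
    level: Callable[[str], str] | None = None,
) -> CountTable:
    """Sum ASV counts into taxon rows.

    Microbial ASVs are grouped by their taxon label (optionally transformed
    by *level*, e.g. ``lambda lab: lab.split(";")[0]`` to cut a lineage
    string at the family rank).  Host ASVs are kept apart, collapsed into
    one row per host amplicon class, so host counts remain available as the
    load denominator after aggregation.  Per-sample totals are preserved
    exactly.
    """
    amap.validate_against(table)
    level = level or (lambda lab: lab)
    sub = amap.table.loc[table.asv_ids]
    is_host = sub["amplicon_class"] == HOST_CLASS
    labels = sub["taxon_label"].map(level)
    labels[is_host] = sub.loc[is_host, "amplicon_class"]
    grouped = table.counts.groupby(labels.values, sort=False).sum()
    grouped.index = grouped.index.astype(str)
    return CountTable(grouped)
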