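"""Readers/writers for count matrices, sample metadata and gene sets.

The canonical interchange format throughout is tab-separated text: a count
matrix is genes x samples with the gene identifier in the first column and
sample identifiers in the header; sample metadata is one row per sample with
at least a ``group`` column; gene sets use the GMT dialect (set name,
description, then members). Gene identifiers are opaque, case-sensitive
strings — orthologue mapping between species is the caller's responsibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_gene_sets",
]

#: columns a metadata table may carry beyond ``sample_id``
METADATA_COLUMNS = ("group", "stage", "status")


class FormatError(ValueError):
    """A file or table violates the format contract (duplicate ids, negative
    counts, missing samples, ...)."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count matrix.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with sample ids as columns. Values must
        be non-negative integers; ids must be unique.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = sorted(set(df.index[df.index.duplicated()]))
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dups))}")
        if df.columns.duplicated().any():
            dups = sorted(set(df.columns[df.columns.duplicated()]))
            raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dups))}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac = values != np.floor(values)
            if frac.any():
                g, s = np.argwhere(frac)[0]
                raise FormatError(
                    f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
                )
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.counts = df.astype(np.int64)
        self.counts.index.name = "gene_id"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated genes x samples count matrix.

    First column holds gene ids, header row sample ids. Raises
    :class:`FormatError` for negative or non-integer values (naming the
    offending cell) and for duplicated identifiers.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric value in count matrix {path}: {exc}") from exc
    return CountMatrix(numeric)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path, matrix: CountMatrix) -> pd.DataFrame:
    """Read sample metadata and align it to ``matrix``.

    The file must be tab-separated with columns ``sample_id`` and ``group``;
    ``stage`` and ``status`` are optional. Samples missing from the file raise
    :class:`FormatError`; extra rows are dropped with a warning. The result is
    indexed by sample id in the matrix's sample order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise FormatError("metadata requires columns 'sample_id' and 'group'")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise FormatError(f"duplicate sample id(s) in metadata: {', '.join(dups)}")
    df = df.set_index("sample_id")
    missing = matrix.samples.difference(df.index)
    if len(missing):
        raise FormatError(
            f"metadata missing sample(s): {', '.join(map(str, sorted(missing)))}"
        )
    extra = df.index.difference(matrix.samples)
    if len(extra):
        logger.warning(
            "metadata contains %d sample(s) absent from the count matrix "
            "(dropped): %s", len(extra), ", ".join(map(str, sorted(extra)))
        )
    meta = df.loc[matrix.samples]
    if meta["group"].isna().any() or (meta["group"] == "").any():
        raise FormatError("every sample needs a non-empty group label")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe, for over-representation
    analysis. Members outside the universe are reported and dropped."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        cleaned = {}
        for name, members in self.sets.items():
            outside = members - self.universe
            if outside:
                warnings.warn(
                    f"gene set {name!r}: {len(outside)} member(s) outside the "
                    f"universe dropped", stacklevel=2,
                )
            kept = members & self.universe
            if kept:
                cleaned[name] = kept
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)


def read_gene_sets(path: str | Path, universe=None) -> GeneSetCollection:
    """Parse a GMT file (set name, description, member ids; tab-separated).

    Duplicate members within a set are collapsed; empty set lines are skipped
    with a warning. The universe defaults to the union of all members.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            name, members = fields[0], [m for m in fields[2:] if m]
            if not members:
                warnings.warn(f"GMT line {lineno}: set {name!r} is empty, skipped")
                continue
            sets[name] = set(members)
    if not sets:
        warnings.warn(f"no gene sets parsed from {path}")
    return GeneSetCollection(sets, set(universe) if universe is not None else set())
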