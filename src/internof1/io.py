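"""Count-matrix and gene-set I/O.

Count matrices are genes x samples tables (TSV/CSV, first column = gene
identifiers, header row = sample identifiers).  Gene-set collections use the
GMT exchange format: one set per line, ``set_id <TAB> description <TAB>
gene1 <TAB> gene2 ...``.

Gene identifiers are compared case-sensitively as exact strings throughout;
no symbol/alias mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "filter_genesets",
]


def _find_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


@dataclass
class CountMatrix:
    """A genes x samples expression matrix with identifier bookkeeping.

    Counts are stored as floats so that normalized data can pass through the
    same container, but all values must be nonnegative and dimensions must
    match the identifier lists.
    """

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = _find_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        dup = _find_duplicate(self.samples)
        if dup is not None:
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def column(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def subset_genes(self, keep: np.ndarray | Sequence[str]) -> "CountMatrix":
        """Return a matrix restricted to ``keep`` (boolean mask or gene ids)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([g in wanted for g in self.genes])
        genes = [g for g, m in zip(self.genes, mask) if m]
        return CountMatrix(genes, list(self.samples), self.counts[mask, :])

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_index(s) for s in samples]
        return CountMatrix(list(self.genes), list(samples), self.counts[:, idx])


def read_counts(path: str | Path, delimiter: str = "\t") -> CountMatrix:
    """Read a delimited genes x samples count table.

    The first column holds gene identifiers and the header row sample
    identifiers.  Raises on duplicate gene ids (naming the offender) and on
    non-numeric cells (naming the coordinates).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    genes = [str(g) for g in frame.index]
    dup = _find_duplicate(genes)
    if dup is not None:
        raise ValueError(f"{path}: duplicate gene identifier {dup!r}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            gene = frame.index[int(np.argmax(bad.to_numpy()))]
            raise ValueError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = frame.index[int(np.argmax(converted.isna().to_numpy()))]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    return CountMatrix(genes, [str(s) for s in frame.columns], values)


def write_counts(matrix: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=delimiter, index_label="gene")


@dataclass
class GeneSet:
    """A named collection of unique gene identifiers (e.g. one GO-BP term)."""

    set_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.genes = tuple(str(g) for g in self.genes)
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        dup = _find_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"gene set {self.set_id!r} has duplicate gene {dup!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def intersect(self, universe: Iterable[str]) -> frozenset[str]:
        return frozenset(self.genes) & frozenset(universe)


@dataclass
class GeneSetCollection:
    """An ordered collection of gene sets with unique identifiers."""

    sets: list[GeneSet]
    universe: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        dup = _find_duplicate([s.set_id for s in self.sets])
        if dup is not None:
            raise ValueError(f"duplicate gene-set identifier: {dup!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def get(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate genes within a line are removed with a warning; a line with
    fewer than three tab-separated fields is an error (reported with its
    line number), as is a repeated set identifier.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name, *genes = fields
            genes = [g for g in genes if g != ""]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: gene set {set_id!r} lists duplicate genes; "
                    "de-duplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id, name, tuple(unique)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for s in collection:
            handle.write("\t".join([s.set_id, s.name, *s.genes]) + "\n")


def filter_genesets(
    collection: GeneSetCollection,
    min_size: int,
    max_size: int,
    universe: Sequence[str],
) -> GeneSetCollection:
    """Retain sets whose size *after intersection with the universe* lies in
    ``[min_size, max_size]`` (both inclusive).

    The retained sets keep their original gene lists; sizes are always
    measured post-intersection, which makes the filter idempotent.
    """
    if min_size > max_size:
        raise ValueError("min_size must be <= max_size")
    universe_set = frozenset(str(g) for g in universe)
    if not universe_set:
        raise ValueError("universe is empty")
    kept = [
        s for s in collection if min_size <= len(s.intersect(universe_set)) <= max_size
    ]
    return GeneSetCollection(kept, universe=sorted(universe_set))
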