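"""Reading, writing and aggregating MLPA-style genotype count tables.

The on-disk format is a tab-separated table: first column ``sample_id``, one
further column per counting-event symbol, integer cells.  This matches
exported MLPA spreadsheets and needs no quoting.  All-zero rows are legal —
a homozygous gene deletion genuinely yields a 0-copy genotype.
"""

from __future__ import annotations

import hashlib
import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph_model import GraphSpec

__all__ = [
    "GenotypeTable",
    "GenotypeMultiset",
    "GenotypeTableError",
    "read_genotypes",
    "write_genotypes",
    "aggregate",
]


class GenotypeTableError(ValueError):
    """A genotype table violates the format or the graph alphabet."""


@dataclass
class GenotypeTable:
    """Per-individual non-negative integer count vectors over an alphabet."""

    individuals: list[str]
    counts: np.ndarray  # shape (N, K) int
    alphabet: tuple[str, ...]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.individuals),
            len(self.alphabet),
        ):
            raise GenotypeTableError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.alphabet)} symbols"
            )
        if len(set(self.alphabet)) != len(self.alphabet):
            raise GenotypeTableError("alphabet symbols must be unique")
        if np.any(self.counts < 0):
            raise GenotypeTableError("counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.individuals)

    def fingerprint(self) -> str:
        """Order-insensitive digest of the observed genotype multiset.

        Identical to the fingerprint of ``aggregate(self)``, so evidence
        results computed from the table and from its multiset agree.
        """
        counts: dict[tuple[int, ...], int] = {}
        for row in self.counts:
            key = tuple(int(c) for c in row)
            counts[key] = counts.get(key, 0) + 1
        payload = repr((self.alphabet, sorted(counts.items()))).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class GenotypeMultiset:
    """Distinct genotype vectors with multiplicities (sum = N)."""

    alphabet: tuple[str, ...]
    counts: dict[tuple[int, ...], int]
    total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise GenotypeTableError("multiplicities must sum to the total N")

    def fingerprint(self) -> str:
        payload = repr((self.alphabet, sorted(self.counts.items()))).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_genotypes(stream, g: GraphSpec) -> GenotypeTable:
    """Read a TSV genotype table and align its columns to the graph alphabet.

    ``stream`` may be a path or an open text handle.  A column missing from
    the table, an extra column absent from the graph alphabet, or any
    non-integer/negative cell raises :class:`GenotypeTableError` naming the
    offending row and column.
    """
    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "rt", encoding="utf-8") as fh:
            return read_genotypes(fh, g)

    df = pd.read_csv(stream, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise GenotypeTableError(
            f"first column must be 'sample_id', found {df.columns[0]!r}"
        )
    cols = list(df.columns[1:])
    alphabet = list(g.alphabet)
    missing = [s for s in alphabet if s not in cols]
    extra = [c for c in cols if c not in alphabet]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing symbol columns {missing}")
        if extra:
            parts.append(f"columns not in the graph alphabet: {extra}")
        raise GenotypeTableError("; ".join(parts))

    individuals = df["sample_id"].astype(str).tolist()
    counts = np.zeros((len(individuals), len(alphabet)), dtype=np.int64)
    for j, sym in enumerate(alphabet):
        for i, raw in enumerate(df[sym].tolist()):
            text = str(raw).strip()
            try:
                value = int(text)
            except (TypeError, ValueError):
                raise GenotypeTableError(
                    f"row {individuals[i]!r}, column {sym!r}: "
                    f"{text!r} is not an integer count"
                ) from None
            if value < 0:
                raise GenotypeTableError(
                    f"row {individuals[i]!r}, column {sym!r}: negative count {value}"
                )
            counts[i, j] = value
    return GenotypeTable(individuals=individuals, counts=counts,
                         alphabet=tuple(alphabet))


def write_genotypes(table: GenotypeTable, stream=None) -> str | None:
    """Write a genotype table as TSV; returns the text when no stream given."""
    buf = io.StringIO()
    buf.write("sample_id\t" + "\t".join(table.alphabet) + "\n")
    for ind, row in zip(table.individuals, table.counts):
        buf.write(ind + "\t" + "\t".join(str(int(c)) for c in row) + "\n")
    text = buf.getvalue()
    if stream is None:
        return text
    if isinstance(stream, (str, os.PathLike)):
        with open(stream, "wt", encoding="utf-8") as fh:
            fh.write(text)
        return None
    stream.write(text)
    return None


def aggregate(table: GenotypeTable) -> GenotypeMultiset:
    """Collapse a table to its distinct genotypes with multiplicities.

    Distinct genotypes are ordered lexicographically, and the result is
    invariant under row permutation of the input.
    """
    if table.n == 0:
        raise GenotypeTableError("cannot aggregate an empty table")
    counts: dict[tuple[int, ...], int] = {}
    for row in table.counts:
        key = tuple(int(c) for c in row)
        counts[key] = counts.get(key, 0) + 1
    ordered = {k: counts[k] for k in sorted(counts)}
    return GenotypeMultiset(alphabet=table.alphabet, counts=ordered,
                            total=table.n)
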