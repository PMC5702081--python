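"""Guide-library reference parsing, exact-match counting and aggregation.

A reference library is a headered delimited file (CSV or TSV) with one row
per guide; the caller declares which column holds the guide sequence and
which columns hold identifiers (gene name, guide ID, chromosomal position).
Filtered guide tags are counted against the reference by exact, full-length,
case-insensitive sequence equality — no mismatch rescue — and counts can be
aggregated by any declared identifier column.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from guidescreen.fastq_filter import SequenceRead


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent guide reference files."""


@dataclass
class GuideReference:
    """Mapping from guide sequence to its identifiers.

    ``table`` is indexed by upper-cased guide sequence, with one column per
    declared identifier.  Duplicate guide sequences are rejected at
    construction.
    """

    table: pd.DataFrame  # index: guide sequence; columns: identifier columns
    sequence_column: str
    identifier_columns: tuple[str, ...]

    def __post_init__(self):
        duplicated = self.table.index[self.table.index.duplicated()].unique().tolist()
        if duplicated:
            raise ReferenceError(f"duplicate guide sequences in reference: {duplicated}")
        if (self.table.index == "").any():
            raise ReferenceError("empty guide sequence in reference")
        self.identifier_columns = tuple(self.identifier_columns)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def guides(self) -> list[str]:
        return self.table.index.tolist()

    def identifier(self, guide: str, column: str) -> str:
        return self.table.at[guide, column]

    def groups(self, by: str) -> pd.Series:
        """Series mapping guide sequence -> identifier value for column ``by``."""
        if by not in self.identifier_columns:
            raise ReferenceError(
                f"unknown identifier column {by!r}; declared: {list(self.identifier_columns)}"
            )
        return self.table[by]


def parse_reference(
    path: str | Path,
    sequence_column: str,
    identifier_columns: Sequence[str],
    delimiter: str = ",",
) -> GuideReference:
    """Parse a headered delimited guide-library file.

    Guide sequences are normalized to upper case.  Columns beyond the
    declared ones are ignored.  Missing declared columns and duplicate guide
    sequences raise :class:`ReferenceError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in [sequence_column, *identifier_columns]:
        if col not in df.columns:
            raise ReferenceError(
                f"declared column {col!r} not found in {path} (header: {list(df.columns)})"
            )
    table = df[list(identifier_columns)].copy()
    table.index = pd.Index(df[sequence_column].str.upper(), name=sequence_column)
    return GuideReference(table, sequence_column, tuple(identifier_columns))


@dataclass
class GuideCounts:
    """Per-library exact-match guide counts plus the unmapped remainder.

    Invariant: sum(counts.values()) + unmapped == number of filtered reads
    counted for this library.
    """

    counts: dict[str, int]
    unmapped: int = 0
    library_label: str = ""

    @property
    def total_mapped(self) -> int:
        return sum(self.counts.values())

    @property
    def total_reads(self) -> int:
        return self.total_mapped + self.unmapped

    def __add__(self, other: "GuideCounts") -> "GuideCounts":
        if set(self.counts) != set(other.counts):
            raise ValueError("cannot add counts over different guide sets")
        merged = {g: self.counts[g] + other.counts[g] for g in self.counts}
        return GuideCounts(merged, self.unmapped + other.unmapped,
                           f"{self.library_label}+{other.library_label}")


def count_guides(
    filtered: Iterable[SequenceRead | str],
    reference: GuideReference,
    library_label: str = "",
) -> GuideCounts:
    """Count exact full-sequence matches of filtered guide tags.

    Accepts SequenceRead objects or bare sequence strings.  Reads containing
    N (or any non-reference sequence) never match and land in ``unmapped``.
    Deterministic and permutation-invariant.
    """
    tally: Counter[str] = Counter()
    n_reads = 0
    for read in filtered:
        seq = read if isinstance(read, str) else read.sequence
        tally[seq.upper()] += 1
        n_reads += 1
    counts = {g: tally.get(g, 0) for g in reference.guides}
    return GuideCounts(counts, unmapped=n_reads - sum(counts.values()),
                       library_label=library_label)


def aggregate(
    counts: GuideCounts, reference: GuideReference, by: str
) -> dict[str, tuple[int, dict[str, int]]]:
    """Sum guide counts per identifier value of column ``by``.

    Returns ``{identifier: (total, {guide: count})}``; the totals sum to the
    mapped read total.
    """
    groups = reference.groups(by)
    out: dict[str, tuple[int, dict[str, int]]] = {}
    for guide, ident in groups.items():
        total, breakdown = out.get(ident, (0, {}))
        c = counts.counts[guide]
        breakdown[guide] = c
        out[ident] = (total + c, breakdown)
    return out


def composition_summary(
    aggregated: dict[str, tuple[int, dict[str, int]]], top_n: int
) -> pd.DataFrame:
    """Ranked table of the top identifiers by count with read fractions.

    Ranking is by count descending, ties broken lexicographically by
    identifier.  The remainder beyond ``top_n`` is lumped into an ``other``
    row, so fractions sum to 1 over the whole table (or to <1 excluding it).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    total = sum(t for t, _ in aggregated.values())
    ranked = sorted(aggregated.items(), key=lambda kv: (-kv[1][0], kv[0]))
    rows = [
        {"identifier": ident, "count": t, "fraction": (t / total if total else 0.0)}
        for ident, (t, _) in ranked[:top_n]
    ]
    rest = ranked[top_n:]
    if rest:
        other = sum(t for _, (t, _) in rest)
        rows.append({"identifier": "other", "count": other,
                     "fraction": other / total if total else 0.0})
    return pd.DataFrame(rows, columns=["identifier", "count", "fraction"])


def counts_to_frame(
    libraries: Sequence[GuideCounts], reference: GuideReference
) -> pd.DataFrame:
    """Wide table: one row per reference guide, identifier columns, one count
    column per library (named by library_label)."""
    df = reference.table.reset_index()
    for i, lib in enumerate(libraries):
        label = lib.library_label or f"library_{i + 1}"
        df[label] = [lib.counts[g] for g in reference.guides]
    return df


def export_counts(
    libraries: Sequence[GuideCounts],
    reference: GuideReference,
    path: str | Path,
) -> None:
    """Write per-guide counts for one or more libraries as delimited text.

    Columns: guide sequence, identifiers, one count column per library; a
    trailing summary row carries each library's unmapped-read count.
    """
    df = counts_to_frame(libraries, reference)
    summary = {c: "" for c in df.columns}
    summary[reference.sequence_column] = "__unmapped__"
    for i, lib in enumerate(libraries):
        summary[lib.library_label or f"library_{i + 1}"] = lib.unmapped
    df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    df.to_csv(path, index=False)


def load_counts_csv(
    path: str | Path, reference: GuideReference
) -> list[GuideCounts]:
    """Re-read a counts CSV written by :func:`export_counts`."""
    df = pd.read_csv(path, dtype={0: str}, keep_default_na=False)
    seq_col = reference.sequence_column
    mask = df[seq_col] == "__unmapped__"
    body = df[~mask].set_index(seq_col)
    tail = df[mask]
    count_cols = [c for c in df.columns if c not in (seq_col, *reference.identifier_columns)]
    out = []
    for col in count_cols:
        counts = {g: int(body.at[g, col]) for g in reference.guides}
        unmapped = int(tail[col].iloc[0]) if len(tail) else 0
        out.append(GuideCounts(counts, unmapped=unmapped, library_label=col))
    return out
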