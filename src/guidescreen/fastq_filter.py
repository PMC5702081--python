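"""Streaming FASTQ filter pipeline.

Reads from a pooled CRISPR screen carry the guide sequence embedded in a
longer amplicon: ``[prefix][anchor][guide][suffix]``.  The anchor is a fixed
vector-derived string (by default ``GAAACACCG``, the U6-promoter/scaffold
junction) that immediately precedes the variable guide.  This module streams
FASTQ records through an ordered pipeline of filter steps — crop, head/tail
cut, replace, anchor search-and-trim, mean-quality filter, length filter,
barcode demultiplexing — producing a filtered FASTQ of fixed-length guide
tags ready for exact-match counting.

All processing is single-pass and memory-bounded: records are never buffered
whole-file, and output order equals input order.  There is no randomness
anywhere in this module.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_ANCHOR = "GAAACACCG"
DEFAULT_GUIDE_LENGTH = 19

WORKFLOW_FORMAT_VERSION = "1"


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records; the message names the record index."""


class WorkflowError(ValueError):
    """Raised for invalid filter-step parameters or workflow configuration."""


@dataclass(slots=True)
class SequenceRead:
    """One FASTQ record: identifier, nucleotide string, per-base qualities.

    The sequence is upper-cased on input; the quality string always has the
    same length as the sequence.
    """

    read_id: str
    sequence: str
    quality: str

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    raw = open(path, "rb")
    head = raw.read(2)
    raw.seek(0)
    if head == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream records from a plain or gzip-compressed 4-line FASTQ file.

    Yields records in file order with sequences upper-cased.  A malformed
    record (sequence/quality length mismatch, missing ``+`` separator,
    truncated file) raises :class:`FastqFormatError` naming the record index.
    """
    index = 0
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record at index {index} in {path}: {exc}"
                ) from exc
            yield SequenceRead(title.split(None, 1)[0], seq.upper(), qual)
            index += 1


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads to a 4-line FASTQ file (gzip if the path ends in .gz).

    Returns the number of records written.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as out:
        for read in reads:
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# individual filter operations (pure; return the new read or None = discard)
# ---------------------------------------------------------------------------

def anchor_search_trim(
    read: SequenceRead,
    anchor: str = DEFAULT_ANCHOR,
    keep_length: int = DEFAULT_GUIDE_LENGTH,
) -> SequenceRead | None:
    """Extract the ``keep_length`` bases immediately after the anchor.

    The first occurrence of the anchor (exact, case-insensitive match) is
    used.  If the anchor is absent, or fewer than ``keep_length`` bases
    follow it, the read is discarded (returns None).
    """
    pos = read.sequence.find(anchor)
    if pos < 0:
        return None
    start = pos + len(anchor)
    end = start + keep_length
    if end > len(read.sequence):
        return None
    return SequenceRead(read.read_id, read.sequence[start:end], read.quality[start:end])


def crop(read: SequenceRead, length: int) -> SequenceRead | None:
    """Keep the first ``length`` bases; a read cropped to length 0 is discarded."""
    if length == 0:
        return None
    return SequenceRead(read.read_id, read.sequence[:length], read.quality[:length])


def head_cut(read: SequenceRead, n: int) -> SequenceRead | None:
    """Remove ``n`` bases from the 5' end; empty results are discarded."""
    if n >= len(read.sequence):
        return None
    return SequenceRead(read.read_id, read.sequence[n:], read.quality[n:])


def tail_cut(read: SequenceRead, n: int) -> SequenceRead | None:
    """Remove ``n`` bases from the 3' end; empty results are discarded."""
    if n >= len(read.sequence):
        return None
    if n == 0:
        return read
    return SequenceRead(read.read_id, read.sequence[:-n], read.quality[:-n])


def replace(read: SequenceRead, pattern: str, replacement: str) -> SequenceRead | None:
    """Substitute all non-overlapping occurrences of ``pattern`` (left to right).

    Quality strings stay aligned with the sequence: the replaced span's
    qualities are kept position-wise (truncated if the replacement is
    shorter); positions beyond the original span — inserted bases — receive
    the maximum quality of the neighbouring original bases.  Reads shortened
    to length 0 are discarded.
    """
    pattern = pattern.upper()
    replacement = replacement.upper()
    seq_parts: list[str] = []
    qual_parts: list[str] = []
    i = 0
    seq, qual = read.sequence, read.quality
    while True:
        j = seq.find(pattern, i)
        if j < 0:
            seq_parts.append(seq[i:])
            qual_parts.append(qual[i:])
            break
        seq_parts.append(seq[i:j])
        qual_parts.append(qual[i:j])
        span_qual = qual[j : j + len(pattern)]
        if len(replacement) <= len(pattern):
            qual_parts.append(span_qual[: len(replacement)])
        else:
            left = qual[j - 1] if j > 0 else ""
            right = qual[j + len(pattern)] if j + len(pattern) < len(qual) else ""
            neighbours = span_qual + left + right
            fill = max(neighbours)  # highest Phred among span + flanks
            qual_parts.append(span_qual + fill * (len(replacement) - len(pattern)))
        seq_parts.append(replacement)
        i = j + len(pattern)
    new_seq = "".join(seq_parts)
    if not new_seq:
        return None
    return SequenceRead(read.read_id, new_seq, "".join(qual_parts))


def mean_quality(read: SequenceRead, offset: int = 33) -> float:
    """Arithmetic mean of per-base Phred scores under the given encoding offset."""
    scores = [ord(c) - offset for c in read.quality]
    if any(s < 0 for s in scores):
        raise FastqFormatError(
            f"quality character below Phred offset {offset} in read {read.read_id!r}"
        )
    if not scores:
        return 0.0
    return sum(scores) / len(scores)


def quality_filter(
    read: SequenceRead, min_mean_quality: float, offset: int = 33
) -> SequenceRead | None:
    """Keep the read iff its mean Phred quality is >= the threshold."""
    return read if mean_quality(read, offset) >= min_mean_quality else None


def length_filter(
    read: SequenceRead, min_length: int = 0, max_length: int | None = None
) -> SequenceRead | None:
    """Keep the read iff min_length <= len <= max_length."""
    n = len(read.sequence)
    if n < min_length:
        return None
    if max_length is not None and n > max_length:
        return None
    return read


def _validate_barcode_map(barcode_map: dict) -> dict[str, str]:
    if not isinstance(barcode_map, dict) or not barcode_map:
        raise WorkflowError("barcode_map must be a non-empty barcode->label mapping")
    normalized: dict[str, str] = {}
    for barcode, label in barcode_map.items():
        bc = str(barcode).upper()
        if bc in normalized:
            raise WorkflowError(f"duplicate barcode {bc!r} in barcode_map")
        normalized[bc] = str(label)
    lengths = {len(bc) for bc in normalized}
    if len(lengths) != 1:
        raise WorkflowError("barcodes must all have the same length")
    return normalized


def demultiplex(
    reads: Iterable[SequenceRead], barcode_map: dict[str, str]
) -> Iterator[tuple[str | None, SequenceRead]]:
    """Assign each read to the sample whose barcode exactly matches its prefix.

    Yields ``(label, read)`` pairs in input order, with the barcode stripped
    from assigned reads; reads matching no barcode are yielded with label
    ``None`` (the unassigned stream), unmodified.  The sum of output counts
    equals the input count by construction.
    """
    bmap = _validate_barcode_map(barcode_map)
    width = len(next(iter(bmap)))
    for read in reads:
        label = bmap.get(read.sequence[:width])
        if label is None:
            yield None, read
        else:
            yield label, SequenceRead(read.read_id, read.sequence[width:], read.quality[width:])


def split_by_barcode(
    reads: Iterable[SequenceRead], barcode_map: dict[str, str]
) -> tuple[dict[str, list[SequenceRead]], list[SequenceRead]]:
    """In-memory convenience wrapper around :func:`demultiplex`."""
    per_label: dict[str, list[SequenceRead]] = {label: [] for label in barcode_map.values()}
    unassigned: list[SequenceRead] = []
    for label, read in demultiplex(reads, barcode_map):
        if label is None:
            unassigned.append(read)
        else:
            per_label[label].append(read)
    return per_label, unassigned


# ---------------------------------------------------------------------------
# filter steps and workflows
# ---------------------------------------------------------------------------

def _require_nonneg_int(value, name: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool) or value < 0:
        raise WorkflowError(f"parameter {name!r} must be a non-negative integer, got {value!r}")
    return value


def _require_pos_int(value, name: str) -> int:
    if not isinstance(value, int) or isinstance(value, bool) or value < 1:
        raise WorkflowError(f"parameter {name!r} must be a positive integer, got {value!r}")
    return value


def _validate_crop(p):
    return {"length": _require_nonneg_int(p["length"], "length")}


def _validate_cut(p):
    return {"n": _require_nonneg_int(p["n"], "n")}


def _validate_replace(p):
    if not p["pattern"]:
        raise WorkflowError("replace pattern must be non-empty")
    return {"pattern": str(p["pattern"]).upper(), "replacement": str(p["replacement"]).upper()}


def _validate_anchor(p):
    if not p["anchor"]:
        raise WorkflowError("anchor must be non-empty")
    return {
        "anchor": str(p["anchor"]).upper(),
        "keep_length": _require_pos_int(p["keep_length"], "keep_length"),
    }


def _validate_quality(p):
    q = p["min_mean_quality"]
    if not isinstance(q, (int, float)) or q < 0:
        raise WorkflowError(f"min_mean_quality must be a non-negative number, got {q!r}")
    offset = p.get("offset", 33)
    if offset not in (33, 64):
        raise WorkflowError(f"Phred offset must be 33 or 64, got {offset!r}")
    return {"min_mean_quality": float(q), "offset": offset}


def _validate_length(p):
    out = {"min_length": _require_nonneg_int(p.get("min_length", 0), "min_length")}
    if p.get("max_length") is not None:
        out["max_length"] = _require_nonneg_int(p["max_length"], "max_length")
    return out


def _validate_demux(p):
    bmap = _validate_barcode_map(p["barcode_map"])
    keep = str(p["keep_label"])
    if keep not in bmap.values():
        raise WorkflowError(f"keep_label {keep!r} is not a label in barcode_map")
    return {"barcode_map": bmap, "keep_label": keep}


_STEP_SPECS: dict[str, tuple[set[str], set[str], callable]] = {
    # kind: (required params, optional params, validator)
    "crop": ({"length"}, set(), _validate_crop),
    "head_cut": ({"n"}, set(), _validate_cut),
    "tail_cut": ({"n"}, set(), _validate_cut),
    "replace": ({"pattern", "replacement"}, set(), _validate_replace),
    "anchor_search": ({"anchor", "keep_length"}, set(), _validate_anchor),
    "quality_filter": ({"min_mean_quality"}, {"offset"}, _validate_quality),
    "length_filter": (set(), {"min_length", "max_length"}, _validate_length),
    "demultiplex": ({"barcode_map", "keep_label"}, set(), _validate_demux),
}


@dataclass(frozen=True)
class FilterStep:
    """A single validated filter step: a kind plus its parameters.

    Unknown kinds and unknown or missing parameter keys are rejected at
    construction.
    """

    kind: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _STEP_SPECS:
            raise WorkflowError(
                f"unknown filter step kind {self.kind!r}; known: {sorted(_STEP_SPECS)}"
            )
        required, optional, validator = _STEP_SPECS[self.kind]
        keys = set(self.parameters)
        missing = required - keys
        if missing:
            raise WorkflowError(f"step {self.kind!r} missing parameters: {sorted(missing)}")
        unknown = keys - required - optional
        if unknown:
            raise WorkflowError(f"step {self.kind!r} has unknown parameters: {sorted(unknown)}")
        object.__setattr__(self, "parameters", validator(self.parameters))

    def apply(self, read: SequenceRead) -> SequenceRead | None:
        p = self.parameters
        if self.kind == "crop":
            return crop(read, p["length"])
        if self.kind == "head_cut":
            return head_cut(read, p["n"])
        if self.kind == "tail_cut":
            return tail_cut(read, p["n"])
        if self.kind == "replace":
            return replace(read, p["pattern"], p["replacement"])
        if self.kind == "anchor_search":
            return anchor_search_trim(read, p["anchor"], p["keep_length"])
        if self.kind == "quality_filter":
            return quality_filter(read, p["min_mean_quality"], p["offset"])
        if self.kind == "length_filter":
            return length_filter(read, p["min_length"], p.get("max_length"))
        if self.kind == "demultiplex":
            width = len(next(iter(p["barcode_map"])))
            label = p["barcode_map"].get(read.sequence[:width])
            if label != p["keep_label"]:
                return None
            return SequenceRead(read.read_id, read.sequence[width:], read.quality[width:])
        raise AssertionError(self.kind)


@dataclass
class FilterWorkflow:
    """An ordered list of filter steps, serializable to versioned YAML.

    Steps are applied in exactly the declared order; an exported workflow,
    re-imported, applies identically to any input.
    """

    steps: list[FilterStep] = field(default_factory=list)
    version: str = WORKFLOW_FORMAT_VERSION

    def apply_read(self, read: SequenceRead) -> tuple[SequenceRead | None, int]:
        """Apply all steps in order; returns (result, index of discarding step or -1)."""
        for i, step in enumerate(self.steps):
            read = step.apply(read)
            if read is None:
                return None, i
        return read, -1

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "steps": [{"kind": s.kind, "parameters": dict(s.parameters)} for s in self.steps],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FilterWorkflow":
        unknown = set(data) - {"version", "steps"}
        if unknown:
            raise WorkflowError(f"unknown workflow keys: {sorted(unknown)}")
        steps = [FilterStep(d["kind"], dict(d.get("parameters", {}))) for d in data.get("steps", [])]
        return cls(steps=steps, version=str(data.get("version", WORKFLOW_FORMAT_VERSION)))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(self.to_dict(), out, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "FilterWorkflow":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        if not isinstance(data, dict):
            raise WorkflowError(f"workflow file {path} does not contain a mapping")
        return cls.from_dict(data)


def guide_extraction_workflow(
    anchor: str = DEFAULT_ANCHOR, keep_length: int = DEFAULT_GUIDE_LENGTH
) -> FilterWorkflow:
    """The default screen workflow: a single anchor search-and-trim step."""
    return FilterWorkflow(
        steps=[FilterStep("anchor_search", {"anchor": anchor, "keep_length": keep_length})]
    )


@dataclass
class StepReport:
    kind: str
    n_in: int = 0
    n_kept: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class FilterReport:
    """Per-step kept/discarded tallies for one workflow run.

    Conservation holds at every step: kept + discarded = input, and the kept
    count of step k is the input count of step k+1.
    """

    steps: list[StepReport]
    n_input: int = 0
    n_output: int = 0

    @property
    def n_discarded(self) -> int:
        return self.n_input - self.n_output

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write("step,kind,input,kept,discarded\n")
            for i, s in enumerate(self.steps, start=1):
                out.write(f"{i},{s.kind},{s.n_in},{s.n_kept},{s.n_discarded}\n")
            out.write(f"total,workflow,{self.n_input},{self.n_output},{self.n_discarded}\n")


def filter_reads(
    reads: Iterable[SequenceRead], workflow: FilterWorkflow, report: FilterReport | None = None
) -> Iterator[SequenceRead]:
    """Stream reads through the workflow, yielding survivors in input order."""
    for read in reads:
        if report is not None:
            report.n_input += 1
        kept = True
        for i, step in enumerate(workflow.steps):
            if report is not None:
                report.steps[i].n_in += 1
            read = step.apply(read)
            if read is None:
                kept = False
                break
            if report is not None:
                report.steps[i].n_kept += 1
        if kept:
            if report is not None:
                report.n_output += 1
            yield read


def new_report(workflow: FilterWorkflow) -> FilterReport:
    return FilterReport(steps=[StepReport(kind=s.kind) for s in workflow.steps])


def run_workflow(
    input_path: str | Path, workflow: FilterWorkflow, output_path: str | Path
) -> FilterReport:
    """Apply the workflow to a FASTQ file and write the filtered FASTQ.

    Deterministic: identical input and workflow give byte-identical output.
    Returns the per-step :class:`FilterReport`.
    """
    report = new_report(workflow)
    write_fastq(filter_reads(read_fastq(input_path), workflow, report), output_path)
    return report


def preview(input_path: str | Path, workflow: FilterWorkflow, n: int = 10) -> list[dict]:
    """Intermediate sequences of the first ``n`` reads at every workflow step.

    Returns one dict per read with keys ``read_id``, ``raw``, and
    ``after <k>:<kind>`` for each step (None once discarded).  No output is
    written; results match what :func:`run_workflow` would produce.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rows: list[dict] = []
    for read in read_fastq(input_path):
        row: dict = {"read_id": read.read_id, "raw": read.sequence}
        current: SequenceRead | None = read
        for i, step in enumerate(workflow.steps, start=1):
            current = step.apply(current) if current is not None else None
            row[f"after {i}:{step.kind}"] = None if current is None else current.sequence
        rows.append(row)
        if len(rows) >= n:
            break
    return rows
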