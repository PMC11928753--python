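"""Sequence input/output and fixed-length segmentation.

Training and prediction both operate on short windows cut from longer
nucleotide records: encoders are trained on 500-bp segments, and query
contigs are scored by averaging over their 500-bp segments. This module
holds the record/segment containers and the windowing rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

#: The two biological classes the framework distinguishes.
CLASSES = ("bacteria", "phage")

#: Default segment length in bases.
DEFAULT_SEGMENT_LENGTH = 500

#: Shortest trailing remainder kept as its own segment.
DEFAULT_MIN_TAIL = 100


@dataclass(frozen=True)
class SequenceRecord:
    """A nucleotide sequence with an identifier and optional class label."""

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.label is not None and self.label not in CLASSES:
            raise ValueError(
                f"record {self.id!r}: label must be one of {CLASSES}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """A contiguous window of a parent record (0-based, half-open)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"segment {self.parent_id}[{self.start}:{self.end}]: "
                f"coordinates span {self.end - self.start} bases but sequence "
                f"has {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path, label: Optional[str] = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    path
        FASTA file (multi-line records allowed).
    label
        Optional class applied uniformly to every record, e.g. when reading
        a file that holds one training class.

    Sequences are uppercased on read; IUPAC ambiguity codes are retained and
    dealt with at tokenization. Duplicate ids raise a ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_header(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(
            SequenceRecord(id=entry.id, sequence=str(entry.seq).upper(), label=label)
        )
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def _check_fasta_header(path: Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA at line {lineno}: expected '>' header, "
                    f"got {line.strip()[:40]!r}"
                )
            return


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    path = Path(path)
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def segment_sequence(
    record: SequenceRecord,
    seg_len: int = DEFAULT_SEGMENT_LENGTH,
    min_tail: int = DEFAULT_MIN_TAIL,
) -> list[Segment]:
    """Cut a record into consecutive non-overlapping ``seg_len``-base windows.

    Windows start at position 0. A final remainder shorter than ``seg_len``
    is kept as its own (variable-length) segment iff it is at least
    ``min_tail`` bases, otherwise discarded. Segments inherit the record's
    label. A record shorter than ``min_tail`` yields an empty list with a
    warning.
    """
    if seg_len <= 0 or min_tail <= 0:
        raise ValueError("seg_len and min_tail must be positive")
    if min_tail > seg_len:
        raise ValueError("min_tail must not exceed seg_len")
    n = len(record)
    if n < min_tail:
        warnings.warn(
            f"record {record.id!r} is {n} bp, shorter than min_tail={min_tail}; "
            "no segments produced",
            stacklevel=2,
        )
        return []
    segments: list[Segment] = []
    for start in range(0, n, seg_len):
        end = min(start + seg_len, n)
        if end - start < seg_len and end - start < min_tail:
            break
        segments.append(
            Segment(
                parent_id=record.id,
                start=start,
                end=end,
                sequence=record.sequence[start:end],
                label=record.label,
            )
        )
    return segments


def segment_records(
    records: Iterable[SequenceRecord],
    seg_len: int = DEFAULT_SEGMENT_LENGTH,
    min_tail: int = DEFAULT_MIN_TAIL,
) -> list[Segment]:
    """Segment every record, concatenating results in input order."""
    out: list[Segment] = []
    for rec in records:
        out.extend(segment_sequence(rec, seg_len=seg_len, min_tail=min_tail))
    return out


def segments_to_bed(segments: Sequence[Segment], path) -> None:
    """Emit segment provenance as BED3+1 (parent, start, end, label) for debugging."""
    with open(path, "w") as handle:
        for seg in segments:
            label = seg.label if seg.label is not None else "."
            handle.write(f"{seg.parent_id}\t{seg.start}\t{seg.end}\t{label}\n")
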