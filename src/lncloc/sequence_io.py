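"""Reading, validating and filtering lncRNA sequence data.

Sequences arrive as FASTA; compartment labels arrive as a headerless
two-column TSV (sequence ID, compartment name).  FASTA descriptions are
deliberately not parsed for labels.  Records are normalized to uppercase on
read; both U and T spellings are accepted and preserved (canonicalization
U->T happens at featurization time, see :mod:`lncloc.features`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "FilterPolicy",
    "RemovedRecord",
    "SequenceParseError",
    "LabelTableError",
    "read_fasta",
    "read_labels",
    "attach_labels",
    "filter_records",
    "write_removal_report",
    "write_fasta",
    "write_labels",
]

#: Unambiguous nucleotide alphabet (DNA and RNA spellings).
CANONICAL_ALPHABET = frozenset("ACGTU")

#: Full IUPAC nucleotide alphabet accepted on input; ambiguity codes beyond
#: the canonical five are legal FASTA content but are typically filtered out
#: downstream by a :class:`FilterPolicy`.
IUPAC_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


class SequenceParseError(ValueError):
    """Raised for malformed FASTA input; names the offending entry."""


class LabelTableError(ValueError):
    """Raised for malformed or inconsistent label tables."""


@dataclass(frozen=True)
class SequenceRecord:
    """One lncRNA: identifier, nucleotide string, optional compartment label.

    ``provenance`` distinguishes samples read from data ("real") from
    SMOTE-interpolated ones ("synthetic"); anything read from a file is real.
    """

    id: str
    sequence: str
    label: str | None = None
    provenance: str = "real"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceParseError(f"record {self.id!r}: empty sequence")
        if self.provenance not in ("real", "synthetic"):
            raise ValueError(f"record {self.id!r}: bad provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterPolicy:
    """Which records to drop before featurization.

    A record is removed iff its sequence contains a forbidden symbol or
    exceeds ``max_length`` (``None`` = unbounded).  The default forbidden set
    {N, R, S, Y} matches the ambiguity codes most often seen in curated
    lncRNA sets; the forbidden set must not intersect the canonical alphabet.
    """

    forbidden_symbols: frozenset[str] = frozenset("NRSY")
    max_length: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.forbidden_symbols) & CANONICAL_ALPHABET
        if overlap:
            raise ValueError(
                f"forbidden_symbols may not contain canonical bases: {sorted(overlap)}"
            )
        if self.max_length is not None and self.max_length <= 0:
            raise ValueError("max_length must be positive or None")

    def removal_reason(self, record: SequenceRecord) -> str | None:
        """Reason this record would be removed, or None if it is kept."""
        hit = set(record.sequence) & set(self.forbidden_symbols)
        if hit:
            return f"forbidden symbol {','.join(sorted(hit))}"
        if self.max_length is not None and len(record) > self.max_length:
            return f"length {len(record)} exceeds max_length {self.max_length}"
        return None


@dataclass(frozen=True)
class RemovedRecord:
    record: SequenceRecord
    reason: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into ordered :class:`SequenceRecord` objects.

    Sequences are uppercased; U and T are both accepted.  An entry with no
    sequence line or with characters outside the IUPAC nucleotide alphabet
    raises :class:`SequenceParseError` naming the entry.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise SequenceParseError(f"FASTA entry {entry.id!r} has no sequence")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise SequenceParseError(
                f"FASTA entry {entry.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        records.append(SequenceRecord(id=entry.id, sequence=seq, provenance="real"))
    return records


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a headerless two-column TSV mapping sequence ID -> compartment.

    Duplicate IDs and rows without exactly two columns are rejected.
    """
    mapping: dict[str, str] = {}
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != 2:
                raise LabelTableError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(row)}"
                )
            seq_id, label = row[0].strip(), row[1].strip()
            if not seq_id or not label:
                raise LabelTableError(f"{path}: line {lineno}: empty field")
            if seq_id in mapping:
                raise LabelTableError(f"{path}: duplicate ID {seq_id!r}")
            mapping[seq_id] = label
    return mapping


def attach_labels(
    records: Sequence[SequenceRecord], labels: Mapping[str, str]
) -> list[SequenceRecord]:
    """Return records with labels filled in from the mapping.

    Every record must have an entry in the mapping; a missing ID raises
    :class:`LabelTableError`.
    """
    out = []
    for rec in records:
        if rec.id not in labels:
            raise LabelTableError(f"no label for sequence {rec.id!r}")
        out.append(replace(rec, label=labels[rec.id]))
    return out


def filter_records(
    records: Iterable[SequenceRecord], policy: FilterPolicy = FilterPolicy()
) -> tuple[list[SequenceRecord], list[RemovedRecord]]:
    """Partition records into (kept, removed-with-reason) under a policy.

    Both outputs preserve input order and together account for every input
    record exactly once.
    """
    kept: list[SequenceRecord] = []
    removed: list[RemovedRecord] = []
    for rec in records:
        reason = policy.removal_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            removed.append(RemovedRecord(rec, reason))
    return kept, removed


def write_removal_report(removed: Sequence[RemovedRecord], path: str | Path) -> None:
    """Write the removed records as a two-column TSV (id, reason)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        for item in removed:
            writer.writerow([item.record.id, item.reason])


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                handle.write(rec.sequence[i : i + 70] + "\n")


def write_labels(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        for rec in records:
            if rec.label is None:
                raise LabelTableError(f"record {rec.id!r} has no label to write")
            writer.writerow([rec.id, rec.label])
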