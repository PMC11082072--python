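"""Peptide records and dataset I/O.

Peptides live on a 21-letter alphabet: the 20 standard amino acids plus
``X`` for an unspecified residue. Every sequence entering the package is
canonicalized here, so downstream modules (tokenization, alignment,
simulation) may assume the alphabet invariant.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Full alphabet including the unknown residue, in sorted order.
ALPHABET = "".join(sorted(STANDARD_AA + "X"))
_ALPHABET_SET = frozenset(ALPHABET)
_STANDARD_SET = frozenset(STANDARD_AA)
#: Symbols silently removed before residue mapping (gaps, stops, whitespace).
_STRIP_CHARS = "-*. \t\r\n"


class ValidationError(ValueError):
    """A record or value violated a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; message carries location context."""


def canonicalize_sequence(raw: str, record_name: str = "<sequence>") -> str:
    """Return the canonical form of a raw peptide string.

    Uppercases, strips gap/stop/whitespace symbols, and maps any symbol
    that is not one of the 20 standard residues to ``'X'``.

    Raises
    ------
    ValidationError
        If the sequence is empty after stripping.
    """
    cleaned = raw.upper()
    for ch in _STRIP_CHARS:
        cleaned = cleaned.replace(ch, "")
    if not cleaned:
        raise ValidationError(f"empty sequence for record {record_name!r}")
    return "".join(c if c in _STANDARD_SET else "X" for c in cleaned)


@dataclass(frozen=True)
class PeptideRecord:
    """One labeled (or unlabeled) peptide sequence.

    label is 1 for an anticancer peptide (ACP), 0 for a non-ACP, or None
    when unknown (e.g. plain FASTA input).
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _ALPHABET_SET
        if bad:
            raise ValidationError(
                f"record {self.id!r} has non-canonical characters {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"record {self.id!r} has label {self.label!r}, expected 0 or 1"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """An ordered collection of peptide records with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)
    split_tag: str = "unsplit"

    _VALID_TAGS = ("train", "validation", "test", "unsplit")

    def __post_init__(self) -> None:
        if self.split_tag not in self._VALID_TAGS:
            raise ValidationError(
                f"split_tag {self.split_tag!r} not in {self._VALID_TAGS}"
            )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[Optional[int]]:
        return [r.label for r in self.records]

    def labeled(self) -> bool:
        return all(r.label is not None for r in self.records)

    def subset(self, indices: Sequence[int], split_tag: Optional[str] = None) -> "PeptideDataset":
        tag = split_tag if split_tag is not None else self.split_tag
        return PeptideDataset([self.records[i] for i in indices], split_tag=tag)

    def truncated(self, max_residues: int) -> "PeptideDataset":
        """Truncate over-long sequences (logged), keeping every record."""
        out = []
        n_trunc = 0
        for r in self.records:
            if len(r.sequence) > max_residues:
                out.append(replace(r, sequence=r.sequence[:max_residues]))
                n_trunc += 1
            else:
                out.append(r)
        if n_trunc:
            logger.warning(
                "truncated %d/%d sequences to %d residues",
                n_trunc, len(self.records), max_residues,
            )
        return PeptideDataset(out, split_tag=self.split_tag)


def read_fasta(path: str | Path) -> PeptideDataset:
    """Read a FASTA file into an unlabeled dataset.

    Multi-line sequence entries are concatenated; sequences are
    canonicalized. Duplicate header ids raise a :class:`ParseError`.
    """
    path = Path(path)
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ParseError(f"{path}: FASTA entry with empty header id")
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        try:
            seq = canonicalize_sequence(str(entry.seq), record_name=entry.id)
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        records.append(PeptideRecord(id=entry.id, sequence=seq))
    return PeptideDataset(records)


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in dataset:
            fh.write(f">{r.id}\n{r.sequence}\n")


def read_dataset_csv(path: str | Path) -> PeptideDataset:
    """Read a labeled dataset from CSV with columns ``sequence,label``.

    An ``id`` column is optional; missing ids are auto-assigned ``seq{i}``.
    Labels must parse as 0 or 1.
    """
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sequence" not in reader.fieldnames:
            raise ParseError(f"{path}: missing header row with a 'sequence' column")
        has_label = "label" in reader.fieldnames
        has_id = "id" in reader.fieldnames
        for i, row in enumerate(reader):
            rid = row["id"] if has_id and row.get("id") else f"seq{i}"
            label: Optional[int] = None
            if has_label and row.get("label") not in (None, ""):
                raw = row["label"].strip()
                if raw not in ("0", "1"):
                    raise ParseError(
                        f"{path}: row {i + 2}: label {raw!r} not in {{0,1}}"
                    )
                label = int(raw)
            try:
                seq = canonicalize_sequence(row["sequence"], record_name=rid)
            except ValidationError as exc:
                raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
            records.append(PeptideRecord(id=rid, sequence=seq, label=label))
    return PeptideDataset(records)


def write_dataset_csv(dataset: PeptideDataset, path: str | Path) -> None:
    """Write a dataset as ``id,sequence,label`` CSV (label blank if absent)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "label"])
        for r in dataset:
            writer.writerow([r.id, r.sequence, "" if r.label is None else r.label])


def _format_float(x: float) -> str:
    return f"{float(x):.6g}"


def write_report(report, path: str | Path) -> None:
    """Serialize a report object to CSV with a deterministic field order.

    Dispatches on a ``report_fields()`` method returning an ordered
    mapping of column name to value; floats are written at 6 significant
    digits. Works for metrics reports, redundancy reports, and any other
    object implementing the protocol.
    """
    fields = report.report_fields()
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(fields))
        writer.writerow(
            [_format_float(v) if isinstance(v, float) else v for v in fields.values()]
        )


def read_report_csv(path: str | Path) -> dict[str, float]:
    """Read back a single-row report CSV as a name→value mapping."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if len(rows) != 2:
        raise ParseError(f"{path}: expected header + one data row, got {len(rows)} rows")
    return {k: float(v) for k, v in zip(rows[0], rows[1])}
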