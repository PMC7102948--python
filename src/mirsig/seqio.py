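"""Sequence and tabular I/O with miRBase-style identifier parsing.

All sequences are held internally in the RNA alphabet {A, C, G, U};
DNA-alphabet input (T) is converted on read. Coordinates are 1-based and
inclusive everywhere in the public interface.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_RNA_TRANSLATION = str.maketrans({"T": "U", "t": "U"})


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, U/T}."""


def normalize_rna(sequence: str, record_id: str = "") -> str:
    """Upper-case a sequence and map T to U; reject anything else.

    Ambiguity codes (N, R, Y, ...) are rejected rather than skipped because
    positional composition statistics would be silently biased by them.
    """
    norm = sequence.strip().upper().translate(_RNA_TRANSLATION)
    bad = set(norm) - RNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(
            f"sequence {record_id!r} contains characters outside A/C/G/U/T: "
            f"{sorted(bad)}"
        )
    return norm


@dataclass
class SeqRecord:
    """A normalized RNA sequence with an identifier and optional species code."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, self.id)
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MirnaRecord(SeqRecord):
    """A mature miRNA with parsed family and arm annotation."""

    family: str = ""
    arm: str = "unknown"  # one of {"5p", "3p", "unknown"}
    precursor_id: str = ""


@dataclass
class PrecursorRecord(SeqRecord):
    """A miRNA precursor (stem-loop) with optional mature-arm spans.

    Spans are 1-based inclusive ``(start, end)`` tuples; when both are
    present the 5p arm must precede the 3p arm.
    """

    mature5p_span: Optional[tuple[int, int]] = None
    mature3p_span: Optional[tuple[int, int]] = None
    family: str = ""

    def __post_init__(self) -> None:
        super().__post_init__()
        for name, span in (("mature5p_span", self.mature5p_span),
                           ("mature3p_span", self.mature3p_span)):
            if span is not None:
                start, end = span
                if not (1 <= start <= end <= self.length):
                    raise ValueError(
                        f"{name}={span} outside [1, {self.length}] for {self.id!r}"
                    )
        if self.mature5p_span is not None and self.mature3p_span is not None:
            if self.mature5p_span[1] >= self.mature3p_span[0]:
                raise ValueError(
                    f"mature arms overlap or are out of order for {self.id!r}: "
                    f"5p={self.mature5p_span}, 3p={self.mature3p_span}"
                )

    def subsequence(self, span: tuple[int, int]) -> str:
        start, end = span
        return self.sequence[start - 1:end]


@dataclass
class ReadRecord:
    """A collapsed small-RNA read: unique sequence, count and RPM."""

    sequence: str
    count: int
    rpm: float = 0.0

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, "read")
        if self.count < 1:
            raise ValueError(f"read count must be >= 1, got {self.count}")
        if self.rpm < 0:
            raise ValueError("rpm must be non-negative")

    @property
    def length(self) -> int:
        return len(self.sequence)


# --------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into normalized :class:`SeqRecord` objects.

    Duplicate ids are retained (miRBase mature entries legitimately repeat
    across precursors) but logged. A header with no sequence raises
    :class:`FastaParseError`.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"record {rec.id!r} has a header but no sequence")
        if rec.id in seen:
            log.warning("duplicate FASTA id %r retained", rec.id)
        seen.add(rec.id)
        species, _, _ = parse_mirna_id(rec.id)
        records.append(SeqRecord(id=rec.id, sequence=str(rec.seq), species=species))
    return records


def read_mirna_fasta(path: str | Path) -> list[MirnaRecord]:
    """Read mature miRNAs, parsing species/family/arm from each identifier."""
    out: list[MirnaRecord] = []
    for rec in read_fasta(path):
        species, family, arm = parse_mirna_id(rec.id)
        if not family:
            log.warning("id %r does not match the miR-number pattern; "
                        "family left empty", rec.id)
        out.append(MirnaRecord(id=rec.id, sequence=rec.sequence,
                               species=species, family=family, arm=arm))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                line_width: int = 60) -> None:
    bio = [
        _BioSeqRecord(_BioSeq(r.sequence), id=r.id, description="")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = _BioSeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(bio)


# --------------------------------------------------------------------------
# Identifier parsing

_MIR_PATTERN = re.compile(r"mir-?0*(\d+)", re.IGNORECASE)


def parse_mirna_id(identifier: str) -> tuple[str, str, str]:
    """Split a miRBase-style id into ``(species, family, arm)``.

    ``species`` is the prefix before the first ``-`` (empty when there is
    none); ``family`` is ``miR`` plus the family number, with variant
    letters and numeric sub-indices stripped and ``MIR`` case-normalized;
    ``arm`` is ``5p``/``3p`` from a trailing suffix, else ``unknown``.
    Ids without a miR-number pattern yield an empty family.

    >>> parse_mirna_id("osa-miR528-5p")
    ('osa', 'miR528', '5p')
    """
    if not identifier:
        raise ValueError("empty identifier")
    species = identifier.split("-", 1)[0] if "-" in identifier else ""
    m = _MIR_PATTERN.search(identifier)
    family = f"miR{m.group(1)}" if m else ""
    lowered = identifier.lower()
    if lowered.endswith("-5p"):
        arm = "5p"
    elif lowered.endswith("-3p"):
        arm = "3p"
    else:
        arm = "unknown"
    return species, family, arm


# --------------------------------------------------------------------------
# Locating matures on precursors

def locate_mature_in_precursor(precursor: SeqRecord,
                               mature: SeqRecord) -> Optional[tuple[int, int]]:
    """Find the first exact occurrence of ``mature`` in ``precursor``.

    Returns a 1-based inclusive span, or None when the mature does not
    occur. Multiple occurrences return the first and log a warning.
    """
    hits = _find_all(precursor.sequence, mature.sequence)
    if not hits:
        log.warning("mature %r not found in precursor %r", mature.id, precursor.id)
        return None
    if len(hits) > 1:
        log.warning("mature %r occurs %d times in precursor %r; using the first",
                    mature.id, len(hits), precursor.id)
    start = hits[0]
    return (start + 1, start + mature.length)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based (possibly overlapping) occurrence starts."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


# --------------------------------------------------------------------------
# Read tables

def read_read_table(path: str | Path,
                    library_total: Optional[float] = None) -> list[ReadRecord]:
    """Read a two-column ``sequence<TAB>count`` table of collapsed reads.

    RPM is computed against ``library_total`` when supplied, else against
    the sum of counts in the file. Zero or non-integer counts are rejected
    with the offending line number.
    """
    rows: list[tuple[str, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'sequence<TAB>count'")
            seq, raw_count = parts
            try:
                count = int(raw_count)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer count "
                                 f"{raw_count!r}") from exc
            if count < 1:
                raise ValueError(f"line {lineno}: count must be >= 1, got {count}")
            rows.append((seq, count))
    total = float(library_total) if library_total is not None else float(
        sum(c for _, c in rows))
    records = []
    for seq, count in rows:
        rpm = count / total * 1e6 if total > 0 else 0.0
        records.append(ReadRecord(sequence=seq, count=count, rpm=rpm))
    return records


def write_read_table(reads: Sequence[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"{r.sequence}\t{r.count}\n")


def compute_rpm(reads: Sequence[ReadRecord],
                library_total: Optional[float] = None) -> list[ReadRecord]:
    """Return copies of ``reads`` with RPM recomputed."""
    total = float(library_total) if library_total is not None else float(
        sum(r.count for r in reads))
    out = []
    for r in reads:
        rpm = r.count / total * 1e6 if total > 0 else 0.0
        out.append(ReadRecord(sequence=r.sequence, count=r.count, rpm=rpm))
    return out


def reverse_complement(sequence: str) -> str:
    """Reverse complement in the RNA alphabet."""
    comp = str.maketrans("ACGU", "UGCA")
    return sequence.translate(comp)[::-1]
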