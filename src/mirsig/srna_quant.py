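"""Exact-match read mapping to precursors and class-wise abundance.

Collapsed small-RNA reads are placed on a (possibly artificial)
precursor by exact, gap-free, forward-strand matching, then summarized
as RPM totals in nested classes: all 21-24-nt reads, 21-nt reads, reads
in the 40-60% GC band, and band reads that additionally carry the
positional signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from mirsig.composition import gc_content
from mirsig.seqio import ReadRecord, SeqRecord, _find_all
from mirsig.signature import SignatureModel, default_signature_model, evaluate_signature

log = logging.getLogger(__name__)

MIN_READ_LENGTH = 16
MAX_READ_LENGTH = 35
SIZE_RANGE = (21, 24)  # size range summarized in the class totals


@dataclass
class Alignment:
    """An exact placement of a read on a precursor (1-based inclusive)."""

    read: str
    precursor_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MappingResult:
    alignments: list[Alignment]
    unmapped: list[ReadRecord]

    @property
    def n_unmapped(self) -> int:
        return len(self.unmapped)


def map_reads(reads: Iterable[ReadRecord], precursor: SeqRecord,
              min_length: int = MIN_READ_LENGTH,
              max_length: int = MAX_READ_LENGTH,
              antisense: bool = False) -> MappingResult:
    """Map reads to a precursor by exact match, no mismatches or gaps.

    Every occurrence of each read is reported (a read matching a repeated
    stem yields one alignment per position). Forward strand only by
    default, as reads derive from the expressed hairpin transcript;
    ``antisense=True`` additionally searches the reverse complement.
    Reads outside [min_length, max_length] are dropped before mapping.
    """
    from mirsig.seqio import reverse_complement

    alignments: list[Alignment] = []
    unmapped: list[ReadRecord] = []
    for read in reads:
        if not (min_length <= read.length <= max_length):
            continue
        queries = [read.sequence]
        if antisense:
            queries.append(reverse_complement(read.sequence))
        hit = False
        for query in queries:
            for start0 in _find_all(precursor.sequence, query):
                alignments.append(Alignment(read=read.sequence,
                                            precursor_id=precursor.id,
                                            start=start0 + 1,
                                            end=start0 + read.length))
                hit = True
        if not hit:
            unmapped.append(read)
    if unmapped:
        log.info("%d reads did not map to %r", len(unmapped), precursor.id)
    # deterministic order regardless of input permutation
    alignments.sort(key=lambda a: (a.start, a.end, a.read))
    return MappingResult(alignments=alignments, unmapped=unmapped)


def filter_rpm(reads: Iterable[ReadRecord], threshold: float = 5.0,
               ) -> list[ReadRecord]:
    """Keep reads strictly above an RPM threshold (default > 5 RPM)."""
    return [r for r in reads if r.rpm > threshold]


@dataclass
class AbundanceSummary:
    """Class-wise abundance of reads mapped to a precursor.

    Classes are nested: ``band_signature`` (band AND 21-nt AND signature)
    <= ``band`` (GC 40-60%, within the 21-24-nt range) <= ``all_21_24``.
    Both RPM-weighted totals and unique-sequence counts are reported,
    since collapsed-read figures can be drawn either way.
    """

    rpm: dict[str, float]
    unique: dict[str, int]
    per_size_rpm: dict[int, float]


def abundance_by_class(mapping: MappingResult | Sequence[Alignment],
                       reads: Sequence[ReadRecord],
                       model: Optional[SignatureModel] = None,
                       ) -> AbundanceSummary:
    """Summarize mapped reads into nested abundance classes.

    A read contributes its RPM once per class no matter how many places
    it maps (multi-hit reads are counted by read, not by placement).
    The GC band applies within the summarized 21-24-nt range so the class
    nesting band_signature <= band <= all_21_24 holds for any input.
    """
    if model is None:
        model = default_signature_model()
    alignments = mapping.alignments if isinstance(mapping, MappingResult) else mapping
    mapped_seqs = {a.read for a in alignments}
    by_seq = {r.sequence: r for r in reads}

    rpm = {"all_21_24": 0.0, "len_21": 0.0, "band": 0.0, "band_signature": 0.0}
    unique = {k: 0 for k in rpm}
    per_size_rpm: dict[int, float] = {}
    lo, hi = SIZE_RANGE
    for seq in sorted(mapped_seqs):
        read = by_seq.get(seq)
        if read is None:
            raise ValueError(f"alignment for unknown read {seq!r}")
        per_size_rpm[read.length] = per_size_rpm.get(read.length, 0.0) + read.rpm
        if not (lo <= read.length <= hi):
            continue
        rpm["all_21_24"] += read.rpm
        unique["all_21_24"] += 1
        if read.length == 21:
            rpm["len_21"] += read.rpm
            unique["len_21"] += 1
        gc = gc_content(seq)
        in_band = model.gc_band[0] <= gc <= model.gc_band[1]
        if in_band:
            rpm["band"] += read.rpm
            unique["band"] += 1
            if read.length == model.length and \
                    evaluate_signature(seq, model).has_signature:
                rpm["band_signature"] += read.rpm
                unique["band_signature"] += 1
    return AbundanceSummary(rpm=rpm, unique=unique, per_size_rpm=per_size_rpm)
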