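"""Read pre-processing: adapter trimming, length filtering, perfect-match SAM filter.

The filtering contract mirrors the standard 5'-end RNA-seq preparation for
single-nucleotide TSS mapping: reads are 3'-adapter-trimmed, reads shorter
than 16 nt are discarded before alignment, and after alignment only reads
matching the genome perfectly — SAM tags ``XM:i:0`` and ``NM:i:0`` both
present — are kept, so that every counted 5' end is an exact genomic
position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pysam

logger = logging.getLogger(__name__)

FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800

DEFAULT_MIN_LENGTH = 16


@dataclass(frozen=True)
class Read:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError("quality string length must equal sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """A minimal SAM alignment record (1-based leftmost position)."""

    read_id: str
    flag: int
    ref_id: str
    pos: int
    cigar: str
    tags: dict = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"


@dataclass
class FilterStats:
    """Bookkeeping for the trimming/length and perfect-match stages."""

    n_input: int = 0
    n_after_trim_and_length: int = 0
    n_mapped: int = 0
    n_perfect: int = 0

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        if self.n_input < self.n_after_trim_and_length:
            raise ValueError("n_input must be >= n_after_trim_and_length")
        if self.n_mapped < self.n_perfect:
            raise ValueError("n_mapped must be >= n_perfect")


def trim_adapter(read: Read, adapter: str) -> Read:
    """Remove everything from the leftmost full occurrence of ``adapter`` onward.

    Matching is exact full-string search; if the adapter does not occur the
    read is returned unchanged.  Qualities are trimmed in step.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    idx = read.seq.find(adapter)
    if idx < 0:
        return read
    return Read(read.id, read.seq[:idx], read.qual[:idx] if read.qual is not None else None)


def length_filter(reads: Iterable[Read], min_len: int = DEFAULT_MIN_LENGTH) -> list[Read]:
    """Keep exactly the reads of length >= ``min_len``, preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [r for r in reads if len(r) >= min_len]


def trim_and_length_filter(
    reads: Iterable[Read], adapter: str, min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[Read], FilterStats]:
    """Adapter-trim then length-filter; returns survivors and counts."""
    trimmed = [trim_adapter(r, adapter) for r in reads]
    kept = length_filter(trimmed, min_len)
    return kept, FilterStats(n_input=len(trimmed), n_after_trim_and_length=len(kept))


def _int_tag(rec: AlignmentRecord, tag: str) -> Optional[int]:
    if tag not in rec.tags:
        return None
    try:
        return int(rec.tags[tag])
    except (TypeError, ValueError):
        logger.warning("rejecting %s: malformed %s tag %r", rec.read_id, tag, rec.tags[tag])
        return None


def perfect_match_filter(
    records: Iterable[AlignmentRecord],
) -> tuple[list[AlignmentRecord], FilterStats]:
    """Select primary mapped records with both ``XM`` and ``NM`` equal to 0.

    Records that are unmapped, secondary or supplementary, missing either tag,
    or carrying a malformed tag value are excluded (malformed values are
    logged, never silently kept).
    """
    records = list(records)
    kept: list[AlignmentRecord] = []
    n_mapped = 0
    for rec in records:
        if not rec.is_mapped:
            continue
        if rec.flag & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue
        n_mapped += 1
        xm = _int_tag(rec, "XM")
        nm = _int_tag(rec, "NM")
        if xm == 0 and nm == 0:
            kept.append(rec)
    stats = FilterStats(
        n_input=len(records),
        n_after_trim_and_length=len(records),
        n_mapped=n_mapped,
        n_perfect=len(kept),
    )
    return kept, stats


# ---------------------------------------------------------------------------
# file formats


def read_fastq(path: str | Path) -> list[Read]:
    reads: list[Read] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            reads.append(Read(header[1:].split()[0].rstrip("\n"), seq, qual or None))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse a SAM text file into :class:`AlignmentRecord` objects."""
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            records.append(
                AlignmentRecord(
                    read_id=rec.query_name or "",
                    flag=rec.flag,
                    ref_id=rec.reference_name or "*",
                    pos=(rec.reference_start + 1) if rec.reference_start is not None and rec.reference_start >= 0 else 0,
                    cigar=rec.cigarstring or "*",
                    tags=dict(rec.get_tags()),
                )
            )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    ref_id: str,
    ref_length: int,
    path: str | Path,
    seqs: Optional[dict[str, str]] = None,
) -> None:
    """Write records as SAM text; ``seqs`` optionally supplies read sequences."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": ref_id, "LN": ref_length}]}
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            seg.flag = rec.flag
            if rec.is_mapped:
                seg.reference_id = 0
                seg.reference_start = rec.pos - 1
                seg.cigarstring = rec.cigar
                seg.mapping_quality = 42
            else:
                seg.reference_id = -1
                seg.reference_start = -1
            if seqs is not None and rec.read_id in seqs:
                seq = seqs[rec.read_id]
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            seg.set_tags(sorted(rec.tags.items()))
            out.write(seg)
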