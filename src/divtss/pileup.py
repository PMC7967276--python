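"""Strand-specific 5'-end pileups and depth normalization across replicates.

The signal for single-nucleotide TSS mapping is the per-position, per-strand
count of aligned-read 5' termini.  Replicates within one growth condition are
made comparable by scaling each replicate's counts with the coefficient

    c_i = N_av / N_i,

where ``N_i`` is that replicate's number of perfectly matching reads and
``N_av`` the mean over the condition's replicates; the condition-level track
is the per-position mean of the scaled replicate counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .reads import AlignmentRecord

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = frozenset("MDN=X")


def reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(n + op for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return sum(int(n) for n, op in ops if op in _REF_CONSUMING)


def five_prime_position(rec: AlignmentRecord) -> tuple[int, str]:
    """Genomic position and strand of an aligned read's 5' end.

    Plus-strand alignments start their transcript at the leftmost reference
    position; minus-strand alignments at the rightmost.  Soft-clipped bases do
    not shift the counted position (the aligned end is used).
    """
    if not rec.is_mapped:
        raise ValueError(f"read {rec.read_id} is unmapped")
    span = reference_span(rec.cigar)
    if span < 1:
        raise ValueError(f"CIGAR {rec.cigar!r} consumes no reference bases")
    if rec.is_reverse:
        return rec.pos + span - 1, "-"
    return rec.pos, "+"


@dataclass
class FivePrimeTrack:
    """Sparse per-strand map position -> 5'-end count (raw int or normalized float)."""

    ref_id: str
    counts_plus: dict[int, float] = field(default_factory=dict)
    counts_minus: dict[int, float] = field(default_factory=dict)
    total_perfect_reads: float = 0

    def counts(self, strand: str) -> dict[int, float]:
        if strand == "+":
            return self.counts_plus
        if strand == "-":
            return self.counts_minus
        raise ValueError(f"invalid strand {strand!r}")

    def total_signal(self) -> float:
        return sum(self.counts_plus.values()) + sum(self.counts_minus.values())


def build_track(records: Iterable[AlignmentRecord], ref_id: Optional[str] = None) -> FivePrimeTrack:
    """Accumulate 5'-end counts from perfect-match-filtered alignment records."""
    records = list(records)
    if ref_id is None:
        ref_id = records[0].ref_id if records else ""
    track = FivePrimeTrack(ref_id=ref_id)
    for rec in records:
        if rec.ref_id != ref_id:
            raise ValueError(f"record {rec.read_id} on unexpected reference {rec.ref_id!r}")
        pos, strand = five_prime_position(rec)
        counts = track.counts(strand)
        counts[pos] = counts.get(pos, 0) + 1
    track.total_perfect_reads = len(records)
    return track


@dataclass
class ConditionGroup:
    """Replicate tracks sharing one growth condition (the normalization unit)."""

    label: str
    replicates: list[FivePrimeTrack]
    replicate_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("a condition group needs at least one replicate")
        if self.replicate_labels is None:
            self.replicate_labels = [f"{self.label}_rep{i + 1}" for i in range(len(self.replicates))]

    @property
    def n_av(self) -> float:
        return sum(t.total_perfect_reads for t in self.replicates) / len(self.replicates)

    @property
    def coefficients(self) -> list[float]:
        return normalization_coefficients([t.total_perfect_reads for t in self.replicates])


def normalization_coefficients(perfect_read_counts: Iterable[float]) -> list[float]:
    """Per-replicate scaling factors c_i = mean(N) / N_i at full precision.

    Rounding to 4 decimal places is applied only in report output.
    """
    counts = list(perfect_read_counts)
    if not counts:
        raise ValueError("need at least one replicate")
    if any(n == 0 for n in counts):
        raise ValueError("replicate with zero perfect-match reads (empty replicate?)")
    n_av = sum(counts) / len(counts)
    return [n_av / n for n in counts]


def normalize_and_average(group: ConditionGroup) -> FivePrimeTrack:
    """Mean over replicates of coefficient-scaled counts, per position and strand.

    Positions absent from a replicate contribute zero to its term, so a
    position seen in only one of two replicates ends up at half its normalized
    height.  The result is invariant under replicate reordering.
    """
    ref_ids = {t.ref_id for t in group.replicates}
    if len(ref_ids) > 1:
        raise ValueError(f"replicates on different references: {sorted(ref_ids)}")
    coeffs = group.coefficients
    n = len(group.replicates)
    out = FivePrimeTrack(ref_id=group.replicates[0].ref_id)
    out.total_perfect_reads = group.n_av
    for strand in "+-":
        acc: dict[int, float] = {}
        for track, c in zip(group.replicates, coeffs):
            for pos, v in track.counts(strand).items():
                acc[pos] = acc.get(pos, 0.0) + v * c
        target = out.counts(strand)
        for pos, v in acc.items():
            target[pos] = v / n
    return out


# ---------------------------------------------------------------------------
# report / export


def replicate_table(groups: Iterable[ConditionGroup], trim_counts: Optional[dict[str, int]] = None) -> pd.DataFrame:
    """Per-replicate summary: label, condition, read counts, 4-dp coefficient."""
    rows = []
    for g in groups:
        for label, track, c in zip(g.replicate_labels, g.replicates, g.coefficients):
            rows.append(
                {
                    "replicate": label,
                    "condition": g.label,
                    "reads_after_trim_and_length": (trim_counts or {}).get(label, pd.NA),
                    "perfect_match_reads": track.total_perfect_reads,
                    "normalizing_coefficient": round(c, 4),
                }
            )
    return pd.DataFrame(rows)


def write_bedgraph(track: FivePrimeTrack, strand: str, path: str | Path) -> None:
    """One strand of a track as bedGraph (0-based half-open), positions sorted."""
    counts = track.counts(strand)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.ref_id}_5p_{strand}"\n')
        for pos in sorted(counts):
            fh.write(f"{track.ref_id}\t{pos - 1}\t{pos}\t{counts[pos]:.6g}\n")


def read_bedgraph(path: str | Path, ref_id: str, strand: str) -> FivePrimeTrack:
    track = FivePrimeTrack(ref_id=ref_id)
    counts = track.counts(strand)
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            _chrom, start0, end0, value = line.split("\t")
            for pos0 in range(int(start0), int(end0)):
                counts[pos0 + 1] = float(value)
    return track
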