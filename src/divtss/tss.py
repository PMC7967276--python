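"""TSS peak calling near annotated 5' ends, shift computation, concordance.

A TSS call is a strand-matching local maximum of the averaged normalized
5'-end track within a window around a feature's annotated transcript 5' end.
The highest peak is ranked *primary* (ties broken toward the annotated
position, then toward upstream), all others *secondary*.  Signed offsets
follow the transcription direction: negative = upstream of the annotated 5'
end (transcript extension), positive = downstream (shortening), so an
extension reads the same on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .genome import Feature, annotated_five_prime, three_prime_end, five_prime_end
from .pileup import FivePrimeTrack

DEFAULT_WINDOW = 300
DEFAULT_MIN_HEIGHT = 5.0

PRIMARY = "primary"
SECONDARY = "secondary"


@dataclass(frozen=True)
class TssCall:
    position: int
    strand: str
    height: float
    rank: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("TSS call height must be positive")
        if self.rank not in (PRIMARY, SECONDARY):
            raise ValueError(f"invalid rank {self.rank!r}")


@dataclass(frozen=True)
class TssShift:
    feature_name: str
    annotated_5p: int
    called: TssCall
    offset: int


@dataclass(frozen=True)
class ConcordanceRecord:
    called: TssCall
    predicted_position: Optional[int]
    distance: Optional[int]
    matched: bool


def _local_maxima(counts: dict[int, float], lo: int, hi: int, min_height: float) -> list[tuple[int, float]]:
    """Positions in [lo, hi] with value >= min_height that dominate both
    neighbours; the leftmost point of an exact plateau is reported once."""
    out = []
    for pos, v in counts.items():
        if lo <= pos <= hi and v >= min_height:
            left = counts.get(pos - 1, 0.0)
            right = counts.get(pos + 1, 0.0)
            if v > left and v >= right:
                out.append((pos, v))
    return out


def call_tss(
    track: FivePrimeTrack,
    feature: Feature,
    window: int = DEFAULT_WINDOW,
    min_height: float = DEFAULT_MIN_HEIGHT,
    condition: str = "",
) -> list[TssCall]:
    """All qualifying peaks near ``feature``'s annotated 5' end, primary first.

    Secondary calls follow sorted by height descending.  A flat (empty) track
    yields an empty list.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    a5p = annotated_five_prime(feature)
    counts = track.counts(feature.strand)
    peaks = _local_maxima(counts, a5p - window, a5p + window, min_height)
    if not peaks:
        return []

    def _key(pv: tuple[int, float]) -> tuple:
        pos, v = pv
        offset = pos - a5p if feature.strand == "+" else a5p - pos
        # height desc, then closest to the annotation, then upstream (negative offset)
        return (-v, abs(offset), offset)

    peaks.sort(key=_key)
    calls = [TssCall(peaks[0][0], feature.strand, peaks[0][1], PRIMARY, condition)]
    calls += [TssCall(p, feature.strand, v, SECONDARY, condition) for p, v in peaks[1:]]
    return calls


def tss_offset(call: TssCall, feature: Feature) -> int:
    """Signed shift of a call from the annotated 5' end, extension < 0."""
    if call.strand != feature.strand:
        raise ValueError(f"strand mismatch: call {call.strand}, feature {feature.strand}")
    a5p = annotated_five_prime(feature)
    if feature.strand == "+":
        return call.position - a5p
    return a5p - call.position


def transcript_variants(calls: Iterable[TssCall], feature: Feature) -> list[int]:
    """Transcript length (nt) per distinct called TSS, to the annotated 3' end.

    Pairwise length differences equal pairwise TSS separations.
    """
    t3 = three_prime_end(feature)
    lengths: list[int] = []
    seen: set[int] = set()
    for call in calls:
        if call.position in seen:
            continue
        seen.add(call.position)
        if feature.strand == "+":
            length = t3 - call.position + 1
        else:
            length = call.position - t3 + 1
        if length < 1:
            raise ValueError(
                f"TSS at {call.position} lies downstream of the 3' end {t3} "
                f"({feature.strand} strand)"
            )
        lengths.append(length)
    return lengths


def concordance(
    calls: Iterable[TssCall],
    predicted: Iterable[Feature],
    tolerance: int = 0,
) -> list[ConcordanceRecord]:
    """Match each call to the nearest same-strand predicted TSS.

    ``matched`` is true exactly when the distance is <= ``tolerance``.  With
    no same-strand predictions the record carries no position or distance.
    """
    by_strand: dict[str, list[int]] = {"+": [], "-": []}
    for f in predicted:
        by_strand[f.strand].append(five_prime_end(f))
    out = []
    for call in calls:
        candidates = by_strand[call.strand]
        if not candidates:
            out.append(ConcordanceRecord(call, None, None, False))
            continue
        nearest = min(candidates, key=lambda p: (abs(p - call.position), p))
        dist = abs(nearest - call.position)
        out.append(ConcordanceRecord(call, nearest, dist, dist <= tolerance))
    return out
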