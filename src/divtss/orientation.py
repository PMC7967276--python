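"""Orientation taxonomy for ncRNAs and their nearest protein-coding neighbors.

Each ncRNA is paired with the protein-coding gene whose transcript 5' end is
closest and classified as *codirected* (head-to-tail, same strand),
*divergent* (head-to-head on opposite strands, spans disjoint),
*overlapping_5prime* (opposite strands with intersecting transcript spans,
counting the neighbor's 5'UTR when its mRNA TSS is known), or *convergent*
(tail-to-tail; reported with its own label but outside the three-way
divergent-ncRNA taxonomy).  A *bona fide* ncRNA is one whose gene span
overlaps no transcript span on the opposite strand; otherwise the coordinate
overlap is its potential antisense duplex length.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional

from .genome import (
    Feature,
    Interval,
    NCRNA,
    PROTEIN_CODING,
    annotated_five_prime,
    overlap_length,
    transcript_span,
)

CODIRECTED = "codirected"
DIVERGENT = "divergent"
OVERLAPPING_5PRIME = "overlapping_5prime"
CONVERGENT = "convergent"


@dataclass(frozen=True)
class ArrangementCall:
    ncrna: Feature
    neighbor: Feature
    arrangement: str
    bona_fide: bool
    antisense_overlap: int
    inter_tss_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bona_fide and self.antisense_overlap != 0:
            raise ValueError("bona fide ncRNA cannot have antisense overlap")
        if self.arrangement == OVERLAPPING_5PRIME and self.antisense_overlap <= 0:
            raise ValueError("overlapping_5prime requires positive overlap")


@dataclass(frozen=True)
class DistanceSummary:
    n_pairs: int
    min: int
    max: int
    median: float

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("min <= median <= max violated")


def nearest_neighbor(ncrna: Feature, annotation: Iterable[Feature]) -> Feature:
    """Protein-coding feature whose transcript 5' end is closest to the
    ncRNA's 5' end; ties break toward the ncRNA's upstream side."""
    ncrna_5p = annotated_five_prime(ncrna)
    candidates = [f for f in annotation if f.kind == PROTEIN_CODING and f.name != ncrna.name]
    if not candidates:
        raise ValueError("annotation contains no protein-coding features")

    def _upstream(f: Feature) -> int:
        p = annotated_five_prime(f)
        if ncrna.strand == "+":
            return 0 if p <= ncrna_5p else 1
        return 0 if p >= ncrna_5p else 1

    return min(candidates, key=lambda f: (abs(annotated_five_prime(f) - ncrna_5p), _upstream(f), f.name))


def classify_arrangement(ncrna: Feature, neighbor: Feature) -> ArrangementCall:
    """Classify one ncRNA/neighbor pair; total over all strand/coordinate layouts."""
    if ncrna.strand == neighbor.strand:
        return ArrangementCall(ncrna, neighbor, CODIRECTED, bona_fide=True, antisense_overlap=0)
    n_span = ncrna.span
    t_span = transcript_span(neighbor)
    ov = overlap_length(n_span, t_span)
    if ov > 0:
        return ArrangementCall(ncrna, neighbor, OVERLAPPING_5PRIME, bona_fide=False, antisense_overlap=ov)
    # disjoint, opposite strands: head-to-head iff the plus-strand partner
    # lies to the right of the minus-strand partner
    plus, minus = (ncrna, neighbor) if ncrna.strand == "+" else (neighbor, ncrna)
    arrangement = DIVERGENT if plus.start > minus.end else CONVERGENT
    return ArrangementCall(ncrna, neighbor, arrangement, bona_fide=True, antisense_overlap=0)


def is_bona_fide(ncrna: Feature, annotation: Iterable[Feature]) -> bool:
    """True iff the ncRNA span overlaps no opposite-strand transcript span."""
    for f in annotation:
        if f.strand == ncrna.strand or f.name == ncrna.name or f.kind not in (PROTEIN_CODING, NCRNA):
            continue
        if overlap_length(ncrna.span, transcript_span(f)) > 0:
            return False
    return True


def antisense_overlap_length(
    ncrna: Feature,
    neighbor: Feature,
    ncrna_tss: Optional[int] = None,
    neighbor_tss: Optional[int] = None,
) -> int:
    """Coordinate overlap between the ncRNA transcript and the neighbor transcript.

    Refined TSS positions, when given, replace the annotated 5' ends (a
    refined upstream TSS enlarges the span and can only increase the overlap).
    The neighbor transcript span runs from its mRNA TSS (or the override) to
    the CDS 3' end.
    """
    if ncrna.strand == neighbor.strand:
        raise ValueError("antisense overlap requires opposite strands")

    def _span(f: Feature, tss: Optional[int]) -> Interval:
        if tss is None:
            return transcript_span(f)
        if f.strand == "+":
            return Interval(min(tss, f.end), f.end, "+")
        return Interval(f.start, max(tss, f.start), "-")

    return overlap_length(_span(ncrna, ncrna_tss), _span(neighbor, neighbor_tss))


def inter_tss_distance(pair: ArrangementCall, tss_a: int, tss_b: int) -> int:
    """Absolute distance between the two TSSs of a divergent pair."""
    if pair.arrangement != DIVERGENT:
        raise ValueError(f"inter-TSS distance defined for divergent pairs, not {pair.arrangement}")
    return abs(tss_a - tss_b)


def summarize_distances(calls: Iterable[ArrangementCall]) -> DistanceSummary:
    """Min/median/max of inter-TSS distances over divergent pairs.

    The median of an even number of pairs is the mean of the central two.
    """
    distances = [c.inter_tss_distance for c in calls if c.arrangement == DIVERGENT and c.inter_tss_distance is not None]
    if not distances:
        raise ValueError("no divergent pairs with inter-TSS distances")
    return DistanceSummary(
        n_pairs=len(distances),
        min=min(distances),
        max=max(distances),
        median=statistics.median(distances),
    )
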