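"""REP-element screen: degenerate motif scanning, poly-T tracks, hairpins.

REP (repetitive extragenic palindromic) elements are ~35-bp self-complementary
motifs recurrent in enterobacterial intergenic regions.  The screen asks, for
an intergenic region between two collinear protein-coding genes, whether a
divergently oriented TSS upstream of a REP copy could read through the
element — i.e. whether a candidate intrinsic terminator (a poly-T track on
the transcribed strand immediately preceded by a self-complementary hairpin)
intervenes between the TSS and the REP 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .genome import (
    Feature,
    GenomeSequence,
    Interval,
    PROTEIN_CODING,
    reverse_complement,
)
from .pileup import FivePrimeTrack
from .tss import PRIMARY, TssCall

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# The consensus is a 35-bp mirror-symmetric motif written as two degenerate
# half-sites around an unspecified center, modeled here as a 0-3 nt spacer of
# N positions; the two literal full-length variants circulating in the
# enterobacterial literature are provided as ungapped patterns.
REP_LEFT_HALF = "GCKGATGGCGRGCK"
REP_RIGHT_HALF = "RCGYCTTATCMGGCCTAC"
REP_VARIANT_A = "TGCCGGATGCGGCGTAAACGCCTTATCCGGCCTAC"
REP_VARIANT_B = "GCCGGATGCGGCGTGAACGCCTTATCCGGCCTACGA"

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_T_RUN = 4
DEFAULT_MIN_STEM = 4
DEFAULT_MAX_LOOP = 8
DEFAULT_MIN_LOOP = 3
DEFAULT_HAIRPIN_WINDOW = 20


@dataclass(frozen=True)
class RepConsensus:
    name: str
    pattern: str
    max_mismatches: int = DEFAULT_MAX_MISMATCHES

    def __post_init__(self) -> None:
        if len(self.pattern) < 10:
            raise ValueError("REP consensus pattern must be >= 10 nt")
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC codes in pattern: {sorted(bad)}")


@dataclass(frozen=True)
class RepMatch:
    start: int
    end: int
    strand: str
    mismatches: int
    consensus_name: str


@dataclass
class RepScanParams:
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    min_t_run: int = DEFAULT_MIN_T_RUN
    min_stem: int = DEFAULT_MIN_STEM
    max_loop: int = DEFAULT_MAX_LOOP
    min_loop: int = DEFAULT_MIN_LOOP
    hairpin_window: int = DEFAULT_HAIRPIN_WINDOW
    min_tss_height: float = 5.0


@dataclass
class RepLocusReport:
    """Outcome of the read-through screen for one intergenic region."""

    igr: Interval
    transcribed_strand: str
    rep_matches: list[RepMatch] = field(default_factory=list)
    divergent_tss: Optional[TssCall] = None
    tn_tracks: list[Interval] = field(default_factory=list)
    tn_hairpin_flags: list[bool] = field(default_factory=list)
    hairpin_upstream_of_tn: bool = False
    tss_to_rep_distance: Optional[int] = None
    read_through: Optional[bool] = None


def builtin_consensuses(max_mismatches: int = DEFAULT_MAX_MISMATCHES) -> list[RepConsensus]:
    """Symmetric consensus (spacers 0-3) plus the two literal variants."""
    out = [
        RepConsensus(f"rep_consensus_s{n}", REP_LEFT_HALF + "N" * n + REP_RIGHT_HALF, max_mismatches)
        for n in range(4)
    ]
    out.append(RepConsensus("rep_35mer_a", REP_VARIANT_A, max_mismatches))
    out.append(RepConsensus("rep_36mer_b", REP_VARIANT_B, max_mismatches))
    return out


_CODE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for ch, i in _CODE_INDEX.items():
        lut[ord(ch)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mismatch_counts(codes: np.ndarray, pattern: str) -> np.ndarray:
    """Vector of mismatch counts for the pattern at every window offset.

    A genome N matches nothing unless the pattern code is N.
    """
    plen = len(pattern)
    n_win = len(codes) - plen + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    mm = np.zeros(n_win, dtype=np.int32)
    for j, ch in enumerate(pattern):
        allowed = np.zeros(5, dtype=bool)
        for base in IUPAC_SETS[ch]:
            allowed[_CODE_INDEX[base]] = True
        mm += ~allowed[codes[j : j + n_win]]
    return mm


def scan_rep(seq: str, consensus: RepConsensus, region_start: int = 1) -> list[RepMatch]:
    """All matches of the consensus on both strands with <= max_mismatches.

    ``region_start`` is the 1-based genome coordinate of ``seq[0]``; reported
    coordinates are genomic.  Minus-strand matches are found by scanning the
    reverse-complemented pattern against the given (plus-strand) sequence.
    """
    seq = seq.upper()
    codes = _encode(seq)
    plen = len(consensus.pattern)
    matches: list[RepMatch] = []
    for strand, pattern in (("+", consensus.pattern), ("-", consensus.pattern.translate(_IUPAC_COMPLEMENT)[::-1])):
        mm = _mismatch_counts(codes, pattern)
        for i in np.flatnonzero(mm <= consensus.max_mismatches):
            start = region_start + int(i)
            matches.append(RepMatch(start, start + plen - 1, strand, int(mm[i]), consensus.name))
    matches.sort(key=lambda m: (m.start, m.strand, m.consensus_name))
    return matches


def find_tn_tracks(
    seq: str, min_run: int = DEFAULT_MIN_T_RUN, strand: str = "+", region_start: int = 1
) -> list[Interval]:
    """Maximal runs of >= min_run consecutive T on the transcribed strand.

    For minus-strand transcription the RNA T corresponds to an A on the
    plus-strand genome sequence given here.  Returned intervals are genomic,
    maximal and pairwise non-overlapping.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    base = "T" if strand == "+" else "A"
    tracks: list[Interval] = []
    i, n = 0, len(seq)
    seq = seq.upper()
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            if j - i >= min_run:
                tracks.append(Interval(region_start + i, region_start + j - 1, strand))
            i = j
        else:
            i += 1
    return tracks


def hairpin_upstream(
    seq: str,
    t_track: Interval,
    min_stem: int = DEFAULT_MIN_STEM,
    max_loop: int = DEFAULT_MAX_LOOP,
    search_window: int = DEFAULT_HAIRPIN_WINDOW,
    strand: str = "+",
    min_loop: int = DEFAULT_MIN_LOOP,
    region_start: int = 1,
) -> bool:
    """True iff a stem-loop (stem >= min_stem, loop min_loop..max_loop) lies
    within ``search_window`` nt upstream of the poly-T track.

    ``seq`` is the plus-strand sequence whose first base sits at genome
    coordinate ``region_start``; "upstream" follows the transcribed strand, so
    for minus-strand transcription the window lies to the genomic right of
    the track and is examined reverse-complemented.  All stem/loop placements
    are enumerated exhaustively (windows are tens of bases).
    """
    seq = seq.upper()
    if strand == "+":
        w_end = t_track.start - region_start  # exclusive, 0-based in seq
        w_start = max(0, w_end - search_window)
        window = seq[w_start:w_end]
    else:
        w_start = t_track.end - region_start + 1
        w_end = min(len(seq), w_start + search_window)
        window = reverse_complement(seq[w_start:w_end])
    n = len(window)
    for s in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * s - min_loop + 1):
            stem1 = window[i : i + s]
            for loop in range(min_loop, max_loop + 1):
                j = i + s + loop
                if j + s > n:
                    break
                if window[j : j + s] == reverse_complement(stem1):
                    return True
    return False


def _rep_five_prime(match: RepMatch, transcribed_strand: str) -> int:
    """5' boundary of a REP copy as seen by a transcript on the given strand."""
    return match.start if transcribed_strand == "+" else match.end


def _igr_tss(
    track: FivePrimeTrack, igr: Interval, strand: str, min_height: float, condition: str = ""
) -> Optional[TssCall]:
    counts = track.counts(strand)
    best: Optional[tuple[float, int]] = None
    for pos, v in counts.items():
        if igr.start <= pos <= igr.end and v >= min_height:
            # highest peak; ties resolved toward the IGR-upstream side
            key = (v, pos if strand == "-" else -pos)
            if best is None or key > best:
                best = key
    if best is None:
        return None
    return TssCall(best[1], strand, best[0], PRIMARY, condition)


def rep_transcription_report(
    igr: Interval,
    annotation: Iterable[Feature],
    genome: GenomeSequence,
    track: FivePrimeTrack,
    consensuses: Optional[Iterable[RepConsensus]] = None,
    params: Optional[RepScanParams] = None,
) -> RepLocusReport:
    """Screen one intergenic region for divergent transcription across a REP.

    The IGR must be flanked by two annotated protein-coding genes on the same
    strand (the collinear-genes layout of the screen); the candidate divergent
    transcript runs on the opposite strand, i.e. against the downstream gene.
    """
    params = params or RepScanParams()
    consensuses = list(consensuses) if consensuses is not None else builtin_consensuses(params.max_mismatches)

    genes = sorted((f for f in annotation if f.kind == PROTEIN_CODING), key=lambda f: f.start)
    left = [f for f in genes if f.end < igr.start]
    right = [f for f in genes if f.start > igr.end]
    if not left or not right:
        raise ValueError(f"IGR {igr.start}..{igr.end} is not flanked by two annotated genes")
    left_gene, right_gene = left[-1], right[0]
    if left_gene.strand != right_gene.strand:
        raise ValueError(
            "REP read-through screen requires collinear flanking genes "
            f"({left_gene.name} is {left_gene.strand}, {right_gene.name} is {right_gene.strand})"
        )
    # divergent transcript opposes the flanking genes' direction
    transcribed = "-" if left_gene.strand == "+" else "+"

    report = RepLocusReport(igr=igr, transcribed_strand=transcribed)
    igr_seq = genome.subseq(igr.start, igr.end)
    for consensus in consensuses:
        report.rep_matches.extend(scan_rep(igr_seq, consensus, region_start=igr.start))
    report.rep_matches.sort(key=lambda m: (m.start, m.strand, m.consensus_name))

    report.divergent_tss = _igr_tss(track, igr, transcribed, params.min_tss_height)
    if report.divergent_tss is None or not report.rep_matches:
        return report

    tss = report.divergent_tss.position
    # nearest REP 5' boundary downstream of the TSS in transcription direction
    candidates = []
    for m in report.rep_matches:
        r5p = _rep_five_prime(m, transcribed)
        dist = (r5p - tss) if transcribed == "+" else (tss - r5p)
        if dist >= 0:
            candidates.append((dist, r5p))
    if not candidates:
        return report
    dist, r5p = min(candidates)
    report.tss_to_rep_distance = dist

    if transcribed == "+":
        lo, hi = tss + 1, r5p - 1
    else:
        lo, hi = r5p + 1, tss - 1
    if lo <= hi:
        between = genome.subseq(lo, hi)
        report.tn_tracks = find_tn_tracks(between, params.min_t_run, transcribed, region_start=lo)
        report.tn_hairpin_flags = [
            hairpin_upstream(
                genome.seq,
                t,
                params.min_stem,
                params.max_loop,
                params.hairpin_window,
                transcribed,
                params.min_loop,
                region_start=1,
            )
            for t in report.tn_tracks
        ]
    report.hairpin_upstream_of_tn = any(report.tn_hairpin_flags)
    report.read_through = not report.hairpin_upstream_of_tn
    return report
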