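"""Genome coordinate model: sequence, annotated features, intervals, strand logic.

Conventions
-----------
All coordinates are 1-based and inclusive on both ends, matching how genome
positions are printed in bacterial annotation databases.  Conversion to the
0-based half-open convention happens only inside the BED and bedGraph
readers/writers.  Strands are the strings ``"+"`` and ``"-"``.

A :class:`Feature` models one annotated transcription unit on a single
(circular) bacterial chromosome.  For protein-coding genes, ``start``/``end``
delimit the CDS and the optional ``mrna_tss`` records an experimentally
supported mRNA transcription start, which may lie well upstream of the coding
start and thereby defines a 5'UTR.  For ncRNAs the annotated 5' end is taken
to coincide with the transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

DNA_ALPHABET = frozenset("ACGTN")

#: feature kinds used throughout the pipeline
PROTEIN_CODING = "protein_coding"
NCRNA = "ncRNA"
REP = "REP"
PREDICTED_TSS = "predicted_TSS"

FEATURE_KINDS = frozenset({PROTEIN_CODING, NCRNA, REP, PREDICTED_TSS})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: mapping of GFF3 column-3 types onto the internal feature kinds
_GFF_TYPE_TO_KIND = {
    "gene": PROTEIN_CODING,
    "CDS": PROTEIN_CODING,
    "ncRNA": NCRNA,
    "sRNA": NCRNA,
    "ncRNA_gene": NCRNA,
    "repeat_region": REP,
    "REP_element": REP,
    "TSS": PREDICTED_TSS,
}

_KIND_TO_GFF_TYPE = {
    PROTEIN_CODING: "gene",
    NCRNA: "ncRNA",
    REP: "repeat_region",
    PREDICTED_TSS: "TSS",
}


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome: identifier, sequence over {A,C,G,T,N}, circularity."""

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-DNA characters in genome sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """1-based inclusive slice. Intervals crossing the origin are rejected."""
        if not (1 <= start <= end <= len(self.seq)):
            raise ValueError(
                f"interval {start}..{end} out of bounds for genome of "
                f"length {len(self.seq)} (origin-crossing intervals unsupported)"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class Interval:
    """A 1-based, both-ends-inclusive genomic interval, optionally stranded."""

    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Feature:
    """A named, strand-aware annotated feature.

    ``mrna_tss`` is only meaningful for protein-coding genes; when set it must
    lie upstream of (or at) the coding start in the direction of transcription.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str
    mrna_tss: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.mrna_tss is not None:
            if self.strand == "+" and self.mrna_tss > self.start:
                raise ValueError("mrna_tss must be <= start on the plus strand")
            if self.strand == "-" and self.mrna_tss < self.end:
                raise ValueError("mrna_tss must be >= end on the minus strand")

    @property
    def span(self) -> Interval:
        return Interval(self.start, self.end, self.strand)


def five_prime_end(feature: Feature) -> int:
    """Position of the feature's 5' end: ``start`` on +, ``end`` on -."""
    return feature.start if feature.strand == "+" else feature.end


def three_prime_end(feature: Feature) -> int:
    return feature.end if feature.strand == "+" else feature.start


def annotated_five_prime(feature: Feature) -> int:
    """Transcript-level 5' end: the mRNA TSS when known, else the feature 5' end."""
    if feature.mrna_tss is not None:
        return feature.mrna_tss
    return five_prime_end(feature)


def transcript_span(feature: Feature) -> Interval:
    """The transcribed span: CDS/gene span extended to ``mrna_tss`` when set."""
    if feature.mrna_tss is None:
        return Interval(feature.start, feature.end, feature.strand)
    if feature.strand == "+":
        return Interval(feature.mrna_tss, feature.end, "+")
    return Interval(feature.start, feature.mrna_tss, "-")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise ValueError(f"non-DNA character {ch!r} at position {i}")
    return seq.translate(_COMPLEMENT)[::-1]


def overlap_length(a: Interval, b: Interval) -> int:
    """Number of positions shared by two intervals (0 if disjoint).

    Symmetric in its arguments; strand is deliberately ignored — callers
    decide whether opposite-strand overlap means an antisense duplex.
    """
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


# ---------------------------------------------------------------------------
# file formats


def read_fasta(path: str | Path, circular: bool = True) -> list[GenomeSequence]:
    return [
        GenomeSequence(rec.id, str(rec.seq).upper(), circular=circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in genomes]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(path: str | Path) -> list[Feature]:
    """Read features from GFF3, using columns 1,3,4,5,7 and the Name attribute.

    Unrecognised feature types are skipped.  An ``mrna_tss`` attribute, when
    present, is parsed as the transcript start of a protein-coding gene.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gf = feature_from_line(line)
            kind = _GFF_TYPE_TO_KIND.get(gf.featuretype)
            if kind is None:
                continue
            name = gf.attributes.get("Name", [gf.id or f"{gf.featuretype}_{gf.start}"])[0]
            mrna_tss = gf.attributes.get("mrna_tss")
            features.append(
                Feature(
                    name=name,
                    kind=kind,
                    start=gf.start,
                    end=gf.end,
                    strand=gf.strand,
                    mrna_tss=int(mrna_tss[0]) if mrna_tss else None,
                )
            )
    return features


def write_gff3(features: Iterable[Feature], ref_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.name};Name={f.name}"
            if f.mrna_tss is not None:
                attrs += f";mrna_tss={f.mrna_tss}"
            fh.write(
                "\t".join(
                    [
                        ref_id,
                        "divtss",
                        _KIND_TO_GFF_TYPE[f.kind],
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_bed6(path: str | Path, kind: str = PREDICTED_TSS) -> list[Feature]:
    """Read a BED6 track (0-based half-open) into 1-based features.

    Intended for predicted-TSS tracks: for multi-base intervals the position
    retained as the feature span is the full interval; downstream code takes
    the strand-aware 5' end.
    """
    features: list[Feature] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"BED6 requires 6 columns, got {len(cols)} on line {i + 1}")
            _, start0, end0, name, _score, strand = cols[:6]
            features.append(
                Feature(name=name, kind=kind, start=int(start0) + 1, end=int(end0), strand=strand)
            )
    return features


def write_bed6(features: Iterable[Feature], ref_id: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{ref_id}\t{f.start - 1}\t{f.end}\t{f.name}\t0\t{f.strand}\n")
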