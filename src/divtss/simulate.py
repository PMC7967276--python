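"""Synthetic desk-scale fixtures with planted ground truth.

The generator emulates the statistical structure of 5'-end-specific RNA-seq
of a bacterial genome: read 5' ends concentrated at planted TSS positions on
both strands with per-condition expression weights, per-replicate depth
variation (so normalization is exercised), a minority of reads carrying 1-2
substitutions (removed by the perfect-match filter), 3'-adapter read-through
contamination, and sub-16-nt fragments (removed by the length filter).  The
default locus plan covers every orientation class (codirected, divergent,
5'-overlapping, convergent), planted TSS shifts of -26 and +60 nt relative
to the annotation, divergent-pair TSS separations spanning 7-290 bp with
median 84, and four REP-element intergenic layouts (read-through, terminator,
poly-T without hairpin, REP without TSS).

Reads are planted exactly at TSS positions (no 5'-end jitter): primary TSSs
of 5'-enriched libraries are single-nucleotide peaks, and exact planting
makes recovery tests sharp.  An alignment oracle writes SAM directly from
read provenance, so no external aligner is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genome import (
    Feature,
    GenomeSequence,
    Interval,
    NCRNA,
    PROTEIN_CODING,
    REP,
    reverse_complement,
    transcript_span,
    overlap_length,
    write_bed6,
    write_fasta,
    write_gff3,
)
from .orientation import (
    CODIRECTED,
    CONVERGENT,
    DIVERGENT,
    OVERLAPPING_5PRIME,
)
from .reads import AlignmentRecord, Read, trim_and_length_filter, write_fastq, write_sam
from .rep import REP_VARIANT_A, find_tn_tracks, hairpin_upstream

DEFAULT_ADAPTER = "AGATCGGAAGA"
DEFAULT_READ_LENGTH = 30

#: transcript-strand hairpin planted in terminator loci: 5-bp stem, 4-nt loop
_HAIRPIN_TRANSCRIPT = "GGCGCCTTGGCGCC"


@dataclass(frozen=True)
class TssSite:
    """One planted transcription start with per-condition expression weights."""

    name: str
    position: int
    strand: str
    weights: dict[str, float]
    feature_name: Optional[str] = None


@dataclass(frozen=True)
class PairPlan:
    """Planted truth for one ncRNA / neighbor-gene pair."""

    ncrna_name: str
    gene_name: str
    arrangement: str
    bona_fide: bool
    antisense_overlap: int
    expected_primary_offset: int
    expected_inter_tss: Optional[int] = None


@dataclass(frozen=True)
class RepLocusPlan:
    """Planted truth for one REP-containing intergenic region."""

    name: str
    igr: tuple[int, int]
    rep_start: int
    tss: Optional[TssSite]
    plant_tn: bool
    plant_hairpin: bool
    tn_start: Optional[int] = None
    expected_distance: Optional[int] = None
    expected_read_through: Optional[bool] = None


@dataclass
class SimulationConfig:
    genome_length: int
    features: list[Feature]
    tss_sites: list[TssSite]
    pairs: list[PairPlan]
    rep_loci: list[RepLocusPlan]
    conditions: dict[str, list[int]]  # label -> replicate read depths
    ref_id: str = "synthetic_chr"
    read_length: int = DEFAULT_READ_LENGTH
    adapter: str = DEFAULT_ADAPTER
    mismatch_read_fraction: float = 0.1
    adapter_contamination_fraction: float = 0.05
    short_read_fraction: float = 0.02

    def __post_init__(self) -> None:
        for frac in (
            self.mismatch_read_fraction,
            self.adapter_contamination_fraction,
            self.short_read_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for site in self.tss_sites:
            if not 1 <= site.position <= self.genome_length:
                raise ValueError(f"planted TSS {site.name} outside the genome")
            if not set(self.conditions) <= set(site.weights):
                raise ValueError(f"site {site.name} weights do not cover all conditions")
        for f in self.features:
            if f.end > self.genome_length:
                raise ValueError(f"planted feature {f.name} outside the genome")


@dataclass(frozen=True)
class ReadOrigin:
    site: TssSite
    n_substitutions: int


@dataclass
class TruthTable:
    sites: pd.DataFrame
    feature_primaries: pd.DataFrame
    pairs: pd.DataFrame
    rep_loci: pd.DataFrame
    replicates: pd.DataFrame


def default_config(**overrides) -> SimulationConfig:
    """The standard ~52-kb desk-scale study design (13 ncRNA/gene pairs in all
    orientation classes, 4 REP loci, 2 conditions x 2 replicates)."""
    g = lambda name, s, e, strand, tss=None: Feature(name, PROTEIN_CODING, s, e, strand, tss)
    nc = lambda name, s, e, strand: Feature(name, NCRNA, s, e, strand)

    features = [
        # P1 codirected (+), duplicated promoters 26 bp apart
        nc("ncA", 2000, 2100, "+"), g("gA", 2600, 3400, "+"),
        # P2 divergent, TSS separation 84
        nc("ncB", 5000, 5100, "-"), g("gB", 5184, 5984, "+"),
        # P3 divergent, true TSS 26 bp upstream of the annotated 5' end
        nc("ncC", 8026, 8140, "+"), g("gC", 7000, 7960, "-"),
        # P4 divergent, true TSS 60 bp downstream of the annotated 5' end
        nc("ncD", 11000, 11105, "-"), g("gD", 11129, 11929, "+"),
        # P5 ncRNA overlapping the neighbor's 5'UTR by 41 bp
        nc("ncE", 13960, 14040, "-"), g("gE", 14100, 14900, "+", 14000),
        # P6 ncRNA contained in the neighbor's transcript over its entire 76 nt
        nc("ncF", 17850, 17925, "+"), g("gF", 17000, 17800, "-", 17950),
        # P7 convergent (tail-to-tail)
        nc("ncG", 20000, 20100, "+"), g("gG", 20400, 21200, "-"),
        # P8-P12 divergent pairs, separations 7 / 290 / 20 / 120 / 200
        nc("ncH", 23000, 23093, "-"), g("gH", 23100, 23900, "+"),
        nc("ncI", 26000, 26080, "-"), g("gI", 26370, 27170, "+"),
        nc("ncJ", 29000, 29090, "-"), g("gJ", 29110, 29910, "+"),
        nc("ncK", 32000, 32100, "-"), g("gK", 32220, 33020, "+"),
        nc("ncL", 35000, 35080, "-"), g("gL", 35280, 36080, "+"),
        # P13 codirected (-), duplicated promoters 71 bp apart
        nc("ncM", 38200, 38300, "-"), g("gM", 37000, 37800, "-"),
        # REP-screen loci: collinear plus-strand gene pairs
        g("rg1a", 41000, 41600, "+"), g("rg1b", 42400, 43000, "+"),
        g("rg2a", 44000, 44600, "+"), g("rg2b", 45400, 46000, "+"),
        g("rg3a", 46800, 47300, "+"), g("rg3b", 48300, 48800, "+"),
        g("rg4a", 49400, 49700, "+"), g("rg4b", 50500, 50900, "+"),
        # planted REP copies, recorded in the annotation for reference
        Feature("REP1", REP, 42000, 42034, "+"),
        Feature("REP2", REP, 44950, 44984, "+"),
        Feature("REP3", REP, 47850, 47884, "+"),
        Feature("REP4", REP, 50050, 50084, "+"),
    ]

    w = lambda e, s: {"exp": float(e), "stat": float(s)}
    rep_tss = {
        "R1": TssSite("rep1_tss", 42200, "-", w(2, 2)),
        "R2": TssSite("rep2_tss", 45200, "-", w(2, 2)),
        "R3": TssSite("rep3_tss", 48100, "-", w(2, 2)),
    }
    sites = [
        TssSite("ncA_p1", 2000, "+", w(4, 1), "ncA"),
        TssSite("ncA_p2", 1974, "+", w(1, 4), "ncA"),
        TssSite("gA_p1", 2600, "+", w(2, 2), "gA"),
        TssSite("ncB_p1", 5100, "-", w(3, 3), "ncB"),
        TssSite("gB_p1", 5184, "+", w(2, 2), "gB"),
        TssSite("ncC_p1", 8000, "+", w(3, 3), "ncC"),
        TssSite("gC_p1", 7960, "-", w(2, 2), "gC"),
        TssSite("ncD_p1", 11045, "-", w(3, 3), "ncD"),
        TssSite("gD_p1", 11129, "+", w(2, 2), "gD"),
        TssSite("ncE_p1", 14040, "-", w(3, 3), "ncE"),
        TssSite("gE_p1", 14000, "+", w(2, 2), "gE"),
        TssSite("ncF_p1", 17850, "+", w(3, 3), "ncF"),
        TssSite("gF_p1", 17950, "-", w(2, 2), "gF"),
        TssSite("ncG_p1", 20000, "+", w(3, 3), "ncG"),
        TssSite("gG_p1", 21200, "-", w(2, 2), "gG"),
        TssSite("ncH_p1", 23093, "-", w(3, 3), "ncH"),
        TssSite("gH_p1", 23100, "+", w(2, 2), "gH"),
        TssSite("ncI_p1", 26080, "-", w(3, 3), "ncI"),
        TssSite("gI_p1", 26370, "+", w(2, 2), "gI"),
        TssSite("ncJ_p1", 29090, "-", w(3, 3), "ncJ"),
        TssSite("gJ_p1", 29110, "+", w(2, 2), "gJ"),
        TssSite("ncK_p1", 32100, "-", w(3, 3), "ncK"),
        TssSite("gK_p1", 32220, "+", w(2, 2), "gK"),
        TssSite("ncL_p1", 35080, "-", w(3, 3), "ncL"),
        TssSite("gL_p1", 35280, "+", w(2, 2), "gL"),
        TssSite("ncM_p1", 38300, "-", w(4, 1), "ncM"),
        TssSite("ncM_p2", 38229, "-", w(1, 4), "ncM"),
        TssSite("gM_p1", 37800, "-", w(2, 2), "gM"),
        TssSite("rg1a_p1", 41000, "+", w(2, 2), "rg1a"),
        TssSite("rg1b_p1", 42400, "+", w(2, 2), "rg1b"),
        TssSite("rg2a_p1", 44000, "+", w(2, 2), "rg2a"),
        TssSite("rg2b_p1", 45400, "+", w(2, 2), "rg2b"),
        TssSite("rg3a_p1", 46800, "+", w(2, 2), "rg3a"),
        TssSite("rg3b_p1", 48300, "+", w(2, 2), "rg3b"),
        TssSite("rg4a_p1", 49400, "+", w(2, 2), "rg4a"),
        TssSite("rg4b_p1", 50500, "+", w(2, 2), "rg4b"),
        rep_tss["R1"],
        rep_tss["R2"],
        rep_tss["R3"],
    ]

    pairs = [
        PairPlan("ncA", "gA", CODIRECTED, True, 0, 0),
        PairPlan("ncB", "gB", DIVERGENT, True, 0, 0, 84),
        PairPlan("ncC", "gC", DIVERGENT, True, 0, -26, 40),
        PairPlan("ncD", "gD", DIVERGENT, True, 0, 60, 84),
        PairPlan("ncE", "gE", OVERLAPPING_5PRIME, False, 41, 0),
        PairPlan("ncF", "gF", OVERLAPPING_5PRIME, False, 76, 0),
        PairPlan("ncG", "gG", CONVERGENT, True, 0, 0),
        PairPlan("ncH", "gH", DIVERGENT, True, 0, 0, 7),
        PairPlan("ncI", "gI", DIVERGENT, True, 0, 0, 290),
        PairPlan("ncJ", "gJ", DIVERGENT, True, 0, 0, 20),
        PairPlan("ncK", "gK", DIVERGENT, True, 0, 0, 120),
        PairPlan("ncL", "gL", DIVERGENT, True, 0, 0, 200),
        PairPlan("ncM", "gM", CODIRECTED, True, 0, 0),
    ]

    # Expected TSS-to-REP distances account for the scanned REP footprint:
    # the planted 35-mer (variant A) always also matches the 36-mer variant B
    # consensus one position downstream with <= 3 mismatches (1 internal plus
    # at most 2 at the tail), so the nearest REP 5' boundary seen by the
    # minus-strand transcript lies 2 nt beyond the planted copy's end.
    rep_loci = [
        RepLocusPlan("R1", (41601, 42399), 42000, rep_tss["R1"], False, False,
                     expected_distance=164, expected_read_through=True),
        RepLocusPlan("R2", (44601, 45399), 44950, rep_tss["R2"], True, True,
                     tn_start=45080, expected_distance=214, expected_read_through=False),
        RepLocusPlan("R3", (47301, 48299), 47850, rep_tss["R3"], True, False,
                     tn_start=47980, expected_distance=214, expected_read_through=True),
        RepLocusPlan("R4", (49701, 50499), 50050, None, False, False),
    ]

    config = SimulationConfig(
        genome_length=52_000,
        features=features,
        tss_sites=sites,
        pairs=pairs,
        rep_loci=rep_loci,
        conditions={"exp": [6000, 9000], "stat": [5000, 7500]},
    )
    return replace(config, **overrides) if overrides else config


# ---------------------------------------------------------------------------
# genome


def _check_no_same_strand_overlap(features: list[Feature]) -> None:
    transcribed = [f for f in features if f.kind in (PROTEIN_CODING, NCRNA)]
    for i, a in enumerate(transcribed):
        for b in transcribed[i + 1 :]:
            if a.strand == b.strand and overlap_length(transcript_span(a), transcript_span(b)) > 0:
                raise ValueError(f"planted features {a.name} and {b.name} overlap on the same strand")


def _plant(seq: list[str], start: int, insert: str) -> None:
    seq[start - 1 : start - 1 + len(insert)] = list(insert)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _constrain_rep_span(
    seq: list[str], locus: RepLocusPlan, transcribed: str, rng: np.random.Generator
) -> None:
    """Rewrite the TSS-to-REP span until its poly-T/hairpin content matches the plan.

    The span between the REP 5' boundary (transcript view) and the planted
    divergent TSS is resampled, the planned poly-T track (a run of 6) and
    hairpin are re-planted, and the package's own detectors are used as
    generation-time validators.
    """
    assert locus.tss is not None and transcribed == "-"
    rep_end = locus.rep_start + len(REP_VARIANT_A) - 1
    lo, hi = rep_end + 1, locus.tss.position - 1
    for _ in range(500):
        _plant(seq, lo, _random_dna(rng, hi - lo + 1))
        if locus.plant_tn:
            _plant(seq, locus.tn_start, "A" * 6)  # T6 on the minus-strand transcript
            if locus.plant_hairpin:
                _plant(seq, locus.tn_start + 6, reverse_complement(_HAIRPIN_TRANSCRIPT))
        span = "".join(seq[lo - 1 : hi])
        tracks = find_tn_tracks(span, strand=transcribed, region_start=lo)
        tn_found = bool(tracks)
        hp_found = any(
            hairpin_upstream("".join(seq), t, strand=transcribed, region_start=1) for t in tracks
        )
        if tn_found == locus.plant_tn and hp_found == locus.plant_hairpin:
            return
    raise RuntimeError(f"could not realise poly-T/hairpin constraints for locus {locus.name}")


def generate_genome(config: SimulationConfig, rng: np.random.Generator) -> tuple[GenomeSequence, list[Feature]]:
    """Random background with planted features and REP loci; deterministic per rng state."""
    _check_no_same_strand_overlap(config.features)
    seq = list(_random_dna(rng, config.genome_length))
    for locus in config.rep_loci:
        _plant(seq, locus.rep_start, REP_VARIANT_A)
        if locus.tss is not None:
            _constrain_rep_span(seq, locus, "-", rng)
    genome = GenomeSequence(config.ref_id, "".join(seq))
    return genome, list(config.features)


# ---------------------------------------------------------------------------
# reads


def _read_sequence(genome: GenomeSequence, site: TssSite, length: int) -> str:
    """First ``length`` transcribed bases starting at the site, strand-aware."""
    if site.strand == "+":
        end = min(site.position + length - 1, len(genome))
        return genome.subseq(site.position, end)
    start = max(1, site.position - length + 1)
    return reverse_complement(genome.subseq(start, site.position))


def generate_reads(
    config: SimulationConfig, genome: GenomeSequence, rng: np.random.Generator
) -> tuple[dict[tuple[str, int], list[Read]], dict[str, ReadOrigin]]:
    """Draw 5'-anchored reads for every condition and replicate.

    Returns the reads keyed by (condition, replicate index) and a provenance
    map from read id to planted origin, consumed by the alignment oracle.
    """
    provenance: dict[str, ReadOrigin] = {}
    out: dict[tuple[str, int], list[Read]] = {}
    bases = "ACGT"
    for cond, depths in config.conditions.items():
        weights = np.array([s.weights[cond] for s in config.tss_sites], dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"no expressed site in condition {cond!r}")
        probs = weights / weights.sum()
        for rep_idx, depth in enumerate(depths):
            if depth == 0:
                raise ValueError("reads_per_replicate must be positive")
            reads: list[Read] = []
            counts = rng.multinomial(depth, probs)
            serial = 0
            for site, n_reads in zip(config.tss_sites, counts):
                for _ in range(n_reads):
                    read_id = f"{cond}_r{rep_idx + 1}_{serial:06d}"
                    serial += 1
                    u = rng.random()
                    if u < config.short_read_fraction:
                        genome_len = 10
                    elif u < config.short_read_fraction + config.adapter_contamination_fraction:
                        genome_len = config.read_length - len(config.adapter)
                    else:
                        genome_len = config.read_length
                    seq = _read_sequence(genome, site, genome_len)
                    n_subs = 0
                    if rng.random() < config.mismatch_read_fraction:
                        n_subs = int(rng.integers(1, 3))
                        seq_list = list(seq)
                        for pos in rng.choice(len(seq_list), size=min(n_subs, len(seq_list)), replace=False):
                            old = seq_list[pos]
                            seq_list[pos] = bases[(bases.index(old) + int(rng.integers(1, 4))) % 4]
                        n_subs = sum(1 for a, b in zip(seq, seq_list) if a != b)
                        seq = "".join(seq_list)
                    if genome_len < config.read_length:
                        filler = config.adapter + _random_dna(rng, config.read_length)
                        seq = (seq + filler)[: config.read_length]
                    reads.append(Read(read_id, seq, "I" * len(seq)))
                    provenance[read_id] = ReadOrigin(site, n_subs)
            out[(cond, rep_idx)] = reads
    return out, provenance


def generate_alignments(
    reads: list[Read],
    genome: GenomeSequence,
    provenance: dict[str, ReadOrigin],
) -> list[AlignmentRecord]:
    """Alignment oracle: emit SAM records from planted provenance.

    Reads are assumed already adapter-trimmed and length-filtered, so the
    whole retained sequence is genome-derived.  ``NM``/``XM`` tags reflect
    planted substitutions.
    """
    records: list[AlignmentRecord] = []
    for read in reads:
        origin = provenance.get(read.id)
        if origin is None:
            raise ValueError(f"read {read.id} has no recorded provenance")
        length = len(read.seq)
        if length < 1:
            raise ValueError(f"read {read.id} is empty after trimming")
        site = origin.site
        if site.strand == "+":
            pos, flag = site.position, 0
        else:
            pos, flag = site.position - length + 1, 16
        records.append(
            AlignmentRecord(
                read_id=read.id,
                flag=flag,
                ref_id=genome.id,
                pos=pos,
                cigar=f"{length}M",
                tags={"NM": origin.n_substitutions, "XM": origin.n_substitutions},
            )
        )
    return records


# ---------------------------------------------------------------------------
# truth table and fixture writing


def truth_table(config: SimulationConfig) -> TruthTable:
    sites = pd.DataFrame(
        [
            {
                "site": s.name,
                "feature": s.feature_name,
                "position": s.position,
                "strand": s.strand,
                **{f"weight_{c}": s.weights[c] for c in config.conditions},
            }
            for s in config.tss_sites
        ]
    )
    primaries = []
    by_feature: dict[str, list[TssSite]] = {}
    for s in config.tss_sites:
        if s.feature_name:
            by_feature.setdefault(s.feature_name, []).append(s)
    for fname, fsites in by_feature.items():
        for cond in config.conditions:
            primary = max(fsites, key=lambda s: s.weights[cond])
            primaries.append(
                {
                    "feature": fname,
                    "condition": cond,
                    "expected_positions": ";".join(
                        str(s.position) for s in fsites if s.weights[cond] > 0
                    ),
                    "expected_primary": primary.position,
                }
            )
    pairs = pd.DataFrame(
        [
            {
                "ncrna": p.ncrna_name,
                "gene": p.gene_name,
                "arrangement": p.arrangement,
                "bona_fide": p.bona_fide,
                "antisense_overlap": p.antisense_overlap,
                "expected_primary_offset": p.expected_primary_offset,
                "expected_inter_tss": p.expected_inter_tss,
            }
            for p in config.pairs
        ]
    )
    rep_loci = pd.DataFrame(
        [
            {
                "locus": r.name,
                "igr_start": r.igr[0],
                "igr_end": r.igr[1],
                "rep_start": r.rep_start,
                "rep_end": r.rep_start + len(REP_VARIANT_A) - 1,
                "tss_position": r.tss.position if r.tss else None,
                "tn_track": r.plant_tn,
                "hairpin": r.plant_hairpin,
                "tss_to_rep_distance": r.expected_distance,
                "read_through": r.expected_read_through,
            }
            for r in config.rep_loci
        ]
    )
    replicates = pd.DataFrame(
        [
            {"condition": cond, "replicate": i + 1, "intended_reads": depth}
            for cond, depths in config.conditions.items()
            for i, depth in enumerate(depths)
        ]
    )
    return TruthTable(sites, pd.DataFrame(primaries), pairs, rep_loci, replicates)


@dataclass
class Fixture:
    """An in-memory or on-disk realisation of one simulated study."""

    config: SimulationConfig
    genome: GenomeSequence
    features: list[Feature]
    reads: dict[tuple[str, int], list[Read]]
    processed_reads: dict[tuple[str, int], list[Read]]
    provenance: dict[str, ReadOrigin]
    alignments: dict[tuple[str, int], list[AlignmentRecord]]
    truth: TruthTable
    paths: dict[str, object] = field(default_factory=dict)


def simulate(config: SimulationConfig, seed: int) -> Fixture:
    """Generate genome, reads and oracle alignments; fully determined by seed."""
    rng = np.random.default_rng(seed)
    genome, features = generate_genome(config, rng)
    raw_reads, provenance = generate_reads(config, genome, rng)
    alignments = {}
    processed = {}
    for key, reads in raw_reads.items():
        surviving, _stats = trim_and_length_filter(reads, config.adapter)
        processed[key] = surviving
        alignments[key] = generate_alignments(surviving, genome, provenance)
    return Fixture(
        config, genome, features, raw_reads, processed, provenance, alignments, truth_table(config)
    )


def write_fixture(config: SimulationConfig, seed: int, outdir: str | Path) -> Fixture:
    """Materialise a fixture on disk: FASTA, GFF3, predicted-TSS BED, per-replicate
    FASTQ and SAM, and the truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = simulate(config, seed)
    paths: dict[str, object] = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "predicted_tss": outdir / "predicted_tss.bed",
    }
    write_fasta([fx.genome], paths["genome"])
    write_gff3(fx.features, fx.genome.id, paths["annotation"])
    predicted = [
        Feature(s.name, "predicted_TSS", s.position, s.position, s.strand)
        for s in config.tss_sites
    ]
    write_bed6(predicted, fx.genome.id, paths["predicted_tss"])
    sam_paths: dict[str, list[Path]] = {}
    for (cond, rep_idx), reads in fx.reads.items():
        fq = outdir / f"{cond}_rep{rep_idx + 1}.fastq"
        write_fastq(reads, fq)
        sam = outdir / f"{cond}_rep{rep_idx + 1}.sam"
        seqs = {r.id: r.seq for r in fx.processed_reads[(cond, rep_idx)]}
        write_sam(fx.alignments[(cond, rep_idx)], fx.genome.id, len(fx.genome), sam, seqs=seqs)
        sam_paths.setdefault(cond, []).append(sam)
    for name, df in (
        ("truth_sites", fx.truth.sites),
        ("truth_feature_primaries", fx.truth.feature_primaries),
        ("truth_pairs", fx.truth.pairs),
        ("truth_rep_loci", fx.truth.rep_loci),
        ("truth_replicates", fx.truth.replicates),
    ):
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    paths["sam"] = sam_paths
    fx.paths = paths
    return fx
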