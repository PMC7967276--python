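"""REP motif scanning, poly-T tracks, hairpins, and the read-through screen."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divtss.genome import Feature, GenomeSequence, Interval, reverse_complement
from divtss.pileup import FivePrimeTrack
from divtss.rep import (
    IUPAC_SETS,
    REP_VARIANT_A,
    REP_VARIANT_B,
    RepConsensus,
    RepScanParams,
    builtin_consensuses,
    find_tn_tracks,
    hairpin_upstream,
    rep_transcription_report,
    scan_rep,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle

from oracles import brute_force_scan


def _plant(background, pos0, motif):
    return background[:pos0] + motif + background[pos0 + len(motif) :]


CONSENSUS_A0 = RepConsensus("a0", REP_VARIANT_A, 0)


def test_scan_rep_exact_plant_both_strands():
    rng = np.random.default_rng(7)
    bg = "".join(rng.choice(list("ACGT"), size=400))
    seq = _plant(bg, 100, REP_VARIANT_A)
    hits = scan_rep(seq, CONSENSUS_A0)
    assert [(m.start, m.strand, m.mismatches) for m in hits] == [(101, "+", 0)]

    seq_rc = _plant(bg, 100, reverse_complement(REP_VARIANT_A))
    hits_rc = scan_rep(seq_rc, CONSENSUS_A0)
    assert [(m.start, m.strand) for m in hits_rc] == [(101, "-")]


def test_scan_rep_mismatch_tolerance():
    rng = np.random.default_rng(11)
    bg = "".join(rng.choice(list("ACGT"), size=300))
    mutated = list(REP_VARIANT_A)
    mutated[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[10]]
    seq = _plant(bg, 50, "".join(mutated))
    assert scan_rep(seq, CONSENSUS_A0) == []
    hits = scan_rep(seq, RepConsensus("a1", REP_VARIANT_A, 1))
    assert [(m.start, m.mismatches) for m in hits] == [(51, 1)]


def test_scan_rep_degenerate_consensus_and_coordinates():
    cons = RepConsensus("deg", "GCKGATGGCGRGCK", 0)
    seq = "TTTT" + "GCTGATGGCGAGCG" + "TTTT"
    hits = scan_rep(seq, cons, region_start=1001)
    plus = [m for m in hits if m.strand == "+"]
    assert [(m.start, m.end) for m in plus] == [(1005, 1018)]


def test_scan_rep_n_matches_only_pattern_n():
    cons = RepConsensus("pat", "ACGTACGTAC", 0)
    assert scan_rep("ACGTNCGTAC", cons) == []
    cons_n = RepConsensus("patn", "ACGTNCGTAC", 0)
    assert [(m.start, m.strand) for m in scan_rep("ACGTNCGTAC", cons_n) if m.strand == "+"] == [(1, "+")]


@given(st.integers(0, 2**31 - 1))
@settings(derandomize=True, max_examples=15)
def test_scan_rep_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    seq = _plant("".join(rng.choice(list("ACGT"), size=800)), 200, REP_VARIANT_A)
    for cons in (
        RepConsensus("a3", REP_VARIANT_A, 3),
        RepConsensus("b3", REP_VARIANT_B, 3),
        RepConsensus("deg", "GCKGATGGCGRGCKNNRCGYCTTATCMGGCCTAC", 3),
    ):
        got = sorted((m.start, m.end, m.strand, m.mismatches) for m in scan_rep(seq, cons))
        assert got == brute_force_scan(seq, cons.pattern, cons.max_mismatches)


def test_scan_rep_strand_symmetry():
    rng = np.random.default_rng(5)
    seq = _plant("".join(rng.choice(list("ACGT"), size=500)), 120, REP_VARIANT_A)
    fwd = scan_rep(seq, RepConsensus("a2", REP_VARIANT_A, 2))
    rev = scan_rep(reverse_complement(seq), RepConsensus("a2", REP_VARIANT_A, 2))
    n = len(seq)
    mirrored = sorted(
        (n + 1 - m.end, n + 1 - m.start, {"+": "-", "-": "+"}[m.strand], m.mismatches)
        for m in rev
    )
    assert mirrored == sorted((m.start, m.end, m.strand, m.mismatches) for m in fwd)


# ---------------------------------------------------------------------------
# poly-T tracks and hairpins


@pytest.mark.parametrize(
    "seq,min_run,expected",
    [
        ("ACTTTTTGA", 4, [(3, 7)]),
        ("ACTTTGA", 4, []),
        ("TTTTTTTT", 4, [(1, 8)]),  # one maximal run, no sub-runs
        ("TTTTATTTT", 4, [(1, 4), (6, 9)]),
    ],
)
def test_find_tn_tracks_plus(seq, min_run, expected):
    tracks = find_tn_tracks(seq, min_run)
    assert [(t.start, t.end) for t in tracks] == expected


def test_find_tn_tracks_minus_strand_reads_a_runs():
    # transcription on minus: RNA T corresponds to genome-plus A
    tracks = find_tn_tracks("GCAAAAAGC", 4, strand="-", region_start=100)
    assert [(t.start, t.end, t.strand) for t in tracks] == [(102, 106, "-")]


@given(st.text(alphabet="ACGT", min_size=1, max_size=120))
@settings(derandomize=True)
def test_tn_tracks_maximal_and_disjoint(seq):
    tracks = find_tn_tracks(seq, 4)
    for t in tracks:
        assert set(seq[t.start - 1 : t.end]) == {"T"}
        # maximality: flanks are not T
        assert t.start == 1 or seq[t.start - 2] != "T"
        assert t.end == len(seq) or seq[t.end] != "T"
    for a, b in zip(tracks, tracks[1:]):
        assert a.end < b.start


def test_hairpin_upstream_examples():
    # GGCGC TTTT GCGCC immediately before a T track: 5-bp stem, 4-nt loop
    seq = "AC" + "GGCGC" + "TTTT" + "GCGCC" + "TTTTTT" + "GACGTA"
    track = Interval(17, 22, "+")
    assert hairpin_upstream(seq, track, min_stem=4, max_loop=8, search_window=14)
    # poly-A window: no self-complementarity
    seq_a = "A" * 20 + "TTTTTT"
    assert not hairpin_upstream(seq_a, Interval(21, 26, "+"), search_window=20)
    # stem below the threshold
    seq_short = "AC" + "GGC" + "TTTT" + "GCC" + "TTTTTT" + "GACGTA"
    assert not hairpin_upstream(seq_short, Interval(13, 18, "+"), min_stem=4, search_window=10)


def test_hairpin_upstream_minus_strand():
    # minus-strand transcript: upstream window lies to the genomic right
    hairpin_genome = reverse_complement("GGCGC" + "TTTA" + "GCGCC")
    seq = "GG" + "AAAAAA" + hairpin_genome + "CCAA"
    track = Interval(3, 8, "-")
    assert hairpin_upstream(seq, track, strand="-", search_window=14)
    assert not hairpin_upstream("GG" + "AAAAAA" + "T" * 18, Interval(3, 8, "-"), strand="-")


# ---------------------------------------------------------------------------
# locus report


def _screen_genome(seed, span_builder):
    """A tiny locus: geneL(+) .. IGR .. geneR(+), REP planted inside the IGR."""
    rng = np.random.default_rng(seed)
    bg = "".join(rng.choice(list("ACGT"), size=1500))
    seq = _plant(bg, 999, REP_VARIANT_A)  # REP at 1000..1034
    seq = span_builder(seq)
    genome = GenomeSequence("chr", seq)
    annotation = [
        Feature("gL", "protein_coding", 100, 800, "+"),
        Feature("gR", "protein_coding", 1350, 1480, "+"),
    ]
    return genome, annotation


def _track_with_minus_tss(pos, height=20.0):
    return FivePrimeTrack("chr", {}, {pos: height}, 100)


def test_rep_report_read_through_when_no_terminator():
    def clean_span(seq):  # no A runs between REP end and TSS
        span = ("GC" * 200)[: 1200 - 1037]
        return seq[:1036] + span + seq[1036 + len(span) :]

    genome, annotation = _screen_genome(3, clean_span)
    report = rep_transcription_report(
        Interval(801, 1349), annotation, genome, _track_with_minus_tss(1200),
        [CONSENSUS_A0], RepScanParams()
    )
    assert report.transcribed_strand == "-"
    assert report.divergent_tss.position == 1200
    assert report.tss_to_rep_distance == 1200 - 1034
    assert report.tn_tracks == [] and report.read_through is True


def test_rep_report_terminator_blocks_read_through():
    def terminator_span(seq):
        # transcript order TSS -> hairpin -> T6 -> REP; genome: A6 then hairpin
        hairpin = reverse_complement("GGCGC" + "TTCG" + "GCGCC")
        insert = "AAAAAA" + hairpin
        filler = ("GC" * 200)[: 1200 - 1037 - len(insert) - 40]
        span = ("GC" * 20)[:40] + insert + filler
        return seq[:1036] + span + seq[1036 + len(span) :]

    genome, annotation = _screen_genome(3, terminator_span)
    report = rep_transcription_report(
        Interval(801, 1349), annotation, genome, _track_with_minus_tss(1200),
        [CONSENSUS_A0], RepScanParams()
    )
    assert len(report.tn_tracks) >= 1
    assert report.hairpin_upstream_of_tn is True
    assert report.read_through is False


def test_rep_report_without_tss_or_flanks():
    genome, annotation = _screen_genome(3, lambda s: s)
    report = rep_transcription_report(
        Interval(801, 1349), annotation, genome, FivePrimeTrack("chr", {}, {}, 0),
        [CONSENSUS_A0], RepScanParams()
    )
    assert report.divergent_tss is None
    assert report.tss_to_rep_distance is None and report.read_through is None
    with pytest.raises(ValueError, match="not flanked"):
        rep_transcription_report(
            Interval(1, 50), annotation, genome, FivePrimeTrack("chr", {}, {}, 0),
            [CONSENSUS_A0], RepScanParams()
        )


def test_planted_rep_loci_recovered(noise_free_fixture, pipeline_result):
    """Every planted REP locus flag (TSS presence, distance, poly-T, hairpin,
    read-through verdict) is recovered by the pipeline screen."""
    truth = noise_free_fixture.truth.rep_loci
    got = pipeline_result.rep_report.set_index("igr_start")
    assert len(got) == len(truth)
    for _, row in truth.iterrows():
        out = got.loc[row["igr_start"]]
        if row["tss_position"] == row["tss_position"]:  # not NaN
            assert out["divergent_tss"] == row["tss_position"]
            assert out["tss_to_rep_distance"] == row["tss_to_rep_distance"]
            assert bool(out["n_tn_tracks"] > 0) == bool(row["tn_track"])
            assert bool(out["hairpin_upstream_of_tn"]) == bool(row["hairpin"])
            assert bool(out["read_through"]) == bool(row["read_through"])
        else:
            assert out["divergent_tss"] != out["divergent_tss"]  # NaN


def test_builtin_consensuses_shapes():
    names = {c.name for c in builtin_consensuses()}
    assert {"rep_35mer_a", "rep_36mer_b"} <= names
    spacered = [c for c in builtin_consensuses() if c.name.startswith("rep_consensus_s")]
    assert sorted(len(c.pattern) for c in spacered) == [32, 33, 34, 35]
    with pytest.raises(ValueError):
        RepConsensus("bad", "ACGTZ" * 3, 0)
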