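"""Orientation taxonomy, antisense overlap, inter-TSS distance statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divtss.genome import Feature
from divtss.orientation import (
    CODIRECTED,
    CONVERGENT,
    DIVERGENT,
    OVERLAPPING_5PRIME,
    ArrangementCall,
    antisense_overlap_length,
    classify_arrangement,
    inter_tss_distance,
    is_bona_fide,
    nearest_neighbor,
    summarize_distances,
)


def _nc(start, end, strand, name="nc"):
    return Feature(name, "ncRNA", start, end, strand)


def _gene(start, end, strand, name="g", mrna_tss=None):
    return Feature(name, "protein_coding", start, end, strand, mrna_tss)


def test_nearest_neighbor_selection():
    nc = _nc(1000, 1100, "+")
    only = _gene(5000, 6000, "+", "only")
    assert nearest_neighbor(nc, [nc, only]) is only
    # closest transcript 5' end wins among several
    near = _gene(1150, 2000, "+", "near")
    far = _gene(1900, 3000, "+", "far")  # 5' at 1900
    farther = _gene(100, 900, "-", "farther")  # 5' at 900 -> distance 100
    assert nearest_neighbor(nc, [nc, near, far, farther]).name == "farther"
    with pytest.raises(ValueError):
        nearest_neighbor(nc, [nc])


def test_nearest_neighbor_tie_goes_upstream():
    nc = _nc(1000, 1100, "+")
    upstream = _gene(500, 950, "+", "up")  # 5' at 500, distance 500
    downstream = _gene(1500, 2100, "+", "down")  # 5' at 1500, distance 500
    assert nearest_neighbor(nc, [upstream, downstream]).name == "up"


@pytest.mark.parametrize(
    "nc,gene,expected",
    [
        (_nc(3000, 3100, "-"), _gene(3200, 4000, "+"), DIVERGENT),
        (_nc(100, 200, "+"), _gene(300, 900, "+"), CODIRECTED),
        (_nc(100, 200, "+"), _gene(400, 900, "-"), CONVERGENT),
    ],
)
def test_classify_arrangement_basic(nc, gene, expected):
    call = classify_arrangement(nc, gene)
    assert call.arrangement == expected
    assert call.bona_fide and call.antisense_overlap == 0


def test_classify_arrangement_5utr_overlap():
    """A divergent gene's long 5'UTR turns a nearby ncRNA into an antisense RNA."""
    nc = _nc(60, 140, "-")
    gene = _gene(200, 900, "+", mrna_tss=100)
    call = classify_arrangement(nc, gene)
    assert call.arrangement == OVERLAPPING_5PRIME
    assert call.antisense_overlap == 41  # shared transcript span 100..140
    assert not call.bona_fide


def test_bona_fide_consistency_constraint():
    with pytest.raises(ValueError):
        ArrangementCall(_nc(1, 10, "+"), _gene(5, 20, "-"), OVERLAPPING_5PRIME, True, 6)


@given(
    st.integers(1, 40),
    st.integers(1, 15),
    st.integers(1, 40),
    st.integers(1, 15),
    st.sampled_from(["+", "-"]),
    st.sampled_from(["+", "-"]),
)
@settings(derandomize=True, max_examples=300)
def test_classification_total_and_mirror_invariant(s1, l1, s2, l2, st1, st2):
    """Every coordinate/strand layout maps to exactly one arrangement, and the
    label is invariant under genome mirroring (reflection + strand flip)."""
    nc, gene = _nc(s1, s1 + l1, st1), _gene(s2, s2 + l2, st2)
    call = classify_arrangement(nc, gene)
    assert call.arrangement in {CODIRECTED, DIVERGENT, OVERLAPPING_5PRIME, CONVERGENT}
    if call.bona_fide:
        assert call.antisense_overlap == 0

    length = 200
    flip = {"+": "-", "-": "+"}
    m_nc = _nc(length + 1 - nc.end, length + 1 - nc.start, flip[nc.strand])
    m_gene = _gene(length + 1 - gene.end, length + 1 - gene.start, flip[gene.strand])
    assert classify_arrangement(m_nc, m_gene).arrangement == call.arrangement


def test_is_bona_fide_against_whole_annotation():
    nc = _nc(1000, 1080, "+")
    annotation = [nc, _gene(2000, 3000, "+"), _gene(500, 900, "-")]
    assert is_bona_fide(nc, annotation)
    annotation.append(_gene(1500, 2500, "-", "utr_gene", mrna_tss=2600))
    assert is_bona_fide(nc, annotation)  # transcript span 1500..2600 misses 1000..1080
    annotation.append(_gene(1050, 1900, "-", "overlapper"))
    assert not is_bona_fide(nc, annotation)


def test_antisense_overlap_containment_and_refinement():
    gene = _gene(200, 900, "+", mrna_tss=100)
    inside = _nc(300, 375, "-")
    assert antisense_overlap_length(inside, gene) == 76  # entire ncRNA length
    disjoint = _nc(2000, 2100, "-")
    assert antisense_overlap_length(disjoint, gene) == 0
    # a refined upstream ncRNA TSS can only grow the duplex
    nc = _nc(60, 140, "-")
    base = antisense_overlap_length(nc, gene)
    extended = antisense_overlap_length(nc, gene, ncrna_tss=180)
    assert base == 41 and extended == 81 and extended >= base
    with pytest.raises(ValueError, match="opposite strands"):
        antisense_overlap_length(_nc(1, 10, "+"), _gene(20, 40, "+"))


def test_inter_tss_distance_rules():
    div = classify_arrangement(_nc(3000, 3100, "-"), _gene(3200, 4000, "+"))
    assert inter_tss_distance(div, 100, 184) == 84
    assert inter_tss_distance(div, 100, 107) == 7
    assert inter_tss_distance(div, 250, 250) == 0
    codir = classify_arrangement(_nc(100, 200, "+"), _gene(300, 900, "+"))
    with pytest.raises(ValueError, match="divergent"):
        inter_tss_distance(codir, 1, 2)


def _div_call(dist):
    return ArrangementCall(
        _nc(3000, 3100, "-"), _gene(3200, 4000, "+"), DIVERGENT, True, 0, dist
    )


def test_summarize_distances():
    summ = summarize_distances([_div_call(d) for d in (7, 84, 290)])
    assert (summ.min, summ.median, summ.max, summ.n_pairs) == (7, 84, 290, 3)
    assert summarize_distances([_div_call(d) for d in (10, 20)]).median == 15
    single = summarize_distances([_div_call(42)])
    assert single.min == single.median == single.max == 42
    with pytest.raises(ValueError):
        summarize_distances([])


def test_planted_arrangements_recovered(noise_free_fixture, pipeline_result):
    """The pipeline recovers every planted orientation label, bona-fide flag,
    antisense overlap and refined inter-TSS distance."""
    truth = noise_free_fixture.truth.pairs.set_index("ncrna")
    got = pipeline_result.arrangements.set_index("ncrna")
    for name, row in truth.iterrows():
        out = got.loc[name]
        assert out["neighbor"] == row["gene"]
        assert out["arrangement"] == row["arrangement"]
        assert bool(out["bona_fide_vs_annotation"]) == bool(row["bona_fide"])
        assert out["antisense_overlap"] == row["antisense_overlap"]
        if row["expected_inter_tss"] == row["expected_inter_tss"]:  # not NaN
            assert out["inter_tss_distance"] == row["expected_inter_tss"]
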