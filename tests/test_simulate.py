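"""Synthetic-data generator: determinism, planted structure, alignment oracle."""

import numpy as np
import pytest

from divtss.genome import Feature, five_prime_end, reverse_complement
from divtss.pileup import build_track, normalization_coefficients
from divtss.reads import Read
from divtss.simulate import (
    ReadOrigin,
    SimulationConfig,
    TssSite,
    default_config,
    generate_alignments,
    generate_genome,
    generate_reads,
    simulate,
    write_fixture,
)


def _mini_config(**overrides):
    """A 3-kb two-site design used for focused generator tests."""
    sites = [
        TssSite("s_plus", 500, "+", {"c": 3.0}, "ncX"),
        TssSite("s_minus", 2200, "-", {"c": 1.0}, "gX"),
    ]
    features = [
        Feature("ncX", "ncRNA", 500, 600, "+"),
        Feature("gX", "protein_coding", 1900, 2200, "-"),
    ]
    base = dict(
        genome_length=3000,
        features=features,
        tss_sites=sites,
        pairs=[],
        rep_loci=[],
        conditions={"c": [400]},
        mismatch_read_fraction=0.0,
        adapter_contamination_fraction=0.0,
        short_read_fraction=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def test_fixture_determinism_byte_identical(tmp_path):
    cfg = default_config(mismatch_read_fraction=0.0)
    fx1 = write_fixture(cfg, 42, tmp_path / "a")
    fx2 = write_fixture(cfg, 42, tmp_path / "b")
    for name in ("genome.fa", "annotation.gff3", "exp_rep1.fastq", "stat_rep2.sam"):
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
    fx3 = simulate(cfg, 43)
    assert fx3.genome.seq != fx1.genome.seq


def test_planted_divergent_separation_in_annotation():
    cfg = default_config()
    by_name = {f.name: f for f in cfg.features}
    sites = {s.name: s for s in cfg.tss_sites}
    # the separation-84 divergent pair is planted at TSS distance 84
    assert abs(sites["ncB_p1"].position - sites["gB_p1"].position) == 84
    assert five_prime_end(by_name["ncB"]) == sites["ncB_p1"].position


def test_background_only_genome():
    cfg = _mini_config(features=[], tss_sites=[], conditions={"c": [10]})
    with pytest.raises(ValueError):
        # no expressed site: reads cannot be drawn
        simulate(cfg, 1)
    genome, features = generate_genome(cfg, np.random.default_rng(1))
    assert len(genome.seq) == 3000 and features == []


def test_same_strand_overlap_rejected():
    overlapping = [
        Feature("a", "ncRNA", 100, 200, "+"),
        Feature("b", "protein_coding", 150, 400, "+"),
    ]
    cfg = _mini_config(features=overlapping, tss_sites=[], conditions={"c": [10]})
    with pytest.raises(ValueError, match="overlap"):
        generate_genome(cfg, np.random.default_rng(1))


def test_reads_follow_weights_and_depths():
    cfg = _mini_config()
    fx = simulate(cfg, 7)
    reads = fx.reads[("c", 0)]
    assert len(reads) == 400
    by_site = {"s_plus": 0, "s_minus": 0}
    for r in reads:
        by_site[fx.provenance[r.id].site.name] += 1
    # weights 3:1 -> roughly three quarters from the plus site
    assert 0.65 < by_site["s_plus"] / 400 < 0.85
    # pileup maximum sits at the planted positions
    track = build_track(fx.alignments[("c", 0)])
    assert max(track.counts_plus, key=track.counts_plus.get) == 500
    assert max(track.counts_minus, key=track.counts_minus.get) == 2200


def test_mismatch_fraction_zero_means_all_perfect():
    fx = simulate(_mini_config(), 3)
    assert all(o.n_substitutions == 0 for o in fx.provenance.values())
    assert all(
        rec.tags["NM"] == 0 and rec.tags["XM"] == 0
        for recs in fx.alignments.values()
        for rec in recs
    )


def test_depth_ratio_drives_coefficients():
    cfg = _mini_config(conditions={"c": [100, 200]})
    fx = simulate(cfg, 5)
    n = [len(fx.reads[("c", 0)]), len(fx.reads[("c", 1)])]
    assert n == [100, 200]
    assert normalization_coefficients(n) == [1.5, 0.75]


def test_alignment_oracle_coordinates():
    cfg = _mini_config()
    genome, _ = generate_genome(cfg, np.random.default_rng(9))
    plus_site = cfg.tss_sites[0]
    minus_site = cfg.tss_sites[1]
    reads = [
        Read("p", genome.subseq(500, 519)),
        Read("m", reverse_complement(genome.subseq(100, 119))),
    ]
    provenance = {
        "p": ReadOrigin(plus_site, 0),
        "m": ReadOrigin(TssSite("m5p", 119, "-", {"c": 1.0}), 1),
    }
    recs = generate_alignments(reads, genome, provenance)
    assert (recs[0].pos, recs[0].flag, recs[0].cigar) == (500, 0, "20M")
    assert recs[0].tags == {"NM": 0, "XM": 0}
    # minus-strand read with planted 5' end 119, length 20 -> pos 100, flag 16
    assert (recs[1].pos, recs[1].flag) == (100, 16)
    assert recs[1].tags == {"NM": 1, "XM": 1}
    with pytest.raises(ValueError, match="provenance"):
        generate_alignments([Read("ghost", "ACGT" * 5)], genome, provenance)


def test_contamination_fractions_exercise_filters():
    cfg = _mini_config(
        adapter_contamination_fraction=0.2,
        short_read_fraction=0.1,
        conditions={"c": [2000]},
    )
    fx = simulate(cfg, 11)
    raw = fx.reads[("c", 0)]
    processed = fx.processed_reads[("c", 0)]
    # short-fragment reads are removed, adapter-trimmed reads survive shortened
    assert len(processed) < len(raw)
    n_short = len(raw) - len(processed)
    assert 0.05 < n_short / len(raw) < 0.15
    trimmed_lengths = {len(r.seq) for r in processed}
    assert trimmed_lengths <= {19, 30}
    # every surviving read still maps with its full retained length
    for rec, read in zip(fx.alignments[("c", 0)], processed):
        assert rec.cigar == f"{len(read.seq)}M"


def test_generator_invariants_on_default_design(noise_free_fixture):
    fx = noise_free_fixture
    truth = fx.truth
    assert len(truth.pairs) >= 12
    assert set(truth.pairs["arrangement"]) == {
        "codirected", "divergent", "overlapping_5prime", "convergent"
    }
    # intended depths realised exactly
    for (cond, idx), reads in fx.reads.items():
        intended = truth.replicates.query("condition == @cond and replicate == @idx + 1")
        assert len(reads) == int(intended["intended_reads"].iloc[0])
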