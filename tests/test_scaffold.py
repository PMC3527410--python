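import random

import pytest

from htspeg.mapping import Hit, MapResult, classify_pair
from htspeg.scaffold import (
    LinkBundle,
    ScaffoldParams,
    assembly_stats,
    build_superscaffolds,
    bundle_links,
    emit,
    n50_gain,
    parse_agp,
)
from htspeg.seqio import GenomicInterval, SeqRecord, revcomp

from conftest import random_dna


def _result(end_id, scaffold, start, end, strand, unique="unique"):
    hit = Hit(end_id, GenomicInterval(scaffold, start, end, strand), 1.0,
              end - start, end - start, end - start)
    return MapResult(end_id, (hit,), hit, unique)


def _cross_pair(pid, sa, pos_a, strand_a, sb, pos_b, strand_b, unique="unique"):
    return classify_pair(
        pid,
        _result(f"{pid}/L", sa, pos_a, pos_a + 100, strand_a, unique),
        _result(f"{pid}/R", sb, pos_b, pos_b + 100, strand_b, unique),
    )


LENGTHS = {"s1": 50_000, "s2": 60_000, "s3": 40_000}
INSERT = 95_000.0


def test_concordant_links_form_one_bundle():
    # three pairs all say: right end of s1 meets left end of s2
    mappings = [
        _cross_pair(f"p{i}", "s1", 40_000 + i * 100, "+", "s2", 45_000 + i * 100, "+")
        for i in range(3)
    ]
    bundles = bundle_links(mappings, LENGTHS, INSERT)
    assert len(bundles) == 1
    b = bundles[0]
    assert (b.scaffold_a, b.scaffold_b) == ("s1", "s2")
    assert b.joint_orientation == ("R", "L")
    assert b.support == 3


def test_single_link_is_not_enough():
    mappings = [_cross_pair("p0", "s1", 40_000, "+", "s2", 45_000, "+")]
    assert bundle_links(mappings, LENGTHS, INSERT) == []


def test_conflicting_orientations_split_and_die():
    mappings = [
        _cross_pair("p0", "s1", 40_000, "+", "s2", 45_000, "+"),
        _cross_pair("p1", "s1", 40_000, "-", "s2", 45_000, "+"),  # different class
    ]
    assert bundle_links(mappings, LENGTHS, INSERT) == []


def test_non_unique_pairs_excluded_by_default():
    mappings = [
        _cross_pair(f"p{i}", "s1", 40_000, "+", "s2", 45_000, "+", unique="multiple")
        for i in range(3)
    ]
    assert bundle_links(mappings, LENGTHS, INSERT) == []
    loose = ScaffoldParams(unique_only=False)
    assert len(bundle_links(mappings, LENGTHS, INSERT, loose)) == 1


def test_gap_estimate_geometry():
    # hits 5 kb from the facing end of each scaffold -> gap = insert - 5k - 5.1k
    mappings = [
        _cross_pair(f"p{i}", "s1", 45_000, "+", "s2", 5_000, "+") for i in range(2)
    ]
    (b,) = bundle_links(mappings, LENGTHS, INSERT)
    assert b.median_gap == pytest.approx(INSERT - 5_000 - 5_100)


def test_grossly_negative_gap_discarded():
    mappings = [_cross_pair(f"p{i}", "s1", 1_000, "+", "s2", 55_000, "+") for i in range(2)]
    # d_a = 49k, d_b = 55.1k -> gap ~ -9.1k > -47.5k: kept
    assert len(bundle_links(mappings, LENGTHS, INSERT)) == 1
    tight = ScaffoldParams(neg_gap_factor=0.05)
    assert bundle_links(mappings, LENGTHS, INSERT, tight) == []


def _bundle(a, ea, b, eb, support=2, gap=500):
    return LinkBundle(a, b, (ea, eb), support, tuple([gap] * support))


def test_chain_of_three():
    bundles = [_bundle("s1", "R", "s2", "L"), _bundle("s2", "R", "s3", "L")]
    chains = build_superscaffolds(bundles, ["s1", "s2", "s3"])
    assert len(chains) == 1
    assert [c[:2] for c in chains[0].components] == [("s1", "+"), ("s2", "+"), ("s3", "+")]


def test_conflicting_bundle_rejected():
    bundles = [
        _bundle("s1", "R", "s2", "L", support=5),
        _bundle("s2", "R", "s3", "L", support=4),
        _bundle("s1", "R", "s3", "R", support=3),  # s1's R already used
    ]
    chains = build_superscaffolds(bundles, ["s1", "s2", "s3"])
    assert len(chains) == 1 and len(chains[0].components) == 3


def test_cycle_rejected_and_order_invariance():
    bundles = [
        _bundle("s1", "R", "s2", "L", support=5),
        _bundle("s2", "R", "s3", "L", support=4),
        _bundle("s3", "R", "s1", "L", support=3),  # would close a cycle
    ]
    for seed in range(3):
        shuffled = bundles[:]
        random.Random(seed).shuffle(shuffled)
        chains = build_superscaffolds(shuffled, ["s1", "s2", "s3"])
        assert len(chains) == 1
        assert [c[:2] for c in chains[0].components] == [("s1", "+"), ("s2", "+"), ("s3", "+")]


def test_reverse_orientation_chain():
    # right end of s1 meets right end of s2: s2 must be reverse-complemented
    chains = build_superscaffolds([_bundle("s1", "R", "s2", "R")], ["s1", "s2"])
    assert [c[:2] for c in chains[0].components] == [("s1", "+"), ("s2", "-")]


def test_emit_and_agp_round_trip(tmp_path, rng):
    seqs = {"s1": random_dna(rng, 100), "s2": random_dna(rng, 100)}
    chains = build_superscaffolds(
        [_bundle("s1", "R", "s2", "R", gap=50)], ["s1", "s2"], ScaffoldParams(min_gap=50)
    )
    fasta, agp = tmp_path / "ss.fasta", tmp_path / "ss.agp"
    (rec,) = emit(chains, seqs, fasta, agp)
    assert len(rec.bases) == 250
    assert rec.bases == seqs["s1"] + "N" * 50 + revcomp(seqs["s2"])
    agp_lines = [l for l in agp.read_text().splitlines() if not l.startswith("#")]
    assert len(agp_lines) == 3
    assert parse_agp(agp)[0].components == chains[0].components
    with pytest.raises(ValueError, match="missing"):
        emit(chains, {"s1": seqs["s1"]}, fasta, agp)


def test_assembly_stats():
    s = assembly_stats([8, 5, 4, 2, 1])
    assert (s.n_scaffolds, s.total_span, s.n50) == (5, 20, 5)
    assert assembly_stats([42]).n50 == 42
    assert assembly_stats([7, 7, 7]).n50 == 7
    with pytest.raises(ValueError):
        assembly_stats([])


def test_n50_gain():
    diff, pct = n50_gain(100_000, 110_000)
    assert diff == 10_000 and pct == pytest.approx(10.0)
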