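import numpy as np
import pytest

from htspeg.anatomy import EndPair
from htspeg.cluster import (
    ClusterParams,
    GreedyClusterer,
    cluster_pairs,
    greedy_cluster,
    merge_pairs,
    pair_identity,
    saturation_curve,
)
from htspeg.seqio import SeqRecord

from conftest import random_dna

PARAMS = ClusterParams()


def naive_greedy(ends: dict, params: ClusterParams):
    """Brute-force reference: same ordering and identity function, no
    prefilter and no edit-distance cap."""
    order = sorted(ends, key=lambda e: (-len(ends[e]), e))
    centroids: list[tuple[str, str]] = []
    assign = {}
    for eid in order:
        seq = ends[eid]
        for c, (_cid, cseq) in enumerate(centroids):
            if pair_identity(seq, cseq) >= params.identity_threshold - 1e-12:
                assign[eid] = c
                break
        else:
            assign[eid] = len(centroids)
            centroids.append((eid, seq))
    return assign, {i: cid for i, (cid, _s) in enumerate(centroids)}


def _sub(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


def test_identical_ends_one_cluster(rng):
    s = random_dna(rng, 50)
    a = greedy_cluster({"e1": s, "e2": s}, PARAMS)
    assert a.n_clusters == 1


def test_identity_threshold_boundary(rng):
    s = random_dna(rng, 50)
    six = _sub(s, [5, 12, 19, 26, 33, 40])
    assert pair_identity(s, six) == pytest.approx(0.88)
    assert greedy_cluster({"a": s, "b": six}, PARAMS).n_clusters == 2
    four = _sub(s, [5, 15, 25, 35])
    assert pair_identity(s, four) == pytest.approx(0.92)
    assert greedy_cluster({"a": s, "b": four}, PARAMS).n_clusters == 1


def test_prefix_joins_centroid_terminal_gaps_free(rng):
    centroid = random_dna(rng, 60)
    prefix = centroid[:45]
    assert pair_identity(prefix, centroid) == 1.0
    a = greedy_cluster({"long": centroid, "short": prefix}, PARAMS)
    assert a.n_clusters == 1
    assert a.centroids[0] == "long"  # processed first (longest)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        greedy_cluster({}, PARAMS)


def test_order_invariance(rng):
    ends = {f"e{i}": random_dna(rng, rng.integers(40, 120)) for i in range(30)}
    a1 = greedy_cluster(dict(sorted(ends.items())), PARAMS)
    a2 = greedy_cluster(dict(sorted(ends.items(), reverse=True)), PARAMS)
    assert a1.end_to_cluster == a2.end_to_cluster


def _random_end_set(rng, n):
    """Random ends plus mutated/truncated copies, to exercise borderline joins."""
    ends = {}
    i = 0
    while len(ends) < n:
        base = random_dna(rng, int(rng.integers(40, 200)))
        ends[f"e{i:04d}"] = base
        i += 1
        for _ in range(int(rng.integers(0, 3))):
            if len(ends) >= n:
                break
            mutated = list(base[: int(rng.integers(40, len(base) + 1))])
            for p in rng.choice(len(mutated), size=int(rng.integers(0, 1 + len(mutated) // 8)), replace=False):
                mutated[p] = "ACGT"[int(rng.integers(0, 4))]
            ends[f"e{i:04d}"] = "".join(mutated)
            i += 1
    return ends


def test_greedy_matches_bruteforce_oracle():
    rng = np.random.default_rng(42)
    for trial in range(10):
        ends = _random_end_set(rng, int(rng.integers(20, 200)))
        fast = greedy_cluster(ends, PARAMS)
        slow_assign, slow_centroids = naive_greedy(ends, PARAMS)
        assert fast.end_to_cluster == slow_assign, f"trial {trial}"
        assert fast.centroids == slow_centroids, f"trial {trial}"


def _pair(pid, left, right):
    return EndPair(pid, SeqRecord(f"{pid}/L", left), SeqRecord(f"{pid}/R", right), False, pid)


def test_merge_pairs_rules(rng):
    left, right = random_dna(rng, 80), random_dna(rng, 90)
    copies = [_pair(f"p{i}", left, right) for i in range(10)]
    reps, _l, _r = cluster_pairs(copies)
    assert len(reps) == 1  # PCR copies collapse to one non-redundant pair

    other_right = random_dna(rng, 90)
    pairs = [_pair("a", left, right), _pair("b", left, other_right)]
    reps, _l, _r = cluster_pairs(pairs)
    assert len(reps) == 2  # shared left cluster but distinct right clusters


def test_merge_pairs_unassigned_end_rejected(rng):
    p = _pair("a", random_dna(rng, 50), random_dna(rng, 50))
    good = greedy_cluster({p.left.id: p.left.bases}, PARAMS)
    with pytest.raises(ValueError, match="unassigned"):
        merge_pairs([p], good, good)


def test_merge_representative_is_longest(rng):
    left = random_dna(rng, 80)
    pairs = [_pair("short", left, left[:50]), _pair("long", left, left[:70])]
    reps, _l, _r = cluster_pairs(pairs)
    assert [p.pair_id for p in reps] == ["long"]


def test_saturation_errors_and_determinism(rng):
    pairs = [_pair(f"p{i}", random_dna(rng, 60), random_dna(rng, 60)) for i in range(30)]
    with pytest.raises(ValueError, match="50"):
        saturation_curve(pairs, [10, 50], 1, seed=0)
    with pytest.raises(ValueError, match="increasing"):
        saturation_curve(pairs, [20, 10], 1, seed=0)
    t1 = saturation_curve(pairs, [10, 20, 30], 2, seed=5)
    t2 = saturation_curve(pairs, [10, 20, 30], 2, seed=5)
    assert t1.equals(t2)


def test_saturation_monotone_and_bounded(rng):
    # 60 distinct fragments duplicated twice: counts monotone, bounded by 60
    distinct = [(random_dna(rng, 70), random_dna(rng, 70)) for _ in range(60)]
    pairs = [
        _pair(f"p{i}_{c}", l, r) for i, (l, r) in enumerate(distinct) for c in range(2)
    ]
    table = saturation_curve(pairs, [40, 80, 120], 3, seed=9)
    for _rep, grp in table.groupby("replicate"):
        counts = grp.sort_values("sample_size")["cluster_count"].tolist()
        assert counts == sorted(counts)
        assert counts[-1] <= 60
    # single full-size sample agrees with clustering the full set
    full = saturation_curve(pairs, [len(pairs)], 1, seed=3)
    reps, _l, _r = cluster_pairs(pairs)
    assert full["cluster_count"].iloc[0] == len(reps)
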