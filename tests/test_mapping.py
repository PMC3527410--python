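import numpy as np
import pytest

from htspeg.mapping import (
    Hit,
    KmerIndex,
    MapParams,
    MapResult,
    classify_pair,
    map_end,
    qc_report,
    summary_percentages,
)
from htspeg.seqio import GenomicInterval, SeqRecord, revcomp

from conftest import random_dna

PARAMS = MapParams()


def local_align_oracle(query: str, scaffolds: dict[str, str]):
    """Exhaustive Smith-Waterman (match +1, mismatch/gap -1) over both
    strands of every scaffold; returns (scaffold, strand, score, start, end)."""
    best = (-1, "", "", 0, 0)
    for sid, target in scaffolds.items():
        for strand in ("+", "-"):
            q = query if strand == "+" else revcomp(query)
            n, m = len(q), len(target)
            prev = [0] * (m + 1)
            prev_start = list(range(m + 1))
            for i in range(1, n + 1):
                cur = [0] * (m + 1)
                cur_start = [0] * (m + 1)
                qc = q[i - 1]
                for j in range(1, m + 1):
                    diag = prev[j - 1] + (1 if qc == target[j - 1] else -1)
                    up = prev[j] - 1
                    left = cur[j - 1] - 1
                    score = max(0, diag, up, left)
                    cur[j] = score
                    if score == 0:
                        cur_start[j] = j
                    elif score == diag:
                        cur_start[j] = prev_start[j - 1]
                    elif score == up:
                        cur_start[j] = prev_start[j]
                    else:
                        cur_start[j] = cur_start[j - 1]
                    if score > best[0]:
                        best = (score, sid, strand, cur_start[j], j)
                prev, prev_start = cur, cur_start
    score, sid, strand, start, end = best
    return sid, strand, score, start, end


def test_index_kmer_count_and_lookup(rng):
    seq = random_dna(rng, 1000)
    idx = KmerIndex([SeqRecord("s", seq)], PARAMS)
    assert len(idx._pos) == 1000 - 16 + 1  # one entry per forward k-mer

    from htspeg._kmer import kmer_codes, seq_codes

    probe = seq[100:116]
    _pos, codes = kmer_codes(seq_codes(probe), 16)
    qidx, gpos = idx.lookup(codes)
    assert 100 in gpos.tolist()


def test_index_skips_short_scaffold(rng, caplog):
    with caplog.at_level("WARNING"):
        idx = KmerIndex([SeqRecord("ok", random_dna(rng, 500)), SeqRecord("tiny", "ACGT")], PARAMS)
    assert "tiny" in caplog.text
    assert idx.ids == ["ok"]


def test_exact_substring_maps_uniquely(rng):
    genome = random_dna(rng, 5000)
    idx = KmerIndex([SeqRecord("s", genome)], PARAMS)
    end = SeqRecord("e", genome[1200:1300])
    res = map_end(end, idx, PARAMS)
    assert res.best is not None
    assert res.best.identity == 1.0
    assert res.best.score == 100
    assert (res.best.target.start, res.best.target.end) == (1200, 1300)
    assert res.best.target.strand == "+"
    assert res.uniqueness == "unique"


def test_reverse_strand_hit(rng):
    genome = random_dna(rng, 4000)
    idx = KmerIndex([SeqRecord("s", genome)], PARAMS)
    end = SeqRecord("e", revcomp(genome[2000:2120]))
    res = map_end(end, idx, PARAMS)
    assert res.best.target.strand == "-"
    assert (res.best.target.start, res.best.target.end) == (2000, 2120)


def test_duplicated_locus_is_multiple(rng):
    insert = random_dna(rng, 150)
    genome = random_dna(rng, 1000) + insert + random_dna(rng, 1000) + insert + random_dna(rng, 500)
    idx = KmerIndex([SeqRecord("s", genome)], PARAMS)
    res = map_end(SeqRecord("e", insert), idx, PARAMS)
    assert res.uniqueness == "multiple"
    assert len(res.hits) >= 2


def test_ten_percent_divergence_at_identity_boundary(rng):
    genome = random_dna(rng, 5000)
    sub = list(genome[800:900])
    # 10 interior substitutions; clumped as random errors typically are, so
    # an exact seed-length stretch survives between them
    for p in (10, 12, 30, 32, 50, 52, 70, 72, 85, 87):
        sub[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[p]]
    res = map_end(SeqRecord("e", "".join(sub)), idx := KmerIndex([SeqRecord("s", genome)], PARAMS), PARAMS)
    assert res.best is not None
    assert res.best.identity == pytest.approx(0.90)


def test_map_end_agrees_with_exhaustive_local_alignment():
    rng = np.random.default_rng(7)
    for trial in range(8):
        scaffolds = {f"s{k}": random_dna(rng, 2000) for k in range(2)}
        sid = f"s{int(rng.integers(0, 2))}"
        start = int(rng.integers(0, 2000 - 120))
        q = list(scaffolds[sid][start : start + 120])
        n_sub = int(rng.integers(0, 9))
        for p in rng.choice(np.arange(2, 118), size=n_sub, replace=False):
            q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
        query = "".join(q)
        if rng.random() < 0.5:
            query = revcomp(query)
        idx = KmerIndex([SeqRecord(k, v) for k, v in scaffolds.items()], PARAMS)
        res = map_end(SeqRecord("e", query), idx, PARAMS)
        o_sid, o_strand, o_score, o_start, o_end = local_align_oracle(query, scaffolds)
        assert res.best is not None, f"trial {trial}"
        assert (res.best.target.seq_id, res.best.target.strand) == (o_sid, o_strand)
        assert res.best.score == o_score
        assert (res.best.target.start, res.best.target.end) == (o_start, o_end)


def _result(end_id, scaffold, start, end, strand, unique="unique"):
    hit = Hit(end_id, GenomicInterval(scaffold, start, end, strand), 1.0, end - start, end - start, end - start)
    return MapResult(end_id, (hit,), hit, unique)


def _unmapped(end_id):
    return MapResult(end_id, (), None, None)


def test_classify_proper_pair_span():
    pm = classify_pair("p", _result("p/L", "s1", 1000, 1100, "+"), _result("p/R", "s1", 95000, 95100, "+"))
    assert pm.map_class == "both_mapped"
    assert pm.locality == "same_scaffold"
    assert pm.orientation == "proper"
    assert pm.span == 94_100


def test_classify_wrong_orientation_opposite_strands():
    pm = classify_pair("p", _result("p/L", "s1", 1000, 1100, "+"), _result("p/R", "s1", 95000, 95100, "-"))
    assert pm.orientation == "wrong"
    # reverse-strand proper geometry: left start > right start on '-'
    pm2 = classify_pair("p", _result("p/L", "s1", 95000, 95100, "-"), _result("p/R", "s1", 1000, 1100, "-"))
    assert pm2.orientation == "proper"


def test_classify_one_end_and_different_scaffolds():
    pm = classify_pair("p", _result("p/L", "s1", 0, 100, "+"), _unmapped("p/R"))
    assert pm.map_class == "one_end"
    assert pm.locality is None and pm.span is None
    pm2 = classify_pair("p", _result("p/L", "s1", 0, 100, "+"), _result("p/R", "s2", 0, 100, "+", "multiple"))
    assert pm2.locality == "different_scaffolds"
    assert pm2.uniqueness == "multiple"


def test_qc_report_partitions_and_empty():
    empty = qc_report([])
    assert empty.n_pairs == 0 and empty.span_median is None
    assert empty.percentages["both_mapped_pct"] is None

    mappings = [
        classify_pair("a", _result("a/L", "s1", 0, 100, "+"), _result("a/R", "s1", 500, 600, "+")),
        classify_pair("b", _result("b/L", "s1", 0, 100, "+"), _result("b/R", "s2", 0, 100, "+")),
        classify_pair("c", _result("c/L", "s1", 0, 100, "+"), _unmapped("c/R")),
        classify_pair("d", _unmapped("d/L"), _unmapped("d/R")),
    ]
    qc = qc_report(mappings)
    assert qc.both_mapped == qc.unique + qc.multiple == 2
    assert qc.same_scaffold + qc.different_scaffolds == qc.both_mapped
    assert qc.one_end == 1 and qc.both_unmapped == 1
    assert qc.span_median == 600


def test_summary_percentage_arithmetic():
    pcts = summary_percentages(
        {"kept": 200, "unique": 60, "multiple": 40, "same_scaffold": 35,
         "different_scaffolds": 65, "wrong_orientation": 7}
    )
    assert pcts["both_mapped"] == 100
    assert pcts["both_mapped_pct"] == pytest.approx(50.0)
    assert pcts["same_scaffold_pct"] == pytest.approx(35.0)
    assert pcts["wrong_orientation_pct"] == pytest.approx(20.0)
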