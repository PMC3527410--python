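"""Seed-and-extend mapping of end pairs to scaffolds, and pair QC.

Each end is mapped by exact k-mer seeding (both strands), chaining seeds
per (scaffold, strand, diagonal band) and extending the chained region
with banded edit-distance alignment; the aligned segment is then trimmed
to its best-scoring local sub-segment under unit scores
(match +1, mismatch/gap -1).  Hits below 90% identity or shorter than
35 aligned columns are discarded, the best survivor per end is chosen by
score, and an end is "multiple" when a second retained hit at a distinct
locus scores within ``multi_margin`` of the best.

Pair classification follows the circularisation geometry of the library:
the two insert termini read out on the *same* genomic strand in
head-to-tail order, so a pair is in proper orientation iff both best
hits share a strand and the left end precedes the right end along it;
anything else on one scaffold is a wrong-orientation (chimeric) pair.
The span of a same-scaffold pair is the distance between the outermost
mapped coordinates and estimates the clone insert size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from ._kmer import kmer_codes, seq_codes
from .anatomy import EndPair
from .seqio import GenomicInterval, SeqRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapParams:
    min_identity: float = 0.90
    min_aln_len: int = 35
    seed_k: int = 16
    multi_margin: float = 0.95
    diag_band: int = 32
    window_pad: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_aln_len < self.seed_k:
            raise ValueError("min_aln_len must be >= seed_k")

    def max_edits(self, query_len: int) -> int:
        t = self.min_identity
        return int(query_len * (1.0 - t) / t) + 2


@dataclass(frozen=True)
class Hit:
    """One retained alignment of an end on a scaffold."""

    end_id: str
    target: GenomicInterval
    identity: float
    aln_len: int
    score: int  # matches - mismatches - gaps
    matches: int


@dataclass(frozen=True)
class MapResult:
    end_id: str
    hits: tuple[Hit, ...]
    best: Optional[Hit]
    uniqueness: Optional[str]  # "unique" | "multiple" | None when unmapped


class KmerIndex:
    """Exact k-mer -> position lookup over a scaffold set (forward strand).

    Reverse-strand hits are found by also querying the reverse complement
    of the end, so only forward k-mers are stored.
    """

    def __init__(self, scaffolds: Sequence[SeqRecord], params: MapParams | None = None):
        params = params or MapParams()
        self.k = params.seed_k
        self.seqs: dict[str, str] = {}
        ids, offsets, pos_parts, code_parts = [], [0], [], []
        total = 0
        for rec in scaffolds:
            if len(rec.bases) < self.k:
                logger.warning("scaffold %s shorter than k=%d; skipped from index", rec.id, self.k)
                continue
            self.seqs[rec.id] = rec.bases
            ids.append(rec.id)
            pos, codes = kmer_codes(seq_codes(rec.bases), self.k)
            pos_parts.append(pos + total)
            code_parts.append(codes)
            total += len(rec.bases)
            offsets.append(total)
        if not ids:
            raise ValueError("no scaffold long enough to index")
        self.ids = ids
        self.offsets = np.asarray(offsets, dtype=np.int64)
        codes = np.concatenate(code_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def lookup(self, qcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global positions of each query k-mer; returns (query_idx, global_pos)."""
        lo = np.searchsorted(self._codes, qcodes, side="left")
        hi = np.searchsorted(self._codes, qcodes, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(len(qcodes)), counts)
        if counts.sum() == 0:
            return qidx, np.empty(0, dtype=np.int64)
        gpos = np.concatenate([self._pos[a:b] for a, b in zip(lo, hi) if b > a])
        return qidx, gpos

    def locate(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split global positions into (scaffold index, local position)."""
        sidx = np.searchsorted(self.offsets, gpos, side="right") - 1
        return sidx, gpos - self.offsets[sidx]


def build_index(scaffolds: Sequence[SeqRecord], params: MapParams | None = None) -> KmerIndex:
    return KmerIndex(scaffolds, params)


_OP_SCORES = {"=": 1, "X": -1, "I": -1, "D": -1}
_OP_DT = {"=": 1, "X": 1, "I": 0, "D": 1}  # target consumption per column


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _best_local_segment(ops: list[tuple[int, str]]) -> tuple[int, int, int, int, int]:
    """Max-scoring contiguous sub-path of an alignment (Kadane on runs).

    Returns (score, t_start, t_end, matches, cols) with target coordinates
    relative to the alignment's target start.  A maximal segment never
    starts or ends inside a negative run, so op granularity is exact.
    """
    best = (0, 0, 0, 0, 0)
    cur_score = cur_matches = cur_cols = 0
    t_pos = 0
    seg_t_start = 0
    for length, op in ops:
        if cur_score <= 0:
            cur_score, cur_matches, cur_cols = 0, 0, 0
            seg_t_start = t_pos
        cur_score += _OP_SCORES[op] * length
        cur_matches += length if op == "=" else 0
        cur_cols += length
        t_pos += _OP_DT[op] * length
        if cur_score > best[0]:
            best = (cur_score, seg_t_start, t_pos, cur_matches, cur_cols)
    return best


def _extend(
    query: str, window: str, window_start: int, scaffold_id: str, strand: str,
    end_id: str, params: MapParams,
) -> Optional[Hit]:
    res = edlib.align(query, window, mode="HW", task="path", k=params.max_edits(len(query)))
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    aln_t_start = min(s or 0 for s, _e in res["locations"])
    score, t0, t1, matches, cols = _best_local_segment(_parse_cigar(res["cigar"]))
    if cols == 0 or t1 == t0:
        return None
    identity = matches / cols
    if identity < params.min_identity or cols < params.min_aln_len:
        return None
    start = window_start + aln_t_start + t0
    end = window_start + aln_t_start + t1
    return Hit(
        end_id=end_id,
        target=GenomicInterval(scaffold_id, start, end, strand),
        identity=identity,
        aln_len=cols,
        score=score,
        matches=matches,
    )


def _dedupe(hits: list[Hit]) -> list[Hit]:
    """Collapse overlapping hits on the same scaffold+strand, keeping the best."""
    hits = sorted(
        hits, key=lambda h: (h.target.seq_id, h.target.strand, h.target.start, -h.score)
    )
    out: list[Hit] = []
    for h in hits:
        if out:
            p = out[-1]
            if (
                p.target.seq_id == h.target.seq_id
                and p.target.strand == h.target.strand
                and h.target.start < p.target.end
            ):
                if (h.score, h.aln_len) > (p.score, p.aln_len):
                    out[-1] = h
                continue
        out.append(h)
    return out


def map_end(end: SeqRecord, index: KmerIndex, params: MapParams | None = None) -> MapResult:
    """Map one end; returns retained hits, the best hit and its uniqueness."""
    params = params or MapParams()
    raw_hits: list[Hit] = []
    for strand in ("+", "-"):
        query = end.bases if strand == "+" else revcomp(end.bases)
        qpos, qcodes = kmer_codes(seq_codes(query), index.k)
        if len(qcodes) == 0:
            continue
        qidx, gpos = index.lookup(qcodes)
        if len(gpos) == 0:
            continue
        sidx, local = index.locate(gpos)
        diag = local - qpos[qidx]
        band_key = sidx.astype(np.int64) * (1 << 32) + (diag + len(query)) // params.diag_band
        for key in np.unique(band_key):
            sel = band_key == key
            s = int(sidx[sel][0])
            scaffold_id = index.ids[s]
            seq = index.seqs[scaffold_id]
            dmin, dmax = int(diag[sel].min()), int(diag[sel].max())
            w0 = max(0, dmin - params.window_pad)
            w1 = min(len(seq), dmax + len(query) + params.window_pad)
            hit = _extend(query, seq[w0:w1], w0, scaffold_id, strand, end.id, params)
            if hit is not None:
                raw_hits.append(hit)
    hits = _dedupe(raw_hits)
    hits.sort(key=lambda h: (-h.score, -h.aln_len, h.target.seq_id, h.target.start, h.target.strand))
    if not hits:
        return MapResult(end.id, (), None, None)
    best = hits[0]
    uniqueness = "unique"
    for h in hits[1:]:
        distinct = (
            h.target.seq_id != best.target.seq_id
            or h.target.strand != best.target.strand
            or h.target.start >= best.target.end
            or h.target.end <= best.target.start
        )
        if distinct and h.score >= params.multi_margin * best.score:
            uniqueness = "multiple"
            break
    return MapResult(end.id, tuple(hits), best, uniqueness)


@dataclass(frozen=True)
class PairMapping:
    """Mapping-based classification of one read pair."""

    pair_id: str
    left: MapResult
    right: MapResult
    map_class: str  # both_unmapped | one_end | both_mapped
    uniqueness: Optional[str] = None  # unique | multiple (both_mapped only)
    locality: Optional[str] = None  # same_scaffold | different_scaffolds
    orientation: Optional[str] = None  # proper | wrong (same_scaffold only)
    span: Optional[int] = None  # bp (same_scaffold only)

    def __post_init__(self) -> None:
        if self.map_class != "both_mapped":
            assert self.uniqueness is None and self.locality is None
        if self.locality != "same_scaffold":
            assert self.orientation is None and self.span is None
        if self.span is not None:
            assert self.span > 0


def classify_pair(pair_id: str, left: MapResult, right: MapResult) -> PairMapping:
    """Classify a pair from its two mapping results (Table-style taxonomy)."""
    if left.best is None and right.best is None:
        return PairMapping(pair_id, left, right, "both_unmapped")
    if left.best is None or right.best is None:
        return PairMapping(pair_id, left, right, "one_end")
    lb, rb = left.best.target, right.best.target
    uniqueness = "unique" if (left.uniqueness == "unique" and right.uniqueness == "unique") else "multiple"
    if lb.seq_id != rb.seq_id:
        return PairMapping(pair_id, left, right, "both_mapped", uniqueness, "different_scaffolds")
    if lb.strand == rb.strand and (
        (lb.strand == "+" and lb.start < rb.start) or (lb.strand == "-" and lb.start > rb.start)
    ):
        orientation = "proper"
    else:
        orientation = "wrong"
    span = max(lb.end, rb.end) - min(lb.start, rb.start)
    return PairMapping(
        pair_id, left, right, "both_mapped", uniqueness, "same_scaffold", orientation, span
    )


def map_pairs(
    pairs: Iterable[EndPair], index: KmerIndex, params: MapParams | None = None
) -> list[PairMapping]:
    params = params or MapParams()
    return [
        classify_pair(p.pair_id, map_end(p.left, index, params), map_end(p.right, index, params))
        for p in pairs
    ]


def summary_percentages(counts: dict) -> dict:
    """Derived percentages of the pair-count taxonomy.

    Input keys: kept, unique, multiple, same_scaffold, different_scaffolds,
    wrong_orientation.  Percentages with a zero denominator are None.
    """
    both_mapped = counts["unique"] + counts["multiple"]

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    return {
        "both_mapped": both_mapped,
        "both_mapped_pct": pct(both_mapped, counts["kept"]),
        "same_scaffold_pct": pct(counts["same_scaffold"], both_mapped),
        "different_scaffolds_pct": pct(counts["different_scaffolds"], both_mapped),
        "wrong_orientation_pct": pct(counts["wrong_orientation"], counts["same_scaffold"]),
    }


@dataclass
class QcReport:
    """Pair-classification counts, derived percentages and span summary.

    Percentages are always recomputed from the counts; the partition
    identities (unique + multiple = both_mapped = same + different) hold
    by construction and are asserted.
    """

    n_pairs: int
    n_kept: int
    both_unmapped: int
    one_end: int
    unique: int
    multiple: int
    same_scaffold: int
    different_scaffolds: int
    proper: int
    wrong_orientation: int
    span_mean: Optional[float]
    span_median: Optional[float]
    span_histogram: list[tuple[int, int, int]]  # (bin_start, bin_end, count)

    def __post_init__(self) -> None:
        assert self.unique + self.multiple == self.same_scaffold + self.different_scaffolds
        assert self.proper + self.wrong_orientation == self.same_scaffold
        assert (
            self.both_unmapped + self.one_end + self.unique + self.multiple == self.n_pairs
        )

    @property
    def both_mapped(self) -> int:
        return self.unique + self.multiple

    @property
    def percentages(self) -> dict:
        return summary_percentages(
            {
                "kept": self.n_kept,
                "unique": self.unique,
                "multiple": self.multiple,
                "same_scaffold": self.same_scaffold,
                "different_scaffolds": self.different_scaffolds,
                "wrong_orientation": self.wrong_orientation,
            }
        )


def qc_report(
    mappings: Sequence[PairMapping], n_kept: int | None = None, n_bins: int = 20
) -> QcReport:
    """Tally the classification taxonomy and the span distribution.

    ``n_kept`` is the denominator for the both-ends-mapped percentage
    (the pairs that survived dissection); it defaults to ``len(mappings)``.
    Span statistics are computed over proper same-scaffold pairs.
    """
    n = len(mappings)
    counts = {"both_unmapped": 0, "one_end": 0, "unique": 0, "multiple": 0,
              "same_scaffold": 0, "different_scaffolds": 0, "proper": 0, "wrong": 0}
    spans: list[int] = []
    for pm in mappings:
        if pm.map_class == "both_unmapped":
            counts["both_unmapped"] += 1
        elif pm.map_class == "one_end":
            counts["one_end"] += 1
        else:
            counts[pm.uniqueness] += 1
            counts[pm.locality] += 1
            if pm.locality == "same_scaffold":
                counts["proper" if pm.orientation == "proper" else "wrong"] += 1
                if pm.orientation == "proper":
                    spans.append(pm.span)
    if spans:
        arr = np.asarray(spans)
        hist, edges = np.histogram(arr, bins=n_bins)
        histogram = [
            (int(edges[i]), int(edges[i + 1]), int(hist[i])) for i in range(len(hist))
        ]
        span_mean, span_median = float(arr.mean()), float(np.median(arr))
    else:
        histogram, span_mean, span_median = [], None, None
    return QcReport(
        n_pairs=n,
        n_kept=n if n_kept is None else n_kept,
        both_unmapped=counts["both_unmapped"],
        one_end=counts["one_end"],
        unique=counts["unique"],
        multiple=counts["multiple"],
        same_scaffold=counts["same_scaffold"],
        different_scaffolds=counts["different_scaffolds"],
        proper=counts["proper"],
        wrong_orientation=counts["wrong"],
        span_mean=span_mean,
        span_median=span_median,
        span_histogram=histogram,
    )
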