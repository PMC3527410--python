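"""Greedy identity clustering of read ends and redundancy removal.

PCR and library redundancy is collapsed by clustering the left ends and
the right ends separately with greedy incremental (centroid-based)
clustering at 90% identity, then merging read pairs whose two ends fall
in the same (left cluster, right cluster) combination into a single
non-redundant pair.  The saturation analysis subsamples the pair pool at
increasing sizes and re-clusters to show how fast new non-redundant
pairs are still being discovered.

Identity definition
-------------------
Ends are processed in decreasing length, so every comparison aligns a
query that is no longer than the centroid.  Identity is computed from
the minimum-edit semi-global alignment of the query into the centroid
(terminal gaps on the centroid side are free and excluded):

    identity = matching columns / alignment columns .

This makes an exact prefix of a centroid 100% identical, which is the
behaviour wanted for 454-style reads truncated at different lengths.
A k-mer counting prefilter restricts which centroids are aligned; its
count bound is conservative for the edit budget implied by the identity
threshold, so the prefiltered result equals a full scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._kmer import kmer_codes, seq_codes
from .anatomy import EndPair


@dataclass(frozen=True)
class ClusterParams:
    """Greedy clustering parameters.

    ``band_terminal_gaps`` marks that terminal gaps are unpenalised and
    excluded from the identity denominator (the only supported mode);
    ``tie_break`` documents the processing order: decreasing length,
    then ascending id.
    """

    identity_threshold: float = 0.90
    band_terminal_gaps: bool = True
    tie_break: str = "length_desc_id_asc"
    prefilter_k: int = 6

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if not self.band_terminal_gaps:
            raise ValueError("penalised terminal gaps are not supported")

    def max_edits(self, query_len: int) -> int:
        """Largest edit distance compatible with the identity threshold.

        From identity = 1 - ed/cols and cols <= query_len + ed.
        """
        t = self.identity_threshold
        return int(query_len * (1.0 - t) / t)


def _alignment_columns(cigar: str) -> int:
    cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            cols += int(num)
            num = ""
    return cols


def pair_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence semi-globally aligned into the longer."""
    if a == b:
        return 1.0
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    if not q:
        return 0.0
    res = edlib.align(q, t, mode="HW", task="path")
    cols = _alignment_columns(res["cigar"])
    return 1.0 - res["editDistance"] / cols


def _meets_threshold(a: str, b: str, params: ClusterParams) -> bool:
    """Same decision as ``pair_identity(...) >= threshold`` with a distance cap."""
    if a == b:
        return True
    q, t = (a, b) if len(a) <= len(b) else (b, a)
    if not q:
        return False
    res = edlib.align(q, t, mode="HW", task="path", k=params.max_edits(len(q)))
    if res["editDistance"] == -1:
        return False
    cols = _alignment_columns(res["cigar"])
    return 1.0 - res["editDistance"] / cols >= params.identity_threshold - 1e-12


@dataclass
class ClusterAssignment:
    """end_id -> cluster, and cluster -> centroid end_id."""

    end_to_cluster: dict[str, int]
    centroids: dict[int, str]

    def __post_init__(self) -> None:
        for cid, end_id in self.centroids.items():
            assert self.end_to_cluster[end_id] == cid, "centroid must belong to its own cluster"

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


class GreedyClusterer:
    """Incremental greedy centroid clustering.

    Each batch is processed in decreasing length (ties by id, ascending);
    an end joins the first existing centroid (in founding order) reaching
    the identity threshold, otherwise it founds a new cluster.  Once made,
    assignments never change, so feeding nested batches yields
    monotonically growing clusterings.  A k-mer presence matrix prunes the
    candidate centroids with a bound that is conservative for the edit
    budget of the identity threshold, so pruning never changes the result.
    """

    def __init__(self, params: ClusterParams | None = None):
        self.params = params or ClusterParams()
        k = self.params.prefilter_k
        self._rows = np.zeros((64, 4**k), dtype=bool)
        self.centroid_seqs: list[str] = []
        self.centroid_ids: list[str] = []
        self._centroid_lens = np.empty(0, dtype=np.int64)
        self.assign: dict[str, int] = {}

    def _candidates(self, kmers: np.ndarray, query_len: int) -> np.ndarray:
        """Centroid indices (founding order) that could reach the threshold.

        The shared-k-mer lower bound uses the shorter of query and
        centroid per centroid: with m = min(len_q, len_c) and e_max edits
        permitted at the threshold, at least (m - k + 1) - k * e_max of
        the query's k-mer windows survive intact inside the alignment.
        """
        n = len(self.centroid_seqs)
        if n == 0:
            return np.empty(0, dtype=np.int64)
        k = self.params.prefilter_k
        if query_len < k or len(kmers) == 0:
            return np.arange(n)  # too short to prefilter
        uniq, counts = np.unique(kmers, return_counts=True)
        m = np.minimum(query_len, self._centroid_lens[:n])
        t = self.params.identity_threshold
        e_max = (m * (1.0 - t) / t).astype(np.int64)
        min_positions = (m - k + 1) - k * e_max
        min_types = np.maximum(1, -(-min_positions // int(counts.max())))
        shared = self._rows[:n][:, uniq].sum(axis=1)
        return np.nonzero((shared >= min_types) | (min_positions <= 0))[0]

    def add(self, ends: Mapping[str, str]) -> None:
        """Assign one batch of ``{end_id: sequence}`` (sorted internally)."""
        params = self.params
        for eid in sorted(ends, key=lambda e: (-len(ends[e]), e)):
            seq = ends[eid]
            _pos, kmers = kmer_codes(seq_codes(seq), params.prefilter_k)
            cluster = None
            for c in self._candidates(kmers, len(seq)):
                if _meets_threshold(seq, self.centroid_seqs[c], params):
                    cluster = int(c)
                    break
            if cluster is None:
                cluster = len(self.centroid_seqs)
                if cluster == len(self._rows):
                    self._rows = np.vstack([self._rows, np.zeros_like(self._rows)])
                if len(kmers):
                    self._rows[cluster, np.unique(kmers)] = True
                self.centroid_seqs.append(seq)
                self.centroid_ids.append(eid)
                self._centroid_lens = np.append(self._centroid_lens, len(seq))
            self.assign[eid] = cluster

    def assignment(self) -> ClusterAssignment:
        return ClusterAssignment(dict(self.assign), dict(enumerate(self.centroid_ids)))


def greedy_cluster(ends: Mapping[str, str], params: ClusterParams | None = None) -> ClusterAssignment:
    """Greedy incremental clustering of ``{end_id: sequence}``.

    Ends are processed in decreasing length (ties by id, ascending); each
    end joins the first existing centroid reaching the identity threshold,
    otherwise it founds a new cluster.  The result is independent of the
    mapping's iteration order.
    """
    if not ends:
        raise ValueError("no ends to cluster")
    clusterer = GreedyClusterer(params)
    clusterer.add(ends)
    return clusterer.assignment()


def merge_pairs(
    pairs: Sequence[EndPair],
    left_assign: ClusterAssignment,
    right_assign: ClusterAssignment,
) -> tuple[list[EndPair], dict[tuple[int, int], list[str]]]:
    """Collapse pairs redundant in both ends to one non-redundant pair each.

    Pairs are grouped by (left cluster, right cluster); each group emits
    the pair maximising left+right length (ties to the smaller pair_id).
    Returns the representatives (sorted by pair_id) and the groups.
    """
    groups: dict[tuple[int, int], list[EndPair]] = {}
    for pair in pairs:
        try:
            key = (left_assign.end_to_cluster[pair.left.id], right_assign.end_to_cluster[pair.right.id])
        except KeyError as exc:
            raise ValueError(f"pair {pair.pair_id} has an unassigned end: {exc}") from exc
        groups.setdefault(key, []).append(pair)
    reps = [
        min(members, key=lambda p: (-(len(p.left.bases) + len(p.right.bases)), p.pair_id))
        for members in groups.values()
    ]
    reps.sort(key=lambda p: p.pair_id)
    member_ids = {key: sorted(p.pair_id for p in members) for key, members in groups.items()}
    return reps, member_ids


def cluster_pairs(
    pairs: Sequence[EndPair], params: ClusterParams | None = None
) -> tuple[list[EndPair], ClusterAssignment, ClusterAssignment]:
    """Cluster left and right ends separately, then merge redundant pairs."""
    params = params or ClusterParams()
    left = greedy_cluster({p.left.id: p.left.bases for p in pairs}, params)
    right = greedy_cluster({p.right.id: p.right.bases for p in pairs}, params)
    reps, _groups = merge_pairs(pairs, left, right)
    return reps, left, right


def saturation_curve(
    pairs: Sequence[EndPair],
    sizes: Sequence[int],
    n_replicates: int,
    seed: int,
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Cluster nested random subsamples of the pair pool at each size.

    Each replicate draws one permutation of the pairs; the sample at every
    size is that permutation's prefix, so within a replicate the samples
    are nested.  The clustering is extended *incrementally* from one size
    to the next (new ends are assigned against the existing centroids),
    which makes the non-redundant pair count non-decreasing within a
    replicate by construction.  Returns a table with columns sample_size,
    replicate, cluster_count and increment_vs_previous_size (the first
    size increments from zero).
    """
    sizes = list(sizes)
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError(f"sizes must be strictly increasing: {sizes}")
    for size in sizes:
        if size > len(pairs):
            raise ValueError(f"sample size {size} exceeds available pairs ({len(pairs)})")
    params = params or ClusterParams()
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm = rng.permutation(len(pairs))
        left, right = GreedyClusterer(params), GreedyClusterer(params)
        keys: set[tuple[int, int]] = set()
        previous = 0
        prev_size = 0
        for size in sizes:
            block = [pairs[i] for i in perm[prev_size:size]]
            left.add({p.left.id: p.left.bases for p in block})
            right.add({p.right.id: p.right.bases for p in block})
            keys.update(
                (left.assign[p.left.id], right.assign[p.right.id]) for p in block
            )
            count = len(keys)
            rows.append(
                {
                    "sample_size": size,
                    "replicate": rep,
                    "cluster_count": count,
                    "increment_vs_previous_size": count - previous,
                }
            )
            previous = count
            prev_size = size
    return pd.DataFrame(rows)
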