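"""Read dissection: locate the hairpin adaptor, trim vector flanks, split ends.

A raw amplicon read has the layout::

    [primer tail][5' vector flank][left end][44-nt hairpin adaptor][right end][3' vector flank][primer tail]

The hairpin adaptor is palindromic, so a single-strand search suffices to
find the junction.  Reads lacking the adaptor are discarded; the genomic
ends between the flank matches and the adaptor become the read pair, and
pairs in which either end is shorter than ``min_end_len`` are discarded.
A pair is *full length* when both the 5' and the 3' vector flank were
located on the read.

Because 454-style reads are frequently shorter than the amplicon, the 3'
vector flank is often only partially present as a prefix hanging off the
read end; a dedicated suffix-anchored alignment recognises such partial
flanks so the right end is still trimmed correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib
import numpy as np

from .seqio import SeqRecord, revcomp

# Landmark sequences of the pCC1BAC-based amplicon design: the palindromic
# hairpin adaptor that separates the two genomic ends, and the vector
# sequence flanking the cloning site on either side.
HAIRPIN_ADAPTOR = "GTTGGAACCGAAAGGGTTTGAATTCAAACCCTTTCGGTTCCAAC"
VECTOR_FLANK5 = "TAATACGACTCACTATAGGGCGAATTC"
VECTOR_FLANK3 = (
    "GAATTCGAGCTCGGTACCCGGGGATCCTCTAGAGTCGACCTGCAGGCATGCAAGCTTGAGTATTCTATAGTCTCACCTAAATAGCTTGGCGT"
)

#: Minimum number of 3'-flank bases that must be anchored at the read end
#: before a partial flank match is trusted.
FLANK3_MIN_ANCHOR = 10


@dataclass(frozen=True)
class AnatomyModel:
    """Landmark sequences and match tolerances that define read structure.

    ``max_flank_edits_per_10nt`` scales the edit budget with flank length:
    a flank of length L may be matched with up to ``int(L / 10 * rate)``
    edits (2 for the 27-nt 5' flank, 9 for the 92-nt 3' flank at the
    default rate of 1).
    """

    adaptor: str = HAIRPIN_ADAPTOR
    flank5: str = VECTOR_FLANK5
    flank3: str = VECTOR_FLANK3
    max_adaptor_edits: int = 4
    max_flank_edits_per_10nt: float = 1.0
    min_end_len: int = 40

    def __post_init__(self) -> None:
        if self.adaptor != revcomp(self.adaptor):
            raise ValueError("hairpin adaptor must be its own reverse complement")
        if self.max_adaptor_edits < 0 or self.min_end_len < 1:
            raise ValueError("tolerances must be non-negative and min_end_len >= 1")

    def flank_edits(self, flank: str) -> int:
        return int(len(flank) / 10 * self.max_flank_edits_per_10nt)


@dataclass(frozen=True)
class EndPair:
    """One dissected read: the two genomic ends flanking the adaptor."""

    pair_id: str
    left: SeqRecord
    right: SeqRecord
    full_length: bool
    source_read_id: str


@dataclass(frozen=True)
class DissectionOutcome:
    status: str  # "ok" | "no_adaptor" | "end_too_short"
    pair: Optional[EndPair] = None

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.pair is not None):
            raise ValueError("pair must be present iff status == 'ok'")


@dataclass
class DissectionStats:
    """Counts partitioning every input read into exactly one bin."""

    n_raw: int = 0
    n_no_adaptor: int = 0
    n_end_too_short: int = 0
    n_kept: int = 0
    n_full_length: int = 0  # full-length pairs among the kept ones

    @property
    def n_with_adaptor(self) -> int:
        return self.n_raw - self.n_no_adaptor

    def check(self) -> None:
        assert self.n_raw == self.n_no_adaptor + self.n_with_adaptor
        assert self.n_with_adaptor == self.n_end_too_short + self.n_kept
        assert self.n_full_length <= self.n_kept


def _best_location(result: dict) -> Optional[tuple[int, int]]:
    """Leftmost minimum-edit location as a half-open interval, or None."""
    if result["editDistance"] == -1 or not result["locations"]:
        return None
    start, end = min(result["locations"], key=lambda se: (se[0] if se[0] else 0, se[1]))
    return (start or 0, end + 1)


def find_adaptor(read_bases: str, model: AnatomyModel) -> Optional[tuple[int, int]]:
    """Best approximate occurrence of the hairpin adaptor on the read.

    Returns a half-open interval or None when no occurrence is within
    ``max_adaptor_edits``.  The adaptor is palindromic, so a single search
    covers both strands.  Ties on edit distance break to the leftmost site.
    """
    if not read_bases:
        raise ValueError("empty read")
    res = edlib.align(model.adaptor, read_bases, mode="HW", task="locations", k=model.max_adaptor_edits)
    return _best_location(res)


def _find_flank(flank: str, region: str, max_edits: int) -> Optional[tuple[int, int]]:
    if not region:
        return None
    res = edlib.align(flank, region, mode="HW", task="locations", k=max_edits)
    return _best_location(res)


def _find_flank3_overhang(region: str, model: AnatomyModel) -> Optional[int]:
    """Start of a 3'-flank prefix anchored at the end of ``region``.

    Dynamic programme over edit distance with a free prefix on the region
    side and a free suffix on the flank side: the cheapest way to align
    ``flank3[:i]`` so that it consumes ``region`` to its last base.  The
    longest flank prefix within the per-length edit budget wins; a minimum
    anchor length guards against chance matches.
    """
    flank = model.flank3
    n, m = len(region), len(flank)
    if n == 0:
        return None
    q = np.frombuffer(flank.encode(), dtype=np.uint8)
    idx = np.arange(m + 1)
    prev = idx.astype(np.int32).copy()  # E[t=0][i] = i
    for t in range(1, n + 1):
        c = ord(region[t - 1])
        sub = prev[:-1] + (q != c)
        cur = np.empty(m + 1, dtype=np.int32)
        cur[0] = 0  # free region prefix
        cur[1:] = np.minimum(sub, prev[1:] + 1)
        # left-to-right gap propagation: cur[i] = min_j<=i cur[j] + (i - j)
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    budget = (idx / 10.0 * model.max_flank_edits_per_10nt).astype(np.int32)
    ok = (prev <= budget) & (idx >= FLANK3_MIN_ANCHOR)
    if not ok.any():
        return None
    i = int(np.nonzero(ok)[0][-1])  # longest explained flank prefix
    # Re-locate that prefix to get the cut position (end-anchored placement).
    res = edlib.align(flank[:i], region, mode="HW", task="locations", k=int(prev[i]))
    if res["editDistance"] == -1 or not res["locations"]:
        return None
    start, _end = max(res["locations"], key=lambda se: se[1])
    return start or 0


def _suffix_prefix_overlap(region: str, flank: str) -> int:
    """Length of the longest suffix of ``region`` equal to a prefix of ``flank``."""
    for length in range(min(len(region), len(flank)), 0, -1):
        if region.endswith(flank[:length]):
            return length
    return 0


def orient_read(read: SeqRecord, model: AnatomyModel) -> SeqRecord:
    """Flip a read sequenced from the B end of the amplicon.

    If the region 5' of the adaptor carries the (reverse-complemented)
    3' flank while the 5' flank is absent, the read came from the other
    amplicon end and is returned reverse-complemented; otherwise it is
    returned unchanged.
    """
    loc = find_adaptor(read.bases, model)
    if loc is None:
        return read
    pre = read.bases[: loc[0]]
    fwd = _find_flank(model.flank5, pre, model.flank_edits(model.flank5))
    rev = _find_flank(revcomp(model.flank3), pre, model.flank_edits(model.flank3))
    if rev is not None and fwd is None:
        quals = read.quals[::-1] if read.quals is not None else None
        return SeqRecord(read.id, revcomp(read.bases), quals)
    return read


def dissect_read(read: SeqRecord, model: AnatomyModel) -> DissectionOutcome:
    """Split one read into its left/right genomic ends (workflow steps i-iii)."""
    loc = find_adaptor(read.bases, model)
    if loc is None:
        return DissectionOutcome("no_adaptor")
    a0, a1 = loc
    pre, post = read.bases[:a0], read.bases[a1:]

    f5 = _find_flank(model.flank5, pre, model.flank_edits(model.flank5))
    left = pre[f5[1] :] if f5 is not None else pre

    f3 = _find_flank(model.flank3, post, model.flank_edits(model.flank3))
    if f3 is not None:
        right = post[: f3[0]]
        f3_found = True
    else:
        cut = _find_flank3_overhang(post, model)
        f3_found = cut is not None
        if cut is None:
            # polish: a read ending 1..9 bases into the 3' flank leaves an
            # exact flank prefix too short for the anchored search; trim the
            # longest read suffix that exactly matches a flank3 prefix.
            cut = len(post) - _suffix_prefix_overlap(post, model.flank3)
        right = post[:cut]

    if len(left) < model.min_end_len or len(right) < model.min_end_len:
        return DissectionOutcome("end_too_short")
    pair = EndPair(
        pair_id=read.id,
        left=SeqRecord(f"{read.id}/L", left),
        right=SeqRecord(f"{read.id}/R", right),
        full_length=f5 is not None and f3_found,
        source_read_id=read.id,
    )
    return DissectionOutcome("ok", pair)


def dissect_stream(
    reads: Iterable[SeqRecord], model: AnatomyModel, orient: bool = True
) -> tuple[list[EndPair], DissectionStats]:
    """Dissect a read stream, tallying the count taxonomy of the workflow."""
    stats = DissectionStats()
    pairs: list[EndPair] = []
    for read in reads:
        stats.n_raw += 1
        if orient:
            read = orient_read(read, model)
        outcome = dissect_read(read, model)
        if outcome.status == "no_adaptor":
            stats.n_no_adaptor += 1
        elif outcome.status == "end_too_short":
            stats.n_end_too_short += 1
        else:
            stats.n_kept += 1
            assert outcome.pair is not None
            if outcome.pair.full_length:
                stats.n_full_length += 1
            pairs.append(outcome.pair)
    stats.check()
    return pairs, stats
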