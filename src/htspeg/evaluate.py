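"""Scoring pipeline output against simulator ground truth.

These helpers compare dissected ends with the genomic stubs recorded in
the truth table, count distinct fragments among kept pairs, and check
whether super-scaffolds recover the true scaffold order and orientation
for every adjacency that had enough link support.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .anatomy import EndPair
from .scaffold import LinkBundle, SuperScaffold
from .seqio import SeqRecord, revcomp


def _oriented(genome: str, start: int, end: int, strand: str) -> str:
    seq = genome[start:end]
    return revcomp(seq) if strand == "-" else seq


def pair_matches_truth(pair: EndPair, row: pd.Series, genome: str) -> bool:
    """True when both dissected ends equal their true genomic stubs.

    The left end must match the full left stub; the right end, which the
    read may truncate, must be a prefix of the full right stub.
    """
    if row["left_start"] < 0 or row["right_start"] < 0:
        return False
    left_exp = _oriented(genome, int(row["left_start"]), int(row["left_end"]), row["left_strand"])
    right_exp = _oriented(genome, int(row["right_start"]), int(row["right_end"]), row["right_strand"])
    return pair.left.bases == left_exp and right_exp.startswith(pair.right.bases)


def truth_match_fraction(pairs: Sequence[EndPair], truth: pd.DataFrame, genome: str) -> float:
    """Fraction of dissected pairs whose ends match the truth stubs."""
    if not len(pairs):
        raise ValueError("no pairs to score")
    t = truth.set_index("read_id")
    hits = sum(pair_matches_truth(p, t.loc[p.source_read_id], genome) for p in pairs)
    return hits / len(pairs)


def kept_distinct_fragments(truth: pd.DataFrame, kept_read_ids: Sequence[str]) -> int:
    """Number of distinct fragments with at least one kept read."""
    t = truth.set_index("read_id")
    return t.loc[list(kept_read_ids), "duplicate_group"].nunique()


def _canonical_junction(a: str, end_a: str, b: str, end_b: str) -> tuple[str, str, str, str]:
    return (a, b, end_a, end_b) if a <= b else (b, a, end_b, end_a)


def truth_adjacency_classes(order: Sequence[tuple[str, str]]) -> list[tuple[str, str, str, str]]:
    """Canonical junction class of each true adjacent scaffold pair.

    ``order`` lists (scaffold_id, orientation) in genome order, where
    orientation '-' means the stored scaffold is the reverse complement
    of the genome segment.
    """
    classes = []
    for (a, oa), (b, ob) in zip(order, order[1:]):
        end_a = "R" if oa == "+" else "L"
        end_b = "L" if ob == "+" else "R"
        classes.append(_canonical_junction(a, end_a, b, end_b))
    return classes


def superscaffold_junctions(superscaffolds: Sequence[SuperScaffold]) -> set[tuple[str, str, str, str]]:
    """Canonical junction classes realised by a super-scaffold set."""
    out = set()
    for ss in superscaffolds:
        for (x, ox, _g), (y, oy, _g2) in zip(ss.components, ss.components[1:]):
            end_x = "R" if ox == "+" else "L"
            end_y = "L" if oy == "+" else "R"
            out.add(_canonical_junction(x, end_x, y, end_y))
    return out


def adjacency_recovery(
    superscaffolds: Sequence[SuperScaffold],
    order: Sequence[tuple[str, str]],
    bundles: Sequence[LinkBundle],
    min_support: int = 2,
) -> tuple[int, int]:
    """(supported, recovered): true adjacencies with >= min_support links
    in a correctly-oriented bundle, and how many appear, correctly
    oriented, in the super-scaffolds."""
    support = {
        _canonical_junction(b.scaffold_a, b.joint_orientation[0], b.scaffold_b, b.joint_orientation[1]): b.support
        for b in bundles
    }
    realised = superscaffold_junctions(superscaffolds)
    n_supported = n_recovered = 0
    for cls in truth_adjacency_classes(order):
        if support.get(cls, 0) >= min_support:
            n_supported += 1
            if cls in realised:
                n_recovered += 1
    return n_supported, n_recovered
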