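"""Mate-link scaffolding: bundle cross-scaffold pairs, chain scaffolds, emit AGP.

Pairs whose two ends map uniquely to different scaffolds are evidence
that those scaffolds are neighbours.  Each such pair contributes one
link with an orientation class (which physical end of scaffold A faces
which end of scaffold B) and a per-link gap estimate

    gap = insert_size_estimate - d_A - d_B

where d is the distance from the hit to the scaffold end it points at.
Links agreeing in scaffold pair and orientation class form a bundle;
bundles need at least two links to be trusted, and bundles whose median
gap is grossly negative (mutually inconsistent placement) are dropped.

Super-scaffolds are then grown greedily: bundles are taken in decreasing
support, and one is accepted iff both scaffold ends it joins are still
free and the join closes no cycle, so the accepted bundles form simple
chains.  Chains are emitted as gapped FASTA (runs of N) plus AGP v2.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Optional, Sequence

from .mapping import PairMapping
from .seqio import SeqRecord, revcomp


@dataclass(frozen=True)
class ScaffoldParams:
    min_support: int = 2
    min_gap: int = 100
    neg_gap_factor: float = 0.5  # discard bundles with median gap < -factor * insert
    unique_only: bool = True  # only unique-unique pairs provide links


@dataclass(frozen=True)
class LinkBundle:
    """Aggregated links between one scaffold pair in one orientation class.

    ``joint_orientation`` is ``(end_of_a, end_of_b)`` with values 'L'/'R':
    the physical ends that face each other across the junction, with
    ``scaffold_a < scaffold_b`` canonically.
    """

    scaffold_a: str
    scaffold_b: str
    joint_orientation: tuple[str, str]
    support: int
    gap_estimates: tuple[int, ...]

    def __post_init__(self) -> None:
        assert self.scaffold_a != self.scaffold_b
        assert self.support >= 1 and len(self.gap_estimates) == self.support

    @property
    def median_gap(self) -> float:
        return median(self.gap_estimates)


@dataclass(frozen=True)
class SuperScaffold:
    """Ordered, oriented chain of scaffolds with estimated gaps after each."""

    id: str
    components: tuple[tuple[str, str, int], ...]  # (scaffold_id, orientation, gap_after)


@dataclass(frozen=True)
class AssemblyStats:
    n_scaffolds: int
    total_span: int
    n50: int


def _link_geometry(pm: PairMapping, lengths: dict[str, int], insert: float):
    """Orientation class and gap for one different-scaffold pair."""
    lb, rb = pm.left.best.target, pm.right.best.target
    # The mate continues downstream along the hit strand, off the scaffold end.
    if lb.strand == "+":
        end_a, d_a = "R", lengths[lb.seq_id] - lb.start
    else:
        end_a, d_a = "L", lb.end
    if rb.strand == "+":
        end_b, d_b = "L", rb.end
    else:
        end_b, d_b = "R", lengths[rb.seq_id] - rb.start
    gap = int(round(insert - d_a - d_b))
    a, b = lb.seq_id, rb.seq_id
    if a <= b:
        return (a, b, end_a, end_b), gap
    return (b, a, end_b, end_a), gap


def bundle_links(
    mappings: Sequence[PairMapping],
    scaffold_lengths: dict[str, int],
    insert_size_estimate: float,
    params: ScaffoldParams | None = None,
) -> list[LinkBundle]:
    """Group cross-scaffold pairs into orientation-consistent link bundles.

    ``insert_size_estimate`` should come from the same-scaffold span
    distribution (its median).  Bundles with fewer than ``min_support``
    links, or whose median gap is below ``-neg_gap_factor * insert``,
    are discarded.
    """
    if insert_size_estimate <= 0:
        raise ValueError("insert_size_estimate must be positive")
    params = params or ScaffoldParams()
    groups: dict[tuple, list[int]] = {}
    for pm in mappings:
        if pm.map_class != "both_mapped" or pm.locality != "different_scaffolds":
            continue
        if params.unique_only and pm.uniqueness != "unique":
            continue
        key, gap = _link_geometry(pm, scaffold_lengths, insert_size_estimate)
        groups.setdefault(key, []).append(gap)
    bundles = []
    for (a, b, ea, eb), gaps in sorted(groups.items()):
        if len(gaps) < params.min_support:
            continue
        bundle = LinkBundle(a, b, (ea, eb), len(gaps), tuple(gaps))
        if bundle.median_gap < -params.neg_gap_factor * insert_size_estimate:
            continue
        bundles.append(bundle)
    return bundles


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def build_superscaffolds(
    bundles: Sequence[LinkBundle],
    scaffold_ids: Sequence[str],
    params: ScaffoldParams | None = None,
) -> list[SuperScaffold]:
    """Greedy chain growing with cycle rejection.

    Bundles are tried in increasing absolute median gap (ties: higher
    support, then scaffold pair id); a bundle is accepted iff both
    scaffold ends it joins are free and it closes no cycle.  Nearest
    neighbours first matters with a single large-insert library: a pair
    whose insert spans a whole intermediate scaffold produces a perfectly
    consistent "skip" bundle whose gap estimate is roughly the skipped
    scaffold's length, and such bundles can carry more links than the
    direct adjacency; taking small-gap bundles first keeps intermediate
    scaffolds in the chain instead of orphaning them.  Every scaffold
    appears in exactly one output chain; unjoined scaffolds pass through
    as singletons.  Output is independent of the bundles' input order.
    """
    params = params or ScaffoldParams()
    order = sorted(
        bundles, key=lambda b: (abs(b.median_gap), -b.support, b.scaffold_a, b.scaffold_b)
    )
    used_ends: set[tuple[str, str]] = set()
    uf = _UnionFind()
    accepted: list[LinkBundle] = []
    for b in order:
        pa, pb = (b.scaffold_a, b.joint_orientation[0]), (b.scaffold_b, b.joint_orientation[1])
        if pa in used_ends or pb in used_ends:
            continue
        if uf.find(b.scaffold_a) == uf.find(b.scaffold_b):
            continue  # would close a cycle
        used_ends.update((pa, pb))
        uf.union(b.scaffold_a, b.scaffold_b)
        accepted.append(b)

    # adjacency: (scaffold, end) -> (other scaffold, other end, gap)
    joins: dict[tuple[str, str], tuple[str, str, int]] = {}
    for b in accepted:
        gap = max(int(round(b.median_gap)), params.min_gap)
        pa = (b.scaffold_a, b.joint_orientation[0])
        pb = (b.scaffold_b, b.joint_orientation[1])
        joins[pa] = (*pb, gap)
        joins[pb] = (*pa, gap)

    degree: dict[str, int] = {}
    for sid, _end in joins:
        degree[sid] = degree.get(sid, 0) + 1
    chains: list[SuperScaffold] = []
    seen: set[str] = set()
    n = 0

    def walk(start: str, entry_end: str) -> list[tuple[str, str, int]]:
        """Traverse a chain left to right; a component's right-facing port
        is the one engaged in the join to the next component."""
        comps = []
        sid, entry = start, entry_end
        while True:
            seen.add(sid)
            exit_end = "R" if entry == "L" else "L"
            orient = "+" if entry == "L" else "-"
            nxt = joins.get((sid, exit_end))
            if nxt is None:
                comps.append((sid, orient, 0))
                return comps
            comps.append((sid, orient, nxt[2]))
            sid, entry = nxt[0], nxt[1]

    # endpoints: scaffolds using only one of their two ends
    endpoints = sorted(sid for sid, deg in degree.items() if deg == 1)
    for sid in endpoints:
        if sid in seen:
            continue
        free_end = "L" if (sid, "L") not in joins else "R"
        # enter through the unused end so the used end faces the chain
        chains.append(SuperScaffold(f"superscaffold_{n:04d}", tuple(walk(sid, free_end))))
        n += 1
    for sid in sorted(scaffold_ids):
        if sid not in seen:
            chains.append(SuperScaffold(f"superscaffold_{n:04d}", (((sid, "+", 0)),)))
            seen.add(sid)
            n += 1
    return chains


def emit(
    superscaffolds: Sequence[SuperScaffold],
    scaffolds: dict[str, str],
    fasta_path: str | Path,
    agp_path: str | Path,
) -> list[SeqRecord]:
    """Write gapped FASTA and AGP v2.1 for the super-scaffolds."""
    records = []
    agp_lines = []
    for ss in superscaffolds:
        parts = []
        pos = 0  # 0-based running coordinate
        part_number = 0
        for i, (sid, orient, gap_after) in enumerate(ss.components):
            try:
                seq = scaffolds[sid]
            except KeyError:
                raise ValueError(f"component sequence missing: {sid}") from None
            parts.append(revcomp(seq) if orient == "-" else seq)
            part_number += 1
            agp_lines.append(
                f"{ss.id}\t{pos + 1}\t{pos + len(seq)}\t{part_number}\tW\t{sid}\t1\t{len(seq)}\t{orient}"
            )
            pos += len(seq)
            if i < len(ss.components) - 1:
                parts.append("N" * gap_after)
                part_number += 1
                agp_lines.append(
                    f"{ss.id}\t{pos + 1}\t{pos + gap_after}\t{part_number}\tN\t{gap_after}\tscaffold\tyes\tpaired-ends"
                )
                pos += gap_after
        records.append(SeqRecord(ss.id, "".join(parts)))
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), 80):
                fh.write(rec.bases[i : i + 80] + "\n")
    with open(agp_path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        fh.write("\n".join(agp_lines) + "\n")
    return records


def parse_agp(path: str | Path) -> list[SuperScaffold]:
    """Read back an AGP v2.1 file written by :func:`emit`."""
    objects: dict[str, list[tuple[str, str, int]]] = {}
    pending_gap: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            obj = f[0]
            if obj not in objects:
                objects[obj] = []
                order.append(obj)
            if f[4] == "W":
                if objects[obj]:
                    sid, orient, _g = objects[obj][-1]
                    objects[obj][-1] = (sid, orient, pending_gap.pop(obj, 0))
                objects[obj].append((f[5], f[8], 0))
            elif f[4] == "N":
                pending_gap[obj] = int(f[5])
    return [SuperScaffold(obj, tuple(objects[obj])) for obj in order]


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """n, total span and N50 (length where the descending cumulative sum
    first reaches half the total)."""
    if not lengths:
        raise ValueError("empty record set")
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    acc = 0
    for l in ls:
        acc += l
        if 2 * acc >= total:
            return AssemblyStats(len(ls), total, l)
    raise AssertionError("unreachable")


def n50_gain(n50_before: int, n50_after: int) -> tuple[int, float]:
    """Absolute and percentage N50 improvement."""
    diff = n50_after - n50_before
    return diff, 100.0 * diff / n50_before
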