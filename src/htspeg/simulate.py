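"""Synthetic BAC paired-end library generator with complete ground truth.

The generative model follows the wet-lab protocol the pipeline is built
for: a circular vector (8,128 bp) carrying a large genomic insert is
hydrodynamically sheared to 8-10 kb keeping only fragments that contain
the whole vector; hairpin adaptors are ligated, the hairpin is opened at
its EcoRI site and the fragment re-circularised, so the two insert
termini end up joined by the intact 44-nt palindromic adaptor;
paired-end PCR across the vector flanks yields an amplicon

    primerA-tail + 5' flank + left stub + adaptor + right stub + 3' flank + rc(primerB-tail)

and double size selection keeps amplicons of 400-500 bp, which also
removes the fixed-size flank-only amplicons of insert-free (negative)
clones.  Each surviving fragment is PCR-duplicated, a configurable
fraction is chimeric (strand-flipped junction or a stub from another
clone), and reads are emitted as error-bearing prefixes of the amplicon.

Every emitted read carries a truth record (clone, stub coordinates,
chimera/duplicate status) so downstream stages can be scored exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .anatomy import HAIRPIN_ADAPTOR, VECTOR_FLANK5, VECTOR_FLANK3
from .seqio import GenomicInterval, SeqRecord, revcomp, write_fasta, write_fastq

# 454-style sequencing-primer tails of the two PE-PCR chimeric primers
# (their 3' portions are the first 20 nt of the 5' flank and the reverse
# complement of the tail of the 3' flank, so they add no extra vector
# sequence beyond the flanks themselves).
PRIMER_A_TAIL = "CGTATCGCCTCCCTCGCGCCATCAG"
PRIMER_B_TAIL = "CTATGCGCCTTGCCAGCCCGCTCAG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Simulator configuration violates a model constraint."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the library-prep and sequencing model.

    Defaults reproduce the amphioxus BAC library the pipeline defaults
    are modelled on, at desk scale: 2 Mb synthetic genome, ~95 kb inserts,
    12% insert-free clones, 8,128 bp vector, 8-10 kb shearing, 400-500 bp
    amplicon size selection, ~350 nt reads, ~35 PCR copies per fragment
    and a chimera rate whose orientation-flip half reproduces the ~6.9%
    wrong-orientation rate observed for this chemistry.
    """

    genome_length: int = 2_000_000
    n_scaffold_breaks: int = 19
    n_clones: int = 10_000
    negative_clone_fraction: float = 0.12
    insert_mean: float = 95_000.0
    insert_sd: float = 10_000.0
    vector_length: int = 8_128
    shear_min: int = 8_000
    shear_max: int = 10_000
    amplicon_min: int = 400
    amplicon_max: int = 500
    read_len_mean: float = 350.0
    read_len_sd: float = 30.0
    subst_rate: float = 0.005
    homopolymer_indel_rate: float = 0.003
    chimera_fraction: float = 0.14
    chimera_flip_fraction: float = 0.5
    duplication_mean: float = 34.0
    bidirectional: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "negative_clone_fraction",
            "subst_rate",
            "homopolymer_indel_rate",
            "chimera_fraction",
            "chimera_flip_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if self.shear_max <= self.vector_length:
            raise ConfigError("shear_max must exceed vector_length, else no genomic stub can exist")
        if self.insert_mean <= self.shear_max:
            raise ConfigError("insert_mean must exceed shear_max")
        if self.amplicon_min >= self.amplicon_max:
            raise ConfigError("amplicon size window must be positive")
        if self.shear_min > self.shear_max:
            raise ConfigError("shear_min must not exceed shear_max")
        if self.duplication_mean < 0:
            raise ConfigError("duplication_mean must be >= 0")

    def rngs(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams derived from the single seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("genome", "library", "amplicons", "reads")
        return dict(zip(names, (np.random.default_rng(c) for c in ss.spawn(len(names)))))


@dataclass(frozen=True)
class CloneTruth:
    clone_id: str
    insert: Optional[GenomicInterval]  # absent for negative clones
    insert_orientation: str  # '+' or '-' relative to the vector
    is_negative: bool

    def __post_init__(self) -> None:
        if self.is_negative and self.insert is not None:
            raise ValueError("negative clones carry no insert")
        if not self.is_negative and self.insert is None:
            raise ValueError("positive clones must carry an insert")


@dataclass(frozen=True)
class FragmentTruth:
    """Ground truth for one retained (size-selected) amplicon."""

    fragment_id: str
    clone_id: str
    left_truth: Optional[GenomicInterval]  # None when the stub has length 0
    right_truth: Optional[GenomicInterval]
    is_chimeric: bool
    chimera_class: str  # "", "flip" or "partner"
    true_span: int  # insert length; -1 for partner chimeras


def fixed_amplicon_length(
    flank5: str = VECTOR_FLANK5, flank3: str = VECTOR_FLANK3, adaptor: str = HAIRPIN_ADAPTOR
) -> int:
    """Amplicon length contributed by primer tails, flanks and adaptor alone.

    This is the full length of a negative-clone (insert-free) amplicon;
    with the default anatomy it is 213 bp, below the 400 bp size-selection
    floor, which is how insert-free clones drop out of the library.
    """
    return len(PRIMER_A_TAIL) + len(flank5) + len(adaptor) + len(flank3) + len(PRIMER_B_TAIL)


def simulate_genome(
    config: SimConfig,
) -> tuple[SeqRecord, list[SeqRecord], list[tuple[str, str]]]:
    """Generate the true genome and a scaffold fragmentation of it.

    Returns ``(genome, scaffolds, order)`` where ``order`` lists
    ``(scaffold_id, orientation)`` in true genome order; a scaffold with
    orientation '-' is stored reverse-complemented in ``scaffolds``, so
    re-orienting and concatenating along ``order`` reconstructs the genome.
    """
    if config.genome_length < 10 * config.insert_mean:
        raise ConfigError(
            f"genome_length {config.genome_length} < 10 x insert_mean {config.insert_mean}"
        )
    rng = config.rngs()["genome"]
    codes = rng.integers(0, 4, config.genome_length, dtype=np.uint8)
    genome = SeqRecord("genome", _BASES[codes].tobytes().decode())

    n_breaks = config.n_scaffold_breaks
    if n_breaks >= config.genome_length:
        raise ConfigError("more scaffold breaks than genome positions")
    breaks = np.sort(rng.choice(np.arange(1, config.genome_length), n_breaks, replace=False))
    bounds = [0, *breaks.tolist(), config.genome_length]
    numbering = rng.permutation(n_breaks + 1)
    flips = rng.random(n_breaks + 1) < 0.5
    scaffolds: list[SeqRecord] = []
    order: list[tuple[str, str]] = []
    for i in range(n_breaks + 1):
        sid = f"scaffold_{numbering[i]:04d}"
        seq = genome.bases[bounds[i] : bounds[i + 1]]
        orient = "-" if flips[i] else "+"
        scaffolds.append(SeqRecord(sid, revcomp(seq) if orient == "-" else seq))
        order.append((sid, orient))
    scaffolds.sort(key=lambda r: r.id)
    return genome, scaffolds, order


def simulate_library(config: SimConfig, genome: SeqRecord) -> list[CloneTruth]:
    """Draw the clone population: insert coordinates and negative clones."""
    rng = config.rngs()["library"]
    n = config.n_clones
    negatives = rng.random(n) < config.negative_clone_fraction
    glen = len(genome.bases)
    lengths = np.rint(rng.normal(config.insert_mean, config.insert_sd, n)).astype(np.int64)
    bad = (lengths <= 0) | (lengths > glen)
    while bad.any():  # truncate the insert-size normal to (0, genome_length]
        lengths[bad] = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, int(bad.sum()))
        ).astype(np.int64)
        bad = (lengths <= 0) | (lengths > glen)
    starts = rng.integers(0, glen - lengths + 1)
    orients = np.where(rng.random(n) < 0.5, "+", "-")
    clones = []
    for i in range(n):
        if negatives[i]:
            clones.append(CloneTruth(f"clone_{i:06d}", None, "+", True))
        else:
            iv = GenomicInterval("genome", int(starts[i]), int(starts[i] + lengths[i]), "+")
            clones.append(CloneTruth(f"clone_{i:06d}", iv, str(orients[i]), False))
    return clones


def _terminus_stubs(
    genome: str, insert: GenomicInterval, orient: str, left_len: int, right_len: int
) -> tuple[str, Optional[GenomicInterval], str, Optional[GenomicInterval]]:
    """Sequences/intervals of the two insert-terminus stubs in amplicon order.

    The amplicon traverses 5' flank -> left stub -> adaptor -> right stub
    -> 3' flank; for a '+'-oriented insert the left stub is the insert
    head read forward and the right stub the insert tail read forward, so
    both ends later map to the same genomic strand in head-to-tail order.
    """
    s, e = insert.start, insert.end
    if orient == "+":
        left = genome[s : s + left_len]
        left_iv = GenomicInterval(insert.seq_id, s, s + left_len, "+") if left_len else None
        right = genome[e - right_len : e]
        right_iv = GenomicInterval(insert.seq_id, e - right_len, e, "+") if right_len else None
    else:
        left = revcomp(genome[e - left_len : e])
        left_iv = GenomicInterval(insert.seq_id, e - left_len, e, "-") if left_len else None
        right = revcomp(genome[s : s + right_len])
        right_iv = GenomicInterval(insert.seq_id, s, s + right_len, "-") if right_len else None
    return left, left_iv, right, right_iv


def simulate_amplicons(
    config: SimConfig, clones: list[CloneTruth], genome: SeqRecord
) -> list[tuple[str, FragmentTruth]]:
    """Shear, re-circularise, amplify and size-select; returns retained amplicons."""
    rng = config.rngs()["amplicons"]
    n = len(clones)
    windows = rng.integers(config.shear_min, config.shear_max + 1, n)
    place_frac = rng.random(n)
    chim_u = rng.random(n)
    flip_u = rng.random(n)
    partner_pick = rng.integers(0, n, n)

    positive_idx = [i for i, c in enumerate(clones) if not c.is_negative]
    fixed = fixed_amplicon_length()
    g = genome.bases
    out: list[tuple[str, FragmentTruth]] = []
    k = 0
    for i, clone in enumerate(clones):
        if clone.is_negative:
            total = 0  # flank-only amplicon
            left_len = right_len = 0
        else:
            total = int(windows[i]) - config.vector_length
            if total < 0:
                continue  # shear window cut the vector; fragment is lost
            left_len = int(place_frac[i] * (total + 1))
            right_len = total - left_len
        amp_len = fixed + total
        if not (config.amplicon_min <= amp_len <= config.amplicon_max):
            continue  # double size selection
        if clone.is_negative:
            left_seq, left_iv, right_seq, right_iv = "", None, "", None
            chim, chim_class, span = False, "", 0
        else:
            assert clone.insert is not None
            left_seq, left_iv, right_seq, right_iv = _terminus_stubs(
                g, clone.insert, clone.insert_orientation, left_len, right_len
            )
            span = len(clone.insert)
            chim = chim_u[i] < config.chimera_fraction
            chim_class = ""
            if chim and right_len > 0:
                if flip_u[i] < config.chimera_flip_fraction:
                    chim_class = "flip"
                    right_seq = revcomp(right_seq)
                    assert right_iv is not None
                    right_iv = GenomicInterval(
                        right_iv.seq_id,
                        right_iv.start,
                        right_iv.end,
                        "-" if right_iv.strand == "+" else "+",
                    )
                else:
                    chim_class = "partner"
                    j = positive_idx[partner_pick[i] % len(positive_idx)]
                    if j == i and len(positive_idx) > 1:
                        j = positive_idx[(partner_pick[i] + 1) % len(positive_idx)]
                    other = clones[j]
                    assert other.insert is not None
                    _, _, right_seq, right_iv = _terminus_stubs(
                        g, other.insert, other.insert_orientation, 0, right_len
                    )
                    span = -1
            else:
                chim = False
        amplicon = (
            PRIMER_A_TAIL
            + VECTOR_FLANK5
            + left_seq
            + HAIRPIN_ADAPTOR
            + right_seq
            + VECTOR_FLANK3
            + revcomp(PRIMER_B_TAIL)
        )
        assert len(amplicon) == amp_len
        truth = FragmentTruth(
            fragment_id=f"frag_{k:06d}",
            clone_id=clone.clone_id,
            left_truth=left_iv,
            right_truth=right_iv,
            is_chimeric=chim,
            chimera_class=chim_class,
            true_span=span,
        )
        out.append((amplicon, truth))
        k += 1
    return out


_HOMOPOLYMER = re.compile(r"A{2,}|C{2,}|G{2,}|T{2,}")


def _sequencing_errors(read: str, rng: np.random.Generator, config: SimConfig) -> str:
    """Apply substitutions and 454-like +-1 homopolymer-length errors."""
    if config.subst_rate > 0 and read:
        codes = np.frombuffer(read.encode(), dtype=np.uint8).copy()
        k = rng.binomial(len(read), config.subst_rate)
        if k:
            pos = rng.choice(len(read), size=k, replace=False)
            lut = np.full(256, 0, dtype=np.uint8)
            for v, b in enumerate(b"ACGT"):
                lut[b] = v
            shift = rng.integers(1, 4, size=k).astype(np.uint8)
            codes[pos] = _BASES[(lut[codes[pos]] + shift) % 4]
        read = codes.tobytes().decode()
    if config.homopolymer_indel_rate > 0:
        runs = [(m.start(), m.end()) for m in _HOMOPOLYMER.finditer(read)]
        if runs:
            hit = rng.random(len(runs)) < config.homopolymer_indel_rate
            grow = rng.random(len(runs)) < 0.5
            edited = []
            prev = 0
            for (s, e), h, gr in zip(runs, hit, grow):
                edited.append(read[prev:s])
                run = read[s:e]
                if h:
                    run = run + run[0] if gr else run[:-1]
                edited.append(run)
                prev = e
            edited.append(read[prev:])
            read = "".join(edited)
    return read


def simulate_reads(
    config: SimConfig, amplicons: list[tuple[str, FragmentTruth]]
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Emit one read per PCR copy of each amplicon plus the truth table."""
    rng = config.rngs()["reads"]
    reads: list[SeqRecord] = []
    rows: list[dict] = []
    for amplicon, truth in amplicons:
        n_copies = int(rng.poisson(config.duplication_mean)) + 1
        for c in range(n_copies):
            read_len = int(round(rng.normal(config.read_len_mean, config.read_len_sd)))
            read_len = max(20, min(read_len, len(amplicon)))
            direction = "A"
            template = amplicon
            if config.bidirectional and rng.random() < 0.5:
                direction = "B"
                template = revcomp(amplicon)
            read = template[:read_len]
            read = _sequencing_errors(read, rng, config)
            read_id = f"{truth.fragment_id}.{c:02d}"
            reads.append(SeqRecord(read_id, read, "?" * len(read)))
            rows.append(
                {
                    "read_id": read_id,
                    "clone_id": truth.clone_id,
                    "duplicate_group": truth.fragment_id,
                    "is_chimeric": int(truth.is_chimeric),
                    "chimera_class": truth.chimera_class,
                    "read_dir": direction,
                    "left_seq_id": truth.left_truth.seq_id if truth.left_truth else "",
                    "left_start": truth.left_truth.start if truth.left_truth else -1,
                    "left_end": truth.left_truth.end if truth.left_truth else -1,
                    "left_strand": truth.left_truth.strand if truth.left_truth else "",
                    "right_seq_id": truth.right_truth.seq_id if truth.right_truth else "",
                    "right_start": truth.right_truth.start if truth.right_truth else -1,
                    "right_end": truth.right_truth.end if truth.right_truth else -1,
                    "right_strand": truth.right_truth.strand if truth.right_truth else "",
                    "true_span": truth.true_span,
                }
            )
    return reads, pd.DataFrame(rows)


def run_simulation(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generative model and write all outputs to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, scaffolds, order = simulate_genome(config)
    clones = simulate_library(config, genome)
    amplicons = simulate_amplicons(config, clones, genome)
    reads, truth = simulate_reads(config, amplicons)

    paths = {
        "genome": outdir / "genome.fasta",
        "scaffolds": outdir / "scaffolds.fasta",
        "scaffold_order": outdir / "scaffold_order.tsv",
        "clones": outdir / "clones.tsv",
        "reads": outdir / "reads.fastq",
        "read_truth": outdir / "read_truth.tsv",
    }
    write_fasta([genome], paths["genome"])
    write_fasta(scaffolds, paths["scaffolds"])
    pd.DataFrame(order, columns=["scaffold_id", "orientation"]).to_csv(
        paths["scaffold_order"], sep="\t", index=False
    )
    clone_rows = [
        {
            "clone_id": c.clone_id,
            "is_negative": int(c.is_negative),
            "seq_id": c.insert.seq_id if c.insert else "",
            "start": c.insert.start if c.insert else -1,
            "end": c.insert.end if c.insert else -1,
            "insert_orientation": c.insert_orientation,
        }
        for c in clones
    ]
    pd.DataFrame(clone_rows).to_csv(paths["clones"], sep="\t", index=False)
    write_fastq(reads, paths["reads"])
    truth.to_csv(paths["read_truth"], sep="\t", index=False)
    return paths
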