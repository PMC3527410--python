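"""File-based pipeline stages and the end-to-end driver.

Every stage communicates through documented FASTA/FASTQ/TSV files so that
real data can enter at any stage boundary; ``run_all`` simply chains the
stages inside one output directory and renders the consolidated report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .anatomy import AnatomyModel, DissectionStats, EndPair, dissect_stream
from .cluster import ClusterParams, cluster_pairs, greedy_cluster, merge_pairs, saturation_curve
from .mapping import (
    Hit,
    KmerIndex,
    MapParams,
    MapResult,
    PairMapping,
    QcReport,
    classify_pair,
    map_pairs,
    qc_report,
)
from .report import render_report
from .scaffold import (
    AssemblyStats,
    ScaffoldParams,
    assembly_stats,
    build_superscaffolds,
    bundle_links,
    emit,
)
from .seqio import GenomicInterval, SeqRecord, read_fasta, read_fastq, write_fasta
from .simulate import SimConfig, run_simulation

logger = logging.getLogger(__name__)


def read_any(path: str | Path):
    """Read FASTA or FASTQ based on the file suffix."""
    suffixes = {s.lower() for s in Path(path).suffixes}
    if suffixes & {".fastq", ".fq"}:
        return read_fastq(path)
    return read_fasta(path)


# ---------------------------------------------------------------- dissect

def stage_dissect(
    reads_path: str | Path,
    outdir: str | Path,
    model: AnatomyModel | None = None,
    orient: bool = True,
) -> tuple[list[EndPair], DissectionStats]:
    """Dissect reads into paired end FASTA files plus a stats table."""
    model = model or AnatomyModel()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pairs, stats = dissect_stream(read_any(reads_path), model, orient=orient)
    write_end_pairs(pairs, outdir / "left.fasta", outdir / "right.fasta", outdir / "pairs.tsv")
    pd.DataFrame(
        [
            {
                "raw_reads": stats.n_raw,
                "no_adaptor": stats.n_no_adaptor,
                "with_adaptor": stats.n_with_adaptor,
                "end_too_short": stats.n_end_too_short,
                "kept_pairs": stats.n_kept,
                "full_length_pairs": stats.n_full_length,
            }
        ]
    ).to_csv(outdir / "dissect_stats.tsv", sep="\t", index=False)
    return pairs, stats


def write_end_pairs(
    pairs: Sequence[EndPair], left_path: Path, right_path: Path, table_path: Optional[Path] = None
) -> None:
    write_fasta([SeqRecord(p.pair_id, p.left.bases) for p in pairs], left_path)
    write_fasta([SeqRecord(p.pair_id, p.right.bases) for p in pairs], right_path)
    if table_path is not None:
        pd.DataFrame(
            [
                {
                    "pair_id": p.pair_id,
                    "full_length": int(p.full_length),
                    "left_len": len(p.left.bases),
                    "right_len": len(p.right.bases),
                }
                for p in pairs
            ]
        ).to_csv(table_path, sep="\t", index=False)


def load_end_pairs(
    left_path: str | Path, right_path: str | Path, table_path: str | Path | None = None
) -> list[EndPair]:
    """Rebuild end pairs from paired FASTA files (ids must correspond)."""
    left = {r.id: r for r in read_fasta(left_path)}
    right = {r.id: r for r in read_fasta(right_path)}
    if set(left) != set(right):
        raise ValueError("left/right FASTA files carry different pair ids")
    full = {}
    if table_path is not None:
        t = pd.read_csv(table_path, sep="\t")
        full = dict(zip(t["pair_id"], t["full_length"].astype(bool)))
    return [
        EndPair(
            pair_id=pid,
            left=SeqRecord(f"{pid}/L", left[pid].bases),
            right=SeqRecord(f"{pid}/R", right[pid].bases),
            full_length=bool(full.get(pid, False)),
            source_read_id=pid,
        )
        for pid in sorted(left)
    ]


# ------------------------------------------------------------------ dedup

def stage_dedup(
    pairs: Sequence[EndPair], outdir: str | Path, params: ClusterParams | None = None
) -> list[EndPair]:
    """Collapse redundant pairs; writes non-redundant FASTA + cluster table."""
    params = params or ClusterParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    left = greedy_cluster({p.left.id: p.left.bases for p in pairs}, params)
    right = greedy_cluster({p.right.id: p.right.bases for p in pairs}, params)
    reps, groups = merge_pairs(pairs, left, right)
    rep_ids = {p.pair_id for p in reps}
    pd.DataFrame(
        [
            {
                "pair_id": p.pair_id,
                "left_cluster": left.end_to_cluster[p.left.id],
                "right_cluster": right.end_to_cluster[p.right.id],
                "representative": int(p.pair_id in rep_ids),
            }
            for p in pairs
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    write_end_pairs(
        reps, outdir / "nonredundant_left.fasta", outdir / "nonredundant_right.fasta",
        outdir / "nonredundant_pairs.tsv",
    )
    return reps


# -------------------------------------------------------------------- map

_PAIR_COLUMNS = [
    "pair_id", "map_class", "pair_uniqueness", "locality", "orientation", "span",
]
_END_COLUMNS = ["scaffold", "start", "end", "strand", "score", "aln_len", "identity", "uniqueness"]


def write_pair_mappings(mappings: Sequence[PairMapping], path: str | Path) -> None:
    rows = []
    for pm in mappings:
        row = {
            "pair_id": pm.pair_id,
            "map_class": pm.map_class,
            "pair_uniqueness": pm.uniqueness or "",
            "locality": pm.locality or "",
            "orientation": pm.orientation or "",
            "span": pm.span if pm.span is not None else -1,
        }
        for side, res in (("left", pm.left), ("right", pm.right)):
            b = res.best
            row.update(
                {
                    f"{side}_scaffold": b.target.seq_id if b else "",
                    f"{side}_start": b.target.start if b else -1,
                    f"{side}_end": b.target.end if b else -1,
                    f"{side}_strand": b.target.strand if b else "",
                    f"{side}_score": b.score if b else 0,
                    f"{side}_aln_len": b.aln_len if b else 0,
                    f"{side}_identity": round(b.identity, 4) if b else 0.0,
                    f"{side}_uniqueness": res.uniqueness or "",
                }
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_pair_mappings(path: str | Path) -> list[PairMapping]:
    """Rebuild pair classifications (best hits only) from the mapping table."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        results = {}
        for side in ("left", "right"):
            if r[f"{side}_scaffold"]:
                hit = Hit(
                    end_id=f"{r['pair_id']}/{side[0].upper()}",
                    target=GenomicInterval(
                        str(r[f"{side}_scaffold"]), int(r[f"{side}_start"]),
                        int(r[f"{side}_end"]), str(r[f"{side}_strand"]),
                    ),
                    identity=float(r[f"{side}_identity"]),
                    aln_len=int(r[f"{side}_aln_len"]),
                    score=int(r[f"{side}_score"]),
                    matches=0,
                )
                results[side] = MapResult(hit.end_id, (hit,), hit, str(r[f"{side}_uniqueness"]))
            else:
                results[side] = MapResult(f"{r['pair_id']}/{side[0].upper()}", (), None, None)
        out.append(classify_pair(str(r["pair_id"]), results["left"], results["right"]))
    return out


def stage_map(
    pairs: Sequence[EndPair],
    scaffolds: Sequence[SeqRecord],
    outdir: str | Path,
    params: MapParams | None = None,
    prefix: str = "",
    n_kept: int | None = None,
    index: KmerIndex | None = None,
) -> tuple[list[PairMapping], QcReport]:
    """Map pairs against scaffolds; writes the pair-classification table."""
    params = params or MapParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = index or KmerIndex(scaffolds, params)
    mappings = map_pairs(pairs, index, params)
    qc = qc_report(mappings, n_kept=n_kept)
    write_pair_mappings(mappings, outdir / f"{prefix}pair_mappings.tsv")
    return mappings, qc


# ---------------------------------------------------------------- scaffold

def stage_scaffold(
    mappings: Sequence[PairMapping],
    scaffolds: Sequence[SeqRecord],
    insert_size_estimate: float,
    outdir: str | Path,
    params: ScaffoldParams | None = None,
):
    """Bundle links, build super-scaffolds, emit FASTA/AGP and stats."""
    params = params or ScaffoldParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = {r.id: len(r.bases) for r in scaffolds}
    bundles = bundle_links(mappings, lengths, insert_size_estimate, params)
    superscaffolds = build_superscaffolds(bundles, list(lengths), params)
    records = emit(
        superscaffolds,
        {r.id: r.bases for r in scaffolds},
        outdir / "superscaffolds.fasta",
        outdir / "superscaffolds.agp",
    )
    before = assembly_stats([len(r.bases) for r in scaffolds])
    after = assembly_stats([len(r.bases) for r in records])
    pd.DataFrame(
        [
            {"stage": "before", "n_scaffolds": before.n_scaffolds, "span_bp": before.total_span, "n50_bp": before.n50},
            {"stage": "after", "n_scaffolds": after.n_scaffolds, "span_bp": after.total_span, "n50_bp": after.n50},
        ]
    ).to_csv(outdir / "assembly_stats.tsv", sep="\t", index=False)
    return bundles, superscaffolds, before, after


# ---------------------------------------------------------------- run-all

@dataclass
class PipelineConfig:
    """Everything needed for an end-to-end run.

    Either ``sim`` is set (a fully synthetic run) or ``reads`` and
    ``scaffolds`` point at existing files.
    """

    outdir: Path
    sim: Optional[SimConfig] = None
    reads: Optional[Path] = None
    scaffolds: Optional[Path] = None
    anatomy: AnatomyModel = field(default_factory=AnatomyModel)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    mapping: MapParams = field(default_factory=MapParams)
    scaffolding: ScaffoldParams = field(default_factory=ScaffoldParams)
    saturation_sizes: Optional[list[int]] = None
    saturation_replicates: int = 3
    orient_reads: bool = True
    seed: int = 0


def run_all(config: PipelineConfig) -> dict:
    """Execute simulate (optional) -> dissect -> dedup -> map -> saturate
    (optional) -> scaffold and render the consolidated report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.sim is not None:
        sim_paths = run_simulation(config.sim, outdir)
        reads_path = sim_paths["reads"]
        scaffolds_path = sim_paths["scaffolds"]
    else:
        if config.reads is None or config.scaffolds is None:
            raise ValueError("either sim or both reads and scaffolds must be given")
        reads_path, scaffolds_path = Path(config.reads), Path(config.scaffolds)

    pairs, stats = stage_dissect(reads_path, outdir, config.anatomy, orient=config.orient_reads)
    reps = stage_dedup(pairs, outdir, config.cluster)
    n_nonred_full = sum(p.full_length for p in reps)

    scaffolds = list(read_fasta(scaffolds_path))
    index = KmerIndex(scaffolds, config.mapping)
    mappings_all, qc_all = stage_map(
        pairs, scaffolds, outdir, config.mapping, prefix="all_", n_kept=stats.n_kept, index=index
    )
    mappings_nr, qc_nr = stage_map(
        reps, scaffolds, outdir, config.mapping, prefix="nonredundant_",
        n_kept=len(reps), index=index,
    )

    saturation = None
    if config.saturation_sizes:
        saturation = saturation_curve(
            pairs, config.saturation_sizes, config.saturation_replicates,
            config.seed, config.cluster,
        )
        saturation.to_csv(outdir / "saturation.tsv", sep="\t", index=False)

    bundles: list = []
    superscaffolds: list = []
    before = after = None
    if qc_nr.span_median is not None:
        bundles, superscaffolds, before, after = stage_scaffold(
            mappings_nr, scaffolds, qc_nr.span_median, outdir, config.scaffolding
        )
    else:
        logger.warning("no same-scaffold proper pairs; skipping scaffolding stage")

    params = {
        "identity_threshold": config.cluster.identity_threshold,
        "min_identity": config.mapping.min_identity,
        "min_aln_len": config.mapping.min_aln_len,
        "min_end_len": config.anatomy.min_end_len,
        "min_support": config.scaffolding.min_support,
    }
    text = render_report(
        stats, len(reps), n_nonred_full, qc_all, qc_nr,
        seed=config.seed, params=params, saturation=saturation,
        stats_before=before, stats_after=after,
    )
    (outdir / "report.txt").write_text(text)
    return {
        "pairs": pairs,
        "stats": stats,
        "nonredundant": reps,
        "qc_all": qc_all,
        "qc_nonredundant": qc_nr,
        "saturation": saturation,
        "bundles": bundles,
        "superscaffolds": superscaffolds,
        "assembly_before": before,
        "assembly_after": after,
        "report": text,
    }
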