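"""End-to-end pipeline orchestration and run manifest.

Stages run in a fixed order: simulate (or load) the genome pair ->
ortholog anchoring -> synteny chaining -> loss candidates -> the four
filters -> classification -> report.  Re-running with an identical
configuration reproduces byte-identical outputs; the manifest records a
SHA-256 digest and record count for every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import __version__, io
from .genome import AnnotatedGenome
from .loss import (
    DepthTrack,
    FilterThresholds,
    LossStatus,
    detect_losses,
    depth_track_from_bed,
    map_reads,
    status_counts,
)
from .orthology import reciprocal_best_hits
from .simulate import SimConfig, simulate_pair, simulate_reads, write_truth_table
from .synteny import chain_anchors, rank_anchors

logger = logging.getLogger("syntloss.pipeline")


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a YAML key-value file."""

    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    # synteny chaining
    max_gap: int = 10
    min_block_size: int = 4
    gap_penalty: float = 1.0
    # orthology
    anchor_min_identity: float = 0.3
    anchor_min_coverage: float = 0.5
    # read mapping
    seed_len: int = 31
    max_mismatch_frac: float = 0.10
    # external inputs (used when simulate is False)
    ref_fasta: str | None = None
    ref_gff3: str | None = None
    ref_proteins: str | None = None
    query_fasta: str | None = None
    query_gff3: str | None = None
    query_proteins: str | None = None
    reads_fastq: str | None = None
    depth_bed: str | None = None
    unanchored_prefix: str = "scaffold_un_"

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        if "n_exons_range" in sim_raw:
            sim_raw["n_exons_range"] = tuple(sim_raw["n_exons_range"])
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        return cls(sim=SimConfig(**sim_raw), thresholds=thr, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["n_exons_range"] = list(d["sim"]["n_exons_range"])
        return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _preflight(config: PipelineConfig) -> None:
    if config.simulate:
        config.sim.validate()
        return
    required = {
        "ref_fasta": config.ref_fasta,
        "ref_gff3": config.ref_gff3,
        "ref_proteins": config.ref_proteins,
        "query_fasta": config.query_fasta,
        "query_gff3": config.query_gff3,
        "query_proteins": config.query_proteins,
    }
    for name, path in required.items():
        if path is None:
            raise FileNotFoundError(f"config is missing required input '{name}'")
        if not os.path.exists(path):
            raise FileNotFoundError(f"{name}: no such file: {path}")
    if config.reads_fastq is None and config.depth_bed is None:
        raise FileNotFoundError("config must provide reads_fastq or depth_bed")
    for name in ("reads_fastq", "depth_bed"):
        path = getattr(config, name)
        if path is not None and not os.path.exists(path):
            raise FileNotFoundError(f"{name}: no such file: {path}")


def run_pipeline(config: PipelineConfig, outdir: str) -> dict:
    """Execute all stages; write outputs and return the manifest dict."""
    _preflight(config)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "tool": f"syntloss {__version__}",
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    paths: dict[str, str] = {}

    def out(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    # -- stage: inputs -------------------------------------------------
    truth = None
    if config.simulate:
        logger.info("[simulate] generating fixture (seed=%d)", config.sim.seed)
        ref, query, truth = simulate_pair(config.sim)
        reads = simulate_reads(
            query.sequences,
            coverage=config.sim.read_coverage,
            read_len=config.sim.read_len,
            error_rate=config.sim.read_error_rate,
            seed=config.sim.seed + 1,
        )
        io.write_fasta(out("ref.fasta"), ref.sequences)
        io.write_gff3(out("ref.gff3"), ref)
        io.write_fasta(out("ref_proteins.fasta"), ref.proteins())
        io.write_fasta(out("query.fasta"), query.sequences)
        io.write_gff3(out("query.gff3"), query)
        io.write_fasta(out("query_proteins.fasta"), query.proteins())
        io.write_fastq(out("reads.fastq"), reads)
        write_truth_table(out("truth.tsv"), truth)
        manifest["stages"]["simulate"] = {
            "n_ref_genes": len(ref.genes),
            "n_query_genes": len(query.genes),
            "n_reads": len(reads),
        }
    else:
        logger.info("[load] reading external inputs")
        ref = io.read_genome(
            config.ref_fasta, config.ref_gff3, config.ref_proteins,
            config.unanchored_prefix,
        )
        query = io.read_genome(
            config.query_fasta, config.query_gff3, config.query_proteins,
            config.unanchored_prefix,
        )
        reads = io.read_fastq(config.reads_fastq) if config.reads_fastq else []
        manifest["stages"]["load"] = {
            "n_ref_genes": len(ref.genes),
            "n_query_genes": len(query.genes),
            "n_reads": len(reads),
        }

    # -- stage: anchors ------------------------------------------------
    logger.info("[anchors] reciprocal best hits")
    anchors = reciprocal_best_hits(
        ref.proteins(),
        query.proteins(),
        min_identity=config.anchor_min_identity,
        min_coverage=config.anchor_min_coverage,
    )
    io.write_tsv(
        out("anchors.tsv"),
        [
            (a.ref_gene_id, a.query_gene_id, f"{a.score:g}", f"{a.identity:.4f}", f"{a.coverage:.4f}")
            for a in anchors
        ],
        ("ref_gene", "query_gene", "score", "identity", "coverage"),
    )
    manifest["stages"]["anchors"] = {"n_anchors": len(anchors)}

    # -- stage: synteny --------------------------------------------------
    logger.info("[synteny] chaining %d anchors", len(anchors))
    ranked = rank_anchors(anchors, ref, query)
    blocks = chain_anchors(
        ranked,
        max_gap=config.max_gap,
        min_block_size=config.min_block_size,
        gap_penalty=config.gap_penalty,
    )
    io.write_tsv(
        out("blocks.tsv"),
        [
            (
                b.block_id, b.ref_scaffold, f"{b.ref_interval[0]}-{b.ref_interval[1]}",
                b.query_scaffold, f"{b.query_interval[0]}-{b.query_interval[1]}",
                b.orientation, b.n_anchors,
            )
            for b in blocks
        ],
        ("block_id", "ref_scaffold", "ref_span", "query_scaffold", "query_span",
         "orientation", "n_anchors"),
    )
    manifest["stages"]["synteny"] = {
        "n_blocks": len(blocks),
        "n_anchors_in_blocks": sum(b.n_anchors for b in blocks),
    }

    # -- stage: depth ------------------------------------------------
    if not config.simulate and config.depth_bed:
        logger.info("[depth] loading precomputed depth track")
        track: DepthTrack = depth_track_from_bed(
            io.read_depth_bed(config.depth_bed), ref.scaffold_lengths
        )
        map_stats = {"source": "depth_bed"}
    else:
        logger.info("[depth] mapping %d reads to the reference", len(reads))
        track, map_stats = map_reads(
            reads,
            ref.anchored_sequences(),
            seed_len=config.seed_len,
            max_mismatch_frac=config.max_mismatch_frac,
        )
    manifest["stages"]["depth"] = map_stats

    # -- stage: losses ----------------------------------------------
    logger.info("[losses] candidate calling and filtering")
    calls = detect_losses(ref, query, blocks, track, config.thresholds)
    rows = []
    lost_rows = []
    for c in sorted(calls, key=lambda c: c.candidate.ref_gene_id):
        cand = c.candidate
        res = c.residues
        rows.append(
            (
                cand.ref_gene_id,
                cand.block_id,
                c.status.value,
                f"{(c.missannotation_hit or c.unanchored_hit).identity:.4f}"
                if (c.missannotation_hit or c.unanchored_hit) else "",
                f"{c.depth.mean_depth:.4f}" if c.depth else "",
                f"{c.depth.body_coverage:.4f}" if c.depth else "",
                res.longest_conserved_run if res else "",
                res.n_premature_stops if res else "",
                res.n_frameshifts if res else "",
            )
        )
        if c.status in (LossStatus.TRUE_LOSS_ABSENT, LossStatus.TRUE_LOSS_PSEUDOGENIZED):
            g = ref.gene(cand.ref_gene_id)
            lost_rows.append(g)
    io.write_tsv(
        out("loss_calls.tsv"),
        rows,
        ("gene", "block", "status", "rescue_identity", "mean_depth",
         "body_coverage", "conserved_run", "n_stops", "n_frameshifts"),
    )
    lost = AnnotatedGenome(sequences={}, genes=lost_rows)
    lost.sequences = {g.scaffold: ref.sequences[g.scaffold] for g in lost_rows}
    io.write_gff3(out("lost_loci.gff3"), lost)
    counts = status_counts(calls)
    manifest["stages"]["losses"] = {
        "n_candidates": len(calls),
        "status_counts": counts,
    }

    # -- summary & manifest ----------------------------------------
    summary = {
        "n_anchors": len(anchors),
        "n_blocks": len(blocks),
        "n_candidates": len(calls),
        "status_counts": counts,
    }
    if truth is not None:
        from .simulate import Event

        planted = {t.gene_id: t.event for t in truth if t.event is not Event.NONE}
        called_lost = {
            c.candidate.ref_gene_id
            for c in calls
            if c.status in (LossStatus.TRUE_LOSS_ABSENT, LossStatus.TRUE_LOSS_PSEUDOGENIZED)
        }
        truly_lost = {
            g for g, e in planted.items()
            if e in (Event.TRUE_DELETION, Event.PSEUDOGENIZATION)
        }
        tp = len(called_lost & truly_lost)
        summary["loss_precision"] = tp / len(called_lost) if called_lost else 1.0
        summary["loss_recall"] = tp / len(truly_lost) if truly_lost else 1.0
    with open(out("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    for name, path in sorted(paths.items()):
        n_records = None
        if path.endswith(".tsv"):
            with open(path) as fh:
                n_records = sum(1 for _ in fh) - 1
        manifest["outputs"][name] = {"sha256": _sha256(path), "n_records": n_records}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
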