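"""Gene-loss calling in synteny blocks with four false-positive filters.

A reference gene that sits inside a synteny block but has no protein
homolog among the annotated query genes of its flanking-anchor window is
a *loss candidate*.  Candidates then pass through four filters, in the
fixed order below; the first rescue wins:

1. **unanchored rescue** - a six-frame translated hit on an unanchored
   scaffold at identity >= 0.80 over >= 0.80 of the reference protein
   means the gene is only "lost" because its scaffold is unplaced
   (misassembly artifact);
2. **missannotation rescue** - the same translated search against the
   syntenic window DNA itself; a strong hit means the gene is present
   but was missed by annotation;
3. **read-depth validation** - query short reads are mapped to the
   reference genome; a candidate whose gene body shows mean depth >= 1x
   or body coverage >= 5% has read support and is rescued;
4. **residue inspection** - survivors are aligned frame-aware against
   the window to report premature stops, frameshifts and the longest
   run of conserved residues, splitting true losses into pseudogenized
   (conserved residues still recognizable) versus absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.Seq import Seq

from .genome import AnnotatedGenome, GeneModel
from .orthology import AlignmentResult, local_align, make_aligner
from .synteny import SyntenyBlock, flanking_window

logger = logging.getLogger(__name__)


class LossStatus(str, Enum):
    TRUE_LOSS_ABSENT = "TRUE_LOSS_ABSENT"
    TRUE_LOSS_PSEUDOGENIZED = "TRUE_LOSS_PSEUDOGENIZED"
    RESCUED_UNANCHORED = "RESCUED_UNANCHORED"
    RESCUED_MISSANNOTATION = "RESCUED_MISSANNOTATION"
    RESCUED_READ_EVIDENCE = "RESCUED_READ_EVIDENCE"


@dataclass(frozen=True)
class FilterThresholds:
    """Decision thresholds for candidate calling and the rescue filters.

    The rescue identity/coverage floor (0.80/0.80) and the depth criteria
    (mean depth < 1x AND gene-body coverage < 5%, both strict) are the
    published decision rules; the candidate-stage floor is a permissive
    screen so that any plausible in-window homolog suppresses a candidate.
    """

    window_anchors: int = 5
    window_margin: int = 2000
    candidate_min_identity: float = 0.50
    candidate_min_coverage: float = 0.50
    rescue_min_identity: float = 0.80
    rescue_min_coverage: float = 0.80
    max_mean_depth: float = 1.0
    max_body_coverage: float = 0.05
    min_conserved_run: int = 10

    def validate(self) -> None:
        fracs = (
            self.candidate_min_identity,
            self.candidate_min_coverage,
            self.rescue_min_identity,
            self.rescue_min_coverage,
            self.max_body_coverage,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("threshold fractions must lie in [0, 1]")
        if self.rescue_min_identity < self.candidate_min_identity:
            raise ValueError("rescue identity floor below candidate floor")
        if self.rescue_min_coverage < self.candidate_min_coverage:
            raise ValueError("rescue coverage floor below candidate floor")


@dataclass
class LossCandidate:
    ref_gene_id: str
    block_id: str
    window: tuple[str, int, int]  # query scaffold, start, end
    best_window_hit: AlignmentResult | None = None


@dataclass(frozen=True)
class DepthSummary:
    mean_depth: float
    body_coverage: float


@dataclass(frozen=True)
class SixFrameHit:
    """Best local alignment of a protein against one frame of a DNA window."""

    score: float
    identity: float
    coverage_protein: float
    frame: int
    strand: str
    protein_interval: tuple[int, int]
    dna_interval: tuple[int, int]  # on the forward strand of the window
    n_matches: int
    aligned_columns: int
    n_stops_aligned: int
    longest_match_run: int


@dataclass(frozen=True)
class ResidueReport:
    identity: float
    longest_conserved_run: int
    n_premature_stops: int
    n_frameshifts: int
    n_hits: int


@dataclass
class LossCall:
    candidate: LossCandidate
    status: LossStatus
    unanchored_hit: SixFrameHit | None = None
    unanchored_scaffold: str | None = None
    missannotation_hit: SixFrameHit | None = None
    depth: DepthSummary | None = None
    residues: ResidueReport | None = None


# ------------------------------------------------------------- six-frame search

def _frame_translations(dna: str):
    """Yield (strand, frame, protein) for all six frames."""
    rc = str(Seq(dna).reverse_complement())
    for strand, seq in (("+", dna), ("-", rc)):
        for frame in range(3):
            usable = (len(seq) - frame) // 3 * 3
            if usable < 3:
                continue
            yield strand, frame, str(Seq(seq[frame : frame + usable]).translate())


def _hit_from_alignment(
    protein: str, trans: str, res: AlignmentResult, strand: str, frame: int, dna_len: int,
    aligned_pairs: list[tuple[int, int, int]],
) -> SixFrameHit:
    # aligned_pairs: (protein_pos, trans_pos, is_match) per gapless column
    n_stops = sum(1 for _, t, _ in aligned_pairs if trans[t] == "*")
    longest = run = 0
    prev: tuple[int, int] | None = None
    for p, t, m in aligned_pairs:
        if m and prev == (p - 1, t - 1):
            run += 1
        elif m:
            run = 1
        else:
            run = 0
        longest = max(longest, run)
        prev = (p, t)
    ts, te = res.target_interval
    if strand == "+":
        dna_iv = (frame + 3 * ts, frame + 3 * te)
    else:
        dna_iv = (dna_len - (frame + 3 * te), dna_len - (frame + 3 * ts))
    return SixFrameHit(
        score=res.score,
        identity=res.identity,
        coverage_protein=res.coverage_query,
        frame=frame,
        strand=strand,
        protein_interval=res.query_interval,
        dna_interval=dna_iv,
        n_matches=res.n_matches,
        aligned_columns=res.aligned_columns,
        n_stops_aligned=n_stops,
        longest_match_run=longest,
    )


def sixframe_hits(
    protein: str,
    dna: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_score: float = 40.0,
) -> list[SixFrameHit]:
    """Best local hit of ``protein`` in each of the six frames of ``dna``.

    Intron-length gaps are bridged inside a single affine-gap alignment,
    so one hit can span several exons when they share a reading frame.
    """
    if len(dna) < 3:
        raise ValueError("window shorter than 3 bp")
    if not protein:
        raise ValueError("empty protein")
    aligner = make_aligner(None, gap_open, gap_extend)
    hits: list[SixFrameHit] = []
    for strand, frame, trans in _frame_translations(dna):
        alignments = aligner.align(protein, trans)
        if len(alignments) == 0 or alignments.score < min_score:
            continue
        best = alignments[0]
        p_blocks, t_blocks = best.aligned
        pairs: list[tuple[int, int, int]] = []
        for (ps, pe), (ts, te) in zip(p_blocks, t_blocks):
            for off in range(pe - ps):
                p, t = ps + off, ts + off
                pairs.append((p, t, int(protein[p] == trans[t])))
        matches = sum(m for _, _, m in pairs)
        res = AlignmentResult(
            score=float(best.score),
            identity=matches / len(pairs) if pairs else 0.0,
            coverage_query=(p_blocks[-1][1] - p_blocks[0][0]) / len(protein),
            coverage_target=(t_blocks[-1][1] - t_blocks[0][0]) / len(trans),
            query_interval=(int(p_blocks[0][0]), int(p_blocks[-1][1])),
            target_interval=(int(t_blocks[0][0]), int(t_blocks[-1][1])),
            n_matches=matches,
            aligned_columns=len(pairs),
        )
        hits.append(
            _hit_from_alignment(protein, trans, res, strand, frame, len(dna), pairs)
        )
    hits.sort(key=lambda h: -h.score)
    return hits


def sixframe_best(protein: str, dna: str, **kw) -> SixFrameHit | None:
    hits = sixframe_hits(protein, dna, **kw)
    return hits[0] if hits else None


# ------------------------------------------------------------- candidate calling

def call_candidates(
    blocks: list[SyntenyBlock],
    ref_genome: AnnotatedGenome,
    query_genome: AnnotatedGenome,
    thresholds: FilterThresholds | None = None,
) -> list[LossCandidate]:
    """Reference genes inside blocks lacking any in-window annotated homolog."""
    thr = thresholds or FilterThresholds()
    thr.validate()
    aligner = make_aligner()
    anchor_members = {a.ref_gene for b in blocks for a in b.anchors}
    scaffold_lengths = query_genome.scaffold_lengths
    candidates: list[LossCandidate] = []
    seen: set[str] = set()
    for block in blocks:
        lo, hi = block.ref_rank_span
        scaf_genes = ref_genome.genes_on(block.ref_scaffold)
        for rank in range(lo + 1, hi):
            gene = scaf_genes[rank]
            if gene.gene_id in anchor_members or gene.gene_id in seen:
                continue
            if gene.protein is None:
                logger.warning("gene %s has no protein translation; skipped", gene.gene_id)
                continue
            window = flanking_window(
                block,
                rank,
                w=thr.window_anchors,
                margin=thr.window_margin,
                scaffold_length=scaffold_lengths.get(block.query_scaffold),
            )
            q_scaf, w_start, w_end = window
            best: AlignmentResult | None = None
            found = False
            for qg in query_genome.genes_on(q_scaf):
                if not qg.overlaps(w_start, w_end) or not qg.protein:
                    continue
                res = local_align(gene.protein, qg.protein, aligner=aligner)
                if best is None or res.score > best.score:
                    best = res
                if (
                    res.identity >= thr.candidate_min_identity
                    and res.min_coverage >= thr.candidate_min_coverage
                ):
                    found = True
                    break
            if not found:
                seen.add(gene.gene_id)
                candidates.append(
                    LossCandidate(gene.gene_id, block.block_id, window, best)
                )
    return candidates


# ------------------------------------------------------------- rescue filters

def rescue_unanchored(
    candidate: LossCandidate,
    ref_protein: str,
    unanchored_sequences: dict[str, str],
    thresholds: FilterThresholds,
) -> tuple[str, SixFrameHit] | None:
    """Filter (1): search the reference protein on unanchored scaffolds."""
    best: tuple[str, SixFrameHit] | None = None
    for name in sorted(unanchored_sequences):
        seq = unanchored_sequences[name]
        if len(seq) < 3:
            continue
        hit = sixframe_best(ref_protein, seq)
        if hit is None:
            continue
        if (
            hit.identity >= thresholds.rescue_min_identity
            and hit.coverage_protein >= thresholds.rescue_min_coverage
        ):
            if best is None or hit.score > best[1].score:
                best = (name, hit)
    return best


def rescue_missannotation(
    candidate: LossCandidate,
    ref_protein: str,
    query_sequences: dict[str, str],
    thresholds: FilterThresholds,
) -> SixFrameHit | None:
    """Filter (2): translated search of the syntenic window DNA itself."""
    scaf, start, end = candidate.window
    seq = query_sequences.get(scaf, "")
    window_dna = seq[max(0, start) : min(len(seq), end)]
    if len(window_dna) < 3:
        logger.warning("window for %s off scaffold end; clipped to nothing", candidate.ref_gene_id)
        return None
    hit = sixframe_best(ref_protein, window_dna)
    if hit is None:
        return None
    if (
        hit.identity >= thresholds.rescue_min_identity
        and hit.coverage_protein >= thresholds.rescue_min_coverage
    ):
        return hit
    return None


# ------------------------------------------------------------- read mapping

DepthTrack = dict[str, np.ndarray]

MATCH_SCORE = 1
MISMATCH_SCORE = -3


def _best_matching_segment(read: str, segment: str) -> tuple[int, int]:
    """Maximal-scoring contiguous interval of an ungapped read placement
    (+1 match, -3 mismatch); the soft-clip stand-in."""
    best_lo = best_hi = lo = 0
    best = score = 0
    for i, (a, b) in enumerate(zip(read, segment)):
        score += MATCH_SCORE if a == b else MISMATCH_SCORE
        if score <= 0:
            score = 0
            lo = i + 1
        elif score > best:
            best = score
            best_lo, best_hi = lo, i + 1
    return best_lo, best_hi


def map_reads(
    reads: list[tuple[str, str]],
    genome_sequences: dict[str, str],
    seed_len: int = 31,
    max_mismatch_frac: float = 0.10,
) -> tuple[DepthTrack, dict[str, int]]:
    """Minimal pseudo-mapper producing a per-base depth track.

    Exact-match seeding on the first ``seed_len`` bases (both strands),
    ungapped full-length extension, acceptance iff the mismatch fraction
    is within ``max_mismatch_frac``; reads with multiple equally good
    placements are discarded.  Depth is deposited over the read's
    best-matching contiguous segment (+1 match / -3 mismatch maximal
    subarray) rather than its full span, emulating the soft-clipping of
    a local mapper: a read anchored in conserved flanking sequence does
    not drag its diverged tail across a locus boundary.  A stand-in for
    a production short-read mapper, adequate because the loss criterion
    only needs approximate gene-body depth.
    """
    if not genome_sequences:
        raise ValueError("empty genome")
    comp = str.maketrans("ACGTN", "TGCAN")
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome_sequences.items():
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i : i + seed_len], []).append((name, i))
    depth: DepthTrack = {
        name: np.zeros(len(seq), dtype=np.int32) for name, seq in genome_sequences.items()
    }
    stats = {"mapped": 0, "unmapped": 0, "ambiguous": 0}
    for _, read in reads:
        n = len(read)
        max_mm = int(max_mismatch_frac * n)
        placements: list[tuple[int, str, int, str]] = []
        for oriented in (read, read.translate(comp)[::-1]):
            if len(oriented) < seed_len:
                continue
            for name, pos in index.get(oriented[:seed_len], ()):
                ref = genome_sequences[name]
                if pos + n > len(ref):
                    continue
                segment = ref[pos : pos + n]
                mm = sum(1 for a, b in zip(oriented, segment) if a != b)
                if mm <= max_mm:
                    placements.append((mm, name, pos, oriented))
        if not placements:
            stats["unmapped"] += 1
            continue
        best_mm = min(p[0] for p in placements)
        best = {(name, pos) for mm, name, pos, _ in placements if mm == best_mm}
        if len(best) > 1:
            stats["ambiguous"] += 1
            continue
        mm, name, pos, oriented = next(
            p for p in placements if (p[1], p[2]) in best and p[0] == best_mm
        )
        if mm == 0:
            lo, hi = 0, n
        else:
            segment = genome_sequences[name][pos : pos + n]
            lo, hi = _best_matching_segment(oriented, segment)
        depth[name][pos + lo : pos + hi] += 1
        stats["mapped"] += 1
    if stats["unmapped"] or stats["ambiguous"]:
        logger.info(
            "map_reads: %(mapped)d mapped, %(unmapped)d unmapped, %(ambiguous)d ambiguous",
            stats,
        )
    return depth, stats


def depth_track_from_bed(
    bed: dict[str, list[tuple[int, int, float]]], scaffold_lengths: dict[str, int]
) -> DepthTrack:
    track = {
        name: np.zeros(length, dtype=np.float64)
        for name, length in scaffold_lengths.items()
    }
    for scaf, intervals in bed.items():
        if scaf not in track:
            continue
        arr = track[scaf]
        for start, end, d in intervals:
            arr[start:end] = d
    return track


def depth_validate(
    gene: GeneModel, depth_track: DepthTrack, thresholds: FilterThresholds
) -> tuple[DepthSummary, bool]:
    """Filter (3): does the read depth over the gene body support loss?

    Returns the summary and ``True`` when BOTH criteria hold (mean depth
    below the ceiling AND body coverage below the ceiling, strictly) -
    i.e. the reads corroborate absence.
    """
    if gene.scaffold not in depth_track:
        raise ValueError(f"depth track does not cover scaffold {gene.scaffold}")
    if gene.span <= 0:
        raise ValueError(f"gene {gene.gene_id} has zero-length body")
    body = depth_track[gene.scaffold][gene.start : gene.end]
    mean_depth = float(body.sum()) / gene.span
    body_coverage = float((body > 0).sum()) / gene.span
    supports_loss = (
        mean_depth < thresholds.max_mean_depth
        and body_coverage < thresholds.max_body_coverage
    )
    return DepthSummary(mean_depth, body_coverage), supports_loss


# ------------------------------------------------------------- residue inspection

def inspect_residues(
    ref_protein: str,
    window_dna: str,
    min_hit_score: float = 40.0,
    max_protein_overlap: int = 30,
) -> ResidueReport:
    """Filter (4): frame-aware inspection of the presumed lost locus.

    The best local hit per frame is chained greedily (hits may overlap by
    at most ``max_protein_overlap`` residues on the protein - local
    alignments routinely overrun a frameshift junction by a stretch of
    chance matches); frame
    changes between chained hits count as frameshifts, stop codons
    aligned against reference residues as premature stops, and the
    longest run of consecutive identical residues measures how
    recognizable the conserved residues still are.
    """
    hits = sixframe_hits(ref_protein, window_dna, min_score=min_hit_score)
    if not hits:
        return ResidueReport(0.0, 0, 0, 0, 0)
    chained: list[SixFrameHit] = []
    for h in hits:  # already sorted by descending score
        ok = True
        for c in chained:
            lo = max(h.protein_interval[0], c.protein_interval[0])
            hi = min(h.protein_interval[1], c.protein_interval[1])
            if hi - lo > max_protein_overlap:
                ok = False
                break
        if ok:
            chained.append(h)
    chained.sort(key=lambda h: h.protein_interval[0])
    matches = sum(h.n_matches for h in chained)
    columns = sum(h.aligned_columns for h in chained)
    stops = sum(h.n_stops_aligned for h in chained)
    frameshifts = sum(
        1
        for a, b in zip(chained, chained[1:])
        if (a.strand, a.frame) != (b.strand, b.frame)
    )
    return ResidueReport(
        identity=matches / columns if columns else 0.0,
        longest_conserved_run=max(h.longest_match_run for h in chained),
        n_premature_stops=stops,
        n_frameshifts=frameshifts,
        n_hits=len(chained),
    )


# ------------------------------------------------------------- classification

def classify(
    candidate: LossCandidate,
    unanchored_evidence: tuple[str, SixFrameHit] | None,
    missannotation_evidence: SixFrameHit | None,
    depth_summary: DepthSummary | None,
    depth_supports_loss: bool | None,
    residue_report: ResidueReport | None,
    min_conserved_run: int = 10,
) -> LossCall:
    """Assign the final status with filter precedence (1) > (2) > (3) > (4)."""
    if unanchored_evidence is not None:
        scaf, hit = unanchored_evidence
        return LossCall(
            candidate,
            LossStatus.RESCUED_UNANCHORED,
            unanchored_hit=hit,
            unanchored_scaffold=scaf,
        )
    if missannotation_evidence is not None:
        return LossCall(
            candidate,
            LossStatus.RESCUED_MISSANNOTATION,
            missannotation_hit=missannotation_evidence,
        )
    if depth_supports_loss is None or depth_summary is None:
        raise ValueError("missing depth evidence for unrescued candidate")
    if not depth_supports_loss:
        return LossCall(candidate, LossStatus.RESCUED_READ_EVIDENCE, depth=depth_summary)
    if residue_report is None:
        raise ValueError("missing residue report for unrescued candidate")
    status = (
        LossStatus.TRUE_LOSS_PSEUDOGENIZED
        if residue_report.longest_conserved_run >= min_conserved_run
        else LossStatus.TRUE_LOSS_ABSENT
    )
    return LossCall(candidate, status, depth=depth_summary, residues=residue_report)


# ------------------------------------------------------------- orchestration

def detect_losses(
    ref_genome: AnnotatedGenome,
    query_genome: AnnotatedGenome,
    blocks: list[SyntenyBlock],
    depth_track: DepthTrack,
    thresholds: FilterThresholds | None = None,
) -> list[LossCall]:
    """Run candidate calling and all four filters; returns one call per candidate."""
    thr = thresholds or FilterThresholds()
    thr.validate()
    candidates = call_candidates(blocks, ref_genome, query_genome, thr)
    unanchored = query_genome.unanchored_sequences()
    calls: list[LossCall] = []
    for cand in candidates:
        protein = ref_genome.gene(cand.ref_gene_id).protein
        assert protein is not None
        ev1 = rescue_unanchored(cand, protein, unanchored, thr)
        if ev1 is not None:
            calls.append(classify(cand, ev1, None, None, None, None, thr.min_conserved_run))
            continue
        ev2 = rescue_missannotation(cand, protein, query_genome.sequences, thr)
        if ev2 is not None:
            calls.append(classify(cand, None, ev2, None, None, None, thr.min_conserved_run))
            continue
        gene = ref_genome.gene(cand.ref_gene_id)
        summary, supports = depth_validate(gene, depth_track, thr)
        if not supports:
            calls.append(
                classify(cand, None, None, summary, supports, None, thr.min_conserved_run)
            )
            continue
        scaf, start, end = cand.window
        seq = query_genome.sequences.get(scaf, "")
        window_dna = seq[max(0, start) : min(len(seq), end)]
        report = inspect_residues(protein, window_dna)
        calls.append(
            classify(cand, None, None, summary, supports, report, thr.min_conserved_run)
        )
    return calls


def status_counts(calls: list[LossCall]) -> dict[str, int]:
    counts = {s.value: 0 for s in LossStatus}
    for c in calls:
        counts[c.status.value] += 1
    return counts
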