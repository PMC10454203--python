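"""Protein local alignment and reciprocal-best-hit (RBH) ortholog anchoring.

RBH is the standard 1:1 orthology proxy: a pair is emitted only when each
protein is the other's unique highest-scoring match and the alignment
clears identity/coverage floors.  Ambiguous best hits (score ties) drop
the gene rather than breaking the tie arbitrarily, because an ambiguous
ortholog must not seed synteny.

Smith-Waterman alignment is delegated to Biopython's ``PairwiseAligner``
(affine gaps; the cost of a gap of length L is ``gap_open +
(L - 1) * gap_extend``).  Identity is matches divided by gapless aligned
columns; coverage is the aligned span divided by sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Align import PairwiseAligner, substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    """Summary of one local alignment."""

    score: float
    identity: float
    coverage_query: float
    coverage_target: float
    query_interval: tuple[int, int]   # 0-based half-open on the first sequence
    target_interval: tuple[int, int]  # 0-based half-open on the second sequence
    n_matches: int
    aligned_columns: int

    @property
    def min_coverage(self) -> float:
        return min(self.coverage_query, self.coverage_target)


@dataclass(frozen=True)
class AnchorPair:
    ref_gene_id: str
    query_gene_id: str
    score: float
    identity: float
    coverage: float
    reciprocal: bool = True


def make_aligner(
    matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0
) -> PairwiseAligner:
    if not gap_open >= gap_extend > 0:
        raise ValueError("require gap_open >= gap_extend > 0")
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = BLOSUM62 if matrix is None else matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def local_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    aligner: PairwiseAligner | None = None,
) -> AlignmentResult:
    """Smith-Waterman local alignment of two protein sequences.

    Passing a prebuilt ``aligner`` skips construction in hot loops.
    """
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(0.0, 0.0, 0.0, 0.0, (0, 0), (0, 0), 0, 0)
    best = alignments[0]
    a_blocks, b_blocks = best.aligned
    matches = 0
    columns = 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        columns += ae - as_
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    qa, qe = int(a_blocks[0][0]), int(a_blocks[-1][1])
    ta, te = int(b_blocks[0][0]), int(b_blocks[-1][1])
    return AlignmentResult(
        score=float(best.score),
        identity=matches / columns if columns else 0.0,
        coverage_query=(qe - qa) / len(a),
        coverage_target=(te - ta) / len(b),
        query_interval=(qa, qe),
        target_interval=(ta, te),
        n_matches=matches,
        aligned_columns=columns,
    )


def _as_dict(proteins) -> dict[str, str]:
    if isinstance(proteins, Mapping):
        return dict(proteins)
    out: dict[str, str] = {}
    for gid, seq in proteins:
        if gid in out:
            raise InputError(f"duplicate protein id: {gid}")
        out[gid] = seq
    return out


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def reciprocal_best_hits(
    ref_proteins,
    query_proteins,
    min_identity: float = 0.3,
    min_coverage: float = 0.5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    prefilter_k: int | None = 5,
    prefilter_min_shared: int = 2,
) -> list[AnchorPair]:
    """One-to-one ortholog pairs by reciprocal unique best hit.

    A shared-k-mer prefilter (pairs must share at least
    ``prefilter_min_shared`` length-``prefilter_k`` peptides) limits the
    all-vs-all alignment to plausible homologs, the usual seeding idea;
    pass ``prefilter_k=None`` to align every pair.
    """
    ref = _as_dict(ref_proteins)
    query = _as_dict(query_proteins)
    if not ref:
        raise InputError("empty reference protein set")
    if not query:
        return []
    aligner = make_aligner(None, gap_open, gap_extend)

    if prefilter_k is not None:
        q_kmers = {qid: _kmer_set(seq, prefilter_k) for qid, seq in query.items()}
    results: dict[tuple[str, str], AlignmentResult] = {}
    for rid, rseq in ref.items():
        if prefilter_k is not None:
            r_kmers = _kmer_set(rseq, prefilter_k)
            candidates = [
                qid
                for qid in query
                if len(r_kmers & q_kmers[qid]) >= prefilter_min_shared
            ]
        else:
            candidates = list(query)
        for qid in candidates:
            results[(rid, qid)] = local_align(rseq, query[qid], aligner=aligner)

    def best_unique(keys_scores: dict[str, float]) -> str | None:
        if not keys_scores:
            return None
        top = max(keys_scores.values())
        winners = [k for k, s in keys_scores.items() if s == top]
        return winners[0] if len(winners) == 1 else None

    by_ref: dict[str, dict[str, float]] = {}
    by_query: dict[str, dict[str, float]] = {}
    for (rid, qid), res in results.items():
        if res.score <= 0:
            continue
        by_ref.setdefault(rid, {})[qid] = res.score
        by_query.setdefault(qid, {})[rid] = res.score

    anchors: list[AnchorPair] = []
    for rid in sorted(by_ref):
        qid = best_unique(by_ref[rid])
        if qid is None:
            continue
        if best_unique(by_query.get(qid, {})) != rid:
            continue
        res = results[(rid, qid)]
        if res.identity < min_identity or res.min_coverage < min_coverage:
            continue
        anchors.append(
            AnchorPair(
                ref_gene_id=rid,
                query_gene_id=qid,
                score=res.score,
                identity=res.identity,
                coverage=res.min_coverage,
            )
        )
    return anchors
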