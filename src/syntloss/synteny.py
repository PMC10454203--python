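"""Collinear chaining of ortholog anchors into synteny blocks.

Anchors carry per-scaffold gene ranks on both genomes.  Within each
(reference scaffold, query scaffold) pair the highest-scoring collinear
chain is found by dynamic programming (separately for the two
orientations), its anchors are removed, and the search repeats - greedy
iterated best-chain extraction.  Chain score is the sum of anchor scores
minus a penalty per skipped gene rank on either genome; chains shorter
than ``min_block_size`` anchors are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import AnnotatedGenome
from .orthology import AnchorPair


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class RankedAnchor:
    """An anchor pair located by scaffold, gene rank and bp interval."""

    ref_gene: str
    query_gene: str
    ref_scaffold: str
    ref_rank: int
    ref_start: int
    ref_end: int
    query_scaffold: str
    query_rank: int
    query_start: int
    query_end: int
    score: float


@dataclass
class SyntenyBlock:
    block_id: str
    orientation: str  # '+' or '-'
    anchors: list[RankedAnchor]
    score: float

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def ref_scaffold(self) -> str:
        return self.anchors[0].ref_scaffold

    @property
    def query_scaffold(self) -> str:
        return self.anchors[0].query_scaffold

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (
            min(a.ref_start for a in self.anchors),
            max(a.ref_end for a in self.anchors),
        )

    @property
    def query_interval(self) -> tuple[int, int]:
        return (
            min(a.query_start for a in self.anchors),
            max(a.query_end for a in self.anchors),
        )

    @property
    def ref_rank_span(self) -> tuple[int, int]:
        return self.anchors[0].ref_rank, self.anchors[-1].ref_rank


def rank_anchors(
    anchors: list[AnchorPair],
    ref_genome: AnnotatedGenome,
    query_genome: AnnotatedGenome,
) -> list[RankedAnchor]:
    """Attach scaffold/rank/coordinate context to RBH anchor pairs."""
    out = []
    for a in anchors:
        r_scaf, r_rank = ref_genome.rank_of(a.ref_gene_id)
        q_scaf, q_rank = query_genome.rank_of(a.query_gene_id)
        rg = ref_genome.gene(a.ref_gene_id)
        qg = query_genome.gene(a.query_gene_id)
        out.append(
            RankedAnchor(
                ref_gene=a.ref_gene_id,
                query_gene=a.query_gene_id,
                ref_scaffold=r_scaf,
                ref_rank=r_rank,
                ref_start=rg.start,
                ref_end=rg.end,
                query_scaffold=q_scaf,
                query_rank=q_rank,
                query_start=qg.start,
                query_end=qg.end,
                score=a.score,
            )
        )
    return out


def _best_chain(
    anchors: list[RankedAnchor],
    orientation: str,
    max_gap: int,
    gap_penalty: float,
) -> tuple[list[int], float]:
    """DP over anchors sorted by ref rank; returns (indices, score).

    Anchor j may extend a chain ending at i iff both rank gaps (skipped
    genes between consecutive anchors) are within ``max_gap`` and the
    query ranks run in the direction required by ``orientation``.
    """
    order = sorted(range(len(anchors)), key=lambda i: anchors[i].ref_rank)
    dp = [anchors[i].score for i in order]
    back: list[int | None] = [None] * len(order)
    for j_pos, j in enumerate(order):
        aj = anchors[j]
        for i_pos in range(j_pos):
            i = order[i_pos]
            ai = anchors[i]
            ref_gap = aj.ref_rank - ai.ref_rank - 1
            if ref_gap < 0 or ref_gap > max_gap:
                continue
            if orientation == "+":
                q_gap = aj.query_rank - ai.query_rank - 1
            else:
                q_gap = ai.query_rank - aj.query_rank - 1
            if q_gap < 0 or q_gap > max_gap:
                continue
            cand = dp[i_pos] + aj.score - gap_penalty * (ref_gap + q_gap)
            if cand > dp[j_pos]:
                dp[j_pos] = cand
                back[j_pos] = i_pos
    if not dp:
        return [], 0.0
    best_pos = max(range(len(dp)), key=lambda p: (dp[p], -anchors[order[p]].ref_rank))
    chain_pos: list[int] = []
    p: int | None = best_pos
    while p is not None:
        chain_pos.append(p)
        p = back[p]
    chain_pos.reverse()
    return [order[p] for p in chain_pos], dp[best_pos]


def chain_anchors(
    anchors: list[RankedAnchor],
    max_gap: int = 10,
    min_block_size: int = 4,
    gap_penalty: float = 1.0,
) -> list[SyntenyBlock]:
    """Greedy iterated extraction of maximum-score collinear chains."""
    groups: dict[tuple[str, str], list[RankedAnchor]] = {}
    seen_ranks: dict[tuple[str, int], str] = {}
    for a in anchors:
        key = (a.ref_scaffold, a.ref_rank)
        if key in seen_ranks:
            raise InputError(
                f"duplicate ref rank {a.ref_rank} on {a.ref_scaffold} "
                f"({seen_ranks[key]} vs {a.ref_gene})"
            )
        seen_ranks[key] = a.ref_gene
        groups.setdefault((a.ref_scaffold, a.query_scaffold), []).append(a)

    blocks: list[SyntenyBlock] = []
    for key in sorted(groups):
        remaining = list(groups[key])
        while remaining:
            best: tuple[list[int], float, str] | None = None
            for orientation in ("+", "-"):
                idx, score = _best_chain(remaining, orientation, max_gap, gap_penalty)
                if idx and (
                    best is None
                    or score > best[1]
                    or (
                        score == best[1]
                        and remaining[idx[0]].ref_rank < remaining[best[0][0]].ref_rank
                    )
                ):
                    best = (idx, score, orientation)
            if best is None:
                break
            idx, score, orientation = best
            chain = [remaining[i] for i in idx]
            if len(chain) >= min_block_size:
                blocks.append(
                    SyntenyBlock(
                        block_id="",
                        orientation=orientation,
                        anchors=sorted(chain, key=lambda a: a.ref_rank),
                        score=score,
                    )
                )
            taken = set(idx)
            remaining = [a for i, a in enumerate(remaining) if i not in taken]

    blocks.sort(key=lambda b: (b.ref_scaffold, b.ref_interval[0], b.query_scaffold))
    for i, b in enumerate(blocks, start=1):
        b.block_id = f"blk_{i:04d}"
    return blocks


def flanking_window(
    block: SyntenyBlock,
    ref_gene_rank: int,
    w: int = 5,
    margin: int = 2000,
    scaffold_length: int | None = None,
) -> tuple[str, int, int]:
    """Query interval spanned by up to ``w`` nearest anchors on each side.

    ``ref_gene_rank`` must lie within the block's ref rank span.  The
    union of the selected anchors' query gene intervals is extended by
    ``margin`` bp and clipped to the scaffold.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    lo, hi = block.ref_rank_span
    if not lo <= ref_gene_rank <= hi:
        raise ValueError(
            f"rank {ref_gene_rank} outside block ref rank span [{lo}, {hi}]"
        )
    left = [a for a in block.anchors if a.ref_rank < ref_gene_rank][-w:]
    right = [a for a in block.anchors if a.ref_rank > ref_gene_rank][:w]
    chosen = left + right
    if not chosen:
        raise ValueError("no flanking anchors around the requested rank")
    start = min(a.query_start for a in chosen) - margin
    end = max(a.query_end for a in chosen) + margin
    start = max(0, start)
    if scaffold_length is not None:
        end = min(end, scaffold_length)
    return block.query_scaffold, start, end
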