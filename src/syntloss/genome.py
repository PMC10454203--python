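"""In-memory containers for annotated genomes.

Coordinates are 0-based half-open throughout the package; GFF3 files use
1-based inclusive coordinates only at the read/write boundary (see
:mod:`syntloss.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_UNANCHORED_PREFIX = "scaffold_un_"


@dataclass
class GeneModel:
    """A protein-coding gene with exon structure on one scaffold.

    ``exons`` are (start, end) pairs in genomic coordinates, ordered 5'->3'
    on the forward strand.  ``protein`` is the translated CDS without a
    trailing stop symbol, or ``None`` when no translation is available.
    """

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class AnnotatedGenome:
    """Scaffold sequences plus an ordered gene annotation.

    ``sequences`` maps scaffold id to its nucleotide string; ``genes`` is
    the full gene list.  Gene *rank* means the 0-based index of a gene in
    the coordinate-sorted gene list of its scaffold; synteny chaining and
    window arithmetic operate on ranks.
    """

    sequences: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)
    unanchored_prefix: str = DEFAULT_UNANCHORED_PREFIX

    def __post_init__(self) -> None:
        self._by_scaffold: dict[str, list[GeneModel]] | None = None
        self._ranks: dict[str, tuple[str, int]] | None = None

    # -- indexing -----------------------------------------------------

    def _ensure_index(self) -> None:
        if self._by_scaffold is not None:
            return
        by_scaf: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_scaf.setdefault(g.scaffold, []).append(g)
        for lst in by_scaf.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._by_scaffold = by_scaf
        self._ranks = {
            g.gene_id: (scaf, i)
            for scaf, lst in by_scaf.items()
            for i, g in enumerate(lst)
        }

    def genes_on(self, scaffold: str) -> list[GeneModel]:
        self._ensure_index()
        assert self._by_scaffold is not None
        return self._by_scaffold.get(scaffold, [])

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """Return (scaffold, rank) for a gene id."""
        self._ensure_index()
        assert self._ranks is not None
        return self._ranks[gene_id]

    def gene(self, gene_id: str) -> GeneModel:
        self._ensure_index()
        assert self._ranks is not None
        scaf, rank = self._ranks[gene_id]
        return self.genes_on(scaf)[rank]

    # -- convenience --------------------------------------------------

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.protein}

    def is_unanchored(self, scaffold: str) -> bool:
        return scaffold.startswith(self.unanchored_prefix)

    def unanchored_sequences(self) -> dict[str, str]:
        return {
            name: seq
            for name, seq in self.sequences.items()
            if self.is_unanchored(name)
        }

    def anchored_sequences(self) -> dict[str, str]:
        return {
            name: seq
            for name, seq in self.sequences.items()
            if not self.is_unanchored(name)
        }
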