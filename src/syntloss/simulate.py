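"""Synthetic annotated genome pairs with planted gene-loss events.

The simulator produces a *reference* genome (the role of the well-assembled
close relative) and a diverged *query* genome (the role of the newly
sequenced species), sharing collinear gene blocks, together with a truth
table recording the planted fate of every reference gene:

``NONE``
    ortholog retained, diverged at the background rate;
``TRUE_DELETION``
    the gene's full genomic span is absent from the query;
``PSEUDOGENIZATION``
    the locus is retained but heavily diverged, carries at least one
    premature stop codon and one frameshift, keeps a synonymously recoded
    block of codons whose protein residues match the reference (the
    "recognizable conserved residues"), and is dropped from the query
    annotation;
``ANNOTATION_DROPOUT``
    the locus is near-intact (background divergence only) but missing
    from the query annotation;
``MOVED_UNANCHORED``
    the gene is removed from its syntenic position and an intact,
    unannotated copy is appended on an unanchored scaffold.

Both species descend from one simulated ancestor, each branch receiving
half the configured background divergence.  Sequence composition is
i.i.d. uniform: the loss filters respond to homology and coverage
structure, not base composition, so no attempt is made at realism there.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .genome import DEFAULT_UNANCHORED_PREFIX, AnnotatedGenome, GeneModel

NUCLEOTIDES = "ACGT"
_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(standard_dna_table.forward_table)  # 61 codons
_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _lst in _SYNONYMS.values():
    _lst.sort()

INTRON_LENGTH = 81  # multiple of 3: all exons of a locus share a reading frame
CONSERVED_WINDOW_CODONS = 30
MIN_CDS_CODONS = 120
EDGE_BUFFER = 5       # planted events stay this many genes from scaffold ends
EVENT_MIN_SPACING = 3  # minimum rank distance between planted events
INVERSION_SEGMENT_GENES = 8


class Event(str, Enum):
    NONE = "NONE"
    TRUE_DELETION = "TRUE_DELETION"
    PSEUDOGENIZATION = "PSEUDOGENIZATION"
    ANNOTATION_DROPOUT = "ANNOTATION_DROPOUT"
    MOVED_UNANCHORED = "MOVED_UNANCHORED"


@dataclass(frozen=True)
class TruthRecord:
    """Planted fate of one reference gene; the acceptance oracle."""

    gene_id: str
    event: Event
    detail: str = ""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome pair.

    Divergences are substitutions/site between reference and query
    orthologs (split evenly over the two branches); ``pseudogene_divergence``
    applies on the query branch at pseudogenized loci and must exceed the
    background so that cross-species read mapping fails there.
    """

    n_genes: int = 200
    n_scaffolds: int = 4
    gene_len_mean: int = 900          # CDS length, bp
    intergenic_len_mean: int = 400
    n_exons_range: tuple[int, int] = (2, 4)
    background_divergence: float = 0.05
    pseudogene_divergence: float = 0.25
    n_true_deletion: int = 8
    n_pseudogenization: int = 4
    n_annotation_dropout: int = 4
    n_moved_unanchored: int = 4
    read_coverage: float = 20.0
    read_len: int = 100
    read_error_rate: float = 0.001
    n_inversions: int = 2
    seed: int = 7
    unanchored_prefix: str = DEFAULT_UNANCHORED_PREFIX

    @property
    def n_events(self) -> int:
        return (
            self.n_true_deletion
            + self.n_pseudogenization
            + self.n_annotation_dropout
            + self.n_moved_unanchored
        )

    def validate(self) -> None:
        counts = (
            self.n_genes,
            self.n_true_deletion,
            self.n_pseudogenization,
            self.n_annotation_dropout,
            self.n_moved_unanchored,
            self.n_inversions,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("all counts must be >= 0")
        if self.n_genes == 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_events > self.n_genes:
            raise ConfigurationError(
                f"planted events ({self.n_events}) exceed n_genes ({self.n_genes})"
            )
        if not 0.0 <= self.background_divergence < 0.75:
            raise ConfigurationError("background_divergence outside [0, 0.75)")
        if self.n_events and self.background_divergence >= self.pseudogene_divergence:
            raise ConfigurationError(
                "background_divergence must be below pseudogene_divergence"
            )
        if self.n_scaffolds < 1 or self.n_scaffolds > self.n_genes:
            raise ConfigurationError("n_scaffolds must be in [1, n_genes]")
        lo, hi = self.n_exons_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("invalid n_exons_range")


# ------------------------------------------------------------------ sequence helpers

def random_dna(rng: np.random.Generator, length: int) -> str:
    return _NT[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site i.i.d. substitution to a uniformly chosen different base."""
    if rate <= 0.0 or not seq:
        # consume no randomness so that rate=0 stays byte-stable
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    # map bytes -> 0..3 via lookup table
    lut = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate(NUCLEOTIDES):
        lut[ord(c)] = i
    states = lut[arr]
    hit = rng.random(states.size) < rate
    shift = rng.integers(1, 4, size=int(hit.sum()))
    states[hit] = (states[hit] + shift) % 4
    return _NT[states].tobytes().decode()


def mutate_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Mutate a coding sequence, reverting any codon that became a stop.

    Keeps the translated product free of internal stops so both species'
    annotated proteins remain valid; the revert rule is deterministic.
    """
    mutated = mutate_dna(cds, rate, rng)
    if mutated == cds:
        return mutated
    out = []
    for i in range(0, len(cds), 3):
        codon = mutated[i : i + 3]
        if codon in STOP_CODONS:
            codon = cds[i : i + 3]
        out.append(codon)
    return "".join(out)


def synonymous_recode(cds: str, rng: np.random.Generator) -> str:
    """Rewrite each codon as a random different synonym where one exists.

    The encoded protein is unchanged while the DNA diverges at most third
    positions - the simulator's model of purifying selection on conserved
    residues of a pseudogene.
    """
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = standard_dna_table.forward_table.get(codon)
        if aa is None:
            out.append(codon)
            continue
        options = [c for c in _SYNONYMS[aa] if c != codon]
        out.append(options[rng.integers(0, len(options))] if options else codon)
    return "".join(out)


def translate_cds(cds: str) -> str:
    return str(Seq(cds[: len(cds) // 3 * 3]).translate()).rstrip("*")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ------------------------------------------------------------------ ancestral layout

@dataclass
class _Locus:
    index: int
    scaffold_idx: int
    spacer: str
    cds: str
    introns: list[str]
    exon_codons: list[int]  # codons per exon
    event: Event = Event.NONE

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


def _ancestral_loci(cfg: SimConfig, rng: np.random.Generator) -> list[_Locus]:
    per_scaf = [cfg.n_genes // cfg.n_scaffolds] * cfg.n_scaffolds
    for i in range(cfg.n_genes % cfg.n_scaffolds):
        per_scaf[i] += 1
    loci: list[_Locus] = []
    idx = 0
    mean_codons = max(cfg.gene_len_mean // 3, MIN_CDS_CODONS)
    for s, count in enumerate(per_scaf):
        for _ in range(count):
            n_codons = max(
                MIN_CDS_CODONS, int(rng.normal(mean_codons, mean_codons / 5))
            )
            n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
            n_exons = min(n_exons, max(1, n_codons // 20))
            base = n_codons // n_exons
            exon_codons = [base] * n_exons
            exon_codons[-1] += n_codons - base * n_exons
            cds = "ATG" + "".join(
                SENSE_CODONS[j] for j in rng.integers(0, len(SENSE_CODONS), n_codons - 1)
            )
            introns = [random_dna(rng, INTRON_LENGTH) for _ in range(n_exons - 1)]
            spacer_len = int(rng.integers(cfg.intergenic_len_mean // 2,
                                          cfg.intergenic_len_mean * 3 // 2 + 1))
            loci.append(
                _Locus(idx, s, random_dna(rng, spacer_len), cds, introns, exon_codons)
            )
            idx += 1
    return loci


def _pick_inversions(
    cfg: SimConfig, per_scaffold: dict[int, list[_Locus]], rng: np.random.Generator
) -> list[list[int]]:
    """Choose contiguous gene-index segments whose query order is reversed."""
    segments: list[list[int]] = []
    taken: set[int] = set()
    scaffolds = sorted(per_scaffold)
    attempts = 0
    while len(segments) < cfg.n_inversions and attempts < 1000:
        attempts += 1
        s = scaffolds[int(rng.integers(0, len(scaffolds)))]
        loci = per_scaffold[s]
        if len(loci) < INVERSION_SEGMENT_GENES + 2 * EDGE_BUFFER:
            continue
        start = int(
            rng.integers(EDGE_BUFFER, len(loci) - INVERSION_SEGMENT_GENES - EDGE_BUFFER + 1)
        )
        seg = [loci[start + k].index for k in range(INVERSION_SEGMENT_GENES)]
        guard = set(
            loci[j].index
            for j in range(max(0, start - 2), min(len(loci), start + INVERSION_SEGMENT_GENES + 2))
        )
        if guard & taken:
            continue
        segments.append(seg)
        taken |= guard
    if len(segments) < cfg.n_inversions:
        raise ConfigurationError("could not place the requested inversions")
    return segments


def _assign_events(
    cfg: SimConfig,
    per_scaffold: dict[int, list[_Locus]],
    inversion_guard: set[int],
    rng: np.random.Generator,
) -> dict[int, Event]:
    eligible: list[int] = []
    for s in sorted(per_scaffold):
        loci = per_scaffold[s]
        for pos in range(EDGE_BUFFER, len(loci) - EDGE_BUFFER):
            if loci[pos].index not in inversion_guard:
                eligible.append(loci[pos].index)
    order = rng.permutation(len(eligible))
    chosen: list[int] = []
    for j in order:
        cand = eligible[j]
        if all(abs(cand - c) >= EVENT_MIN_SPACING for c in chosen):
            chosen.append(cand)
            if len(chosen) == cfg.n_events:
                break
    if len(chosen) < cfg.n_events:
        raise ConfigurationError(
            "could not place all planted events with the required spacing; "
            "reduce event counts or increase n_genes"
        )
    events: dict[int, Event] = {}
    cursor = 0
    for ev, n in (
        (Event.TRUE_DELETION, cfg.n_true_deletion),
        (Event.PSEUDOGENIZATION, cfg.n_pseudogenization),
        (Event.ANNOTATION_DROPOUT, cfg.n_annotation_dropout),
        (Event.MOVED_UNANCHORED, cfg.n_moved_unanchored),
    ):
        for _ in range(n):
            events[chosen[cursor]] = ev
            cursor += 1
    return events


# ------------------------------------------------------------------ genome assembly

def _gene_piece(
    cds: str, introns: list[str], exon_codons: list[int]
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate exons and introns; return (sequence, exon offsets)."""
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    cds_pos = 0
    for i, ncod in enumerate(exon_codons):
        exon = cds[cds_pos : cds_pos + 3 * ncod]
        cds_pos += 3 * ncod
        exons.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    return "".join(parts), exons


def _pseudogenize(locus: _Locus, ref_cds: str, cfg: SimConfig, rng: np.random.Generator) -> str:
    """Derive the query pseudogene CDS: heavy divergence, a synonymously
    recoded conserved window matching the reference protein, one planted
    premature stop upstream of the window and a 1-bp deletion downstream."""
    n = locus.n_codons
    w0 = n // 2 - CONSERVED_WINDOW_CODONS // 2
    stop_at = max(2, n // 5)
    fs_codon = w0 + CONSERVED_WINDOW_CODONS + (n - w0 - CONSERVED_WINDOW_CODONS) // 2
    diverged = mutate_dna(locus.cds, cfg.pseudogene_divergence, rng)
    codons = [diverged[i : i + 3] for i in range(0, len(diverged), 3)]
    window = synonymous_recode(
        ref_cds[3 * w0 : 3 * (w0 + CONSERVED_WINDOW_CODONS)], rng
    )
    codons[w0 : w0 + CONSERVED_WINDOW_CODONS] = [
        window[i : i + 3] for i in range(0, len(window), 3)
    ]
    codons[stop_at] = "TAA"
    seq = "".join(codons)
    cut = 3 * fs_codon + 1
    return seq[:cut] + seq[cut + 1 :]  # 1-bp deletion => frameshift


def simulate_pair(
    config: SimConfig,
) -> tuple[AnnotatedGenome, AnnotatedGenome, list[TruthRecord]]:
    """Simulate the annotated reference/query genome pair and truth table.

    Identical configs (including seed) give identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    loci = _ancestral_loci(config, rng)
    per_scaffold: dict[int, list[_Locus]] = {}
    for loc in loci:
        per_scaffold.setdefault(loc.scaffold_idx, []).append(loc)

    inversions = (
        _pick_inversions(config, per_scaffold, rng) if config.n_inversions else []
    )
    inv_guard: set[int] = set()
    for seg in inversions:
        inv_guard.update(seg)
        inv_guard.update({seg[0] - 1, seg[0] - 2, seg[-1] + 1, seg[-1] + 2})
    events = _assign_events(config, per_scaffold, inv_guard, rng)
    for loc in loci:
        loc.event = events.get(loc.index, Event.NONE)

    half = config.background_divergence / 2.0
    terminal_spacers = {
        s: random_dna(rng, config.intergenic_len_mean) for s in sorted(per_scaffold)
    }

    # reference branch
    ref_seqs: dict[str, str] = {}
    ref_genes: list[GeneModel] = []
    ref_cds_by_index: dict[int, str] = {}
    for s in sorted(per_scaffold):
        name = f"scaffold_{s + 1}"
        parts: list[str] = []
        pos = 0
        for loc in per_scaffold[s]:
            spacer = mutate_dna(loc.spacer, half, rng)
            parts.append(spacer)
            pos += len(spacer)
            cds = mutate_cds(loc.cds, half, rng)
            introns = [mutate_dna(i, half, rng) for i in loc.introns]
            piece, exon_offsets = _gene_piece(cds, introns, loc.exon_codons)
            gid = f"g{loc.index + 1:04d}"
            ref_genes.append(
                GeneModel(
                    gene_id=gid,
                    scaffold=name,
                    start=pos,
                    end=pos + len(piece),
                    strand="+",
                    exons=[(pos + a, pos + b) for a, b in exon_offsets],
                    protein=translate_cds(cds),
                )
            )
            ref_cds_by_index[loc.index] = cds
            parts.append(piece)
            pos += len(piece)
        parts.append(mutate_dna(terminal_spacers[s], half, rng))
        ref_seqs[name] = "".join(parts)

    # query branch
    inv_membership: dict[int, int] = {}
    for seg_id, seg in enumerate(inversions):
        for gi in seg:
            inv_membership[gi] = seg_id

    query_seqs: dict[str, str] = {}
    query_genes: list[GeneModel] = []
    moved: list[tuple[_Locus, str]] = []
    truth_detail: dict[int, str] = {}
    for s in sorted(per_scaffold):
        name = f"scaffold_{s + 1}"
        ordered: list[_Locus] = []
        i = 0
        scaf_loci = per_scaffold[s]
        while i < len(scaf_loci):
            loc = scaf_loci[i]
            if loc.index in inv_membership:
                seg = inversions[inv_membership[loc.index]]
                ordered.extend(reversed([l for l in scaf_loci if l.index in seg]))
                i += len(seg)
            else:
                ordered.append(loc)
                i += 1
        parts = []
        pos = 0
        for loc in ordered:
            spacer = mutate_dna(loc.spacer, half, rng)
            parts.append(spacer)
            pos += len(spacer)
            ev = loc.event
            if ev in (Event.TRUE_DELETION, Event.MOVED_UNANCHORED):
                if ev is Event.MOVED_UNANCHORED:
                    cds = mutate_cds(loc.cds, half, rng)
                    introns = [mutate_dna(x, half, rng) for x in loc.introns]
                    piece, _ = _gene_piece(cds, introns, loc.exon_codons)
                    moved.append((loc, piece))
                continue
            if ev is Event.PSEUDOGENIZATION:
                cds = _pseudogenize(loc, ref_cds_by_index[loc.index], config, rng)
                introns = [
                    mutate_dna(x, config.pseudogene_divergence, rng) for x in loc.introns
                ]
                # exon codon splits no longer align after the frameshift;
                # carve the (shortened) pseudo-CDS into the same exon count
                piece, _ = _pseudo_piece(cds, introns, loc.exon_codons)
                truth_detail[loc.index] = f"pseudogene at {name}:{pos}-{pos + len(piece)}"
                parts.append(piece)
                pos += len(piece)
                continue
            cds = mutate_cds(loc.cds, half, rng)
            introns = [mutate_dna(x, half, rng) for x in loc.introns]
            piece, exon_offsets = _gene_piece(cds, introns, loc.exon_codons)
            if ev is Event.ANNOTATION_DROPOUT:
                truth_detail[loc.index] = f"intact locus at {name}:{pos}-{pos + len(piece)}"
            else:
                qid = f"q{loc.index + 1:04d}"
                query_genes.append(
                    GeneModel(
                        gene_id=qid,
                        scaffold=name,
                        start=pos,
                        end=pos + len(piece),
                        strand="+",
                        exons=[(pos + a, pos + b) for a, b in exon_offsets],
                        protein=translate_cds(cds),
                    )
                )
            parts.append(piece)
            pos += len(piece)
        parts.append(mutate_dna(terminal_spacers[s], half, rng))
        query_seqs[name] = "".join(parts)

    for k, (loc, piece) in enumerate(moved, start=1):
        name = f"{config.unanchored_prefix}{k}"
        pad5 = random_dna(rng, 500)
        pad3 = random_dna(rng, 500)
        query_seqs[name] = pad5 + piece + pad3
        truth_detail[loc.index] = f"moved to {name}"

    truth = [
        TruthRecord(
            gene_id=f"g{loc.index + 1:04d}",
            event=loc.event,
            detail=truth_detail.get(loc.index, ""),
        )
        for loc in loci
    ]
    ref = AnnotatedGenome(ref_seqs, ref_genes, config.unanchored_prefix)
    query = AnnotatedGenome(query_seqs, query_genes, config.unanchored_prefix)
    return ref, query, truth


def _pseudo_piece(cds: str, introns: list[str], exon_codons: list[int]) -> tuple[str, list[tuple[int, int]]]:
    """Split a disrupted CDS across the locus's intron structure.

    Uses the original exon *lengths* in bp as far as the shortened CDS
    allows; the final exon absorbs the difference.
    """
    lengths = [3 * n for n in exon_codons]
    total = len(cds)
    cuts: list[int] = []
    acc = 0
    for L in lengths[:-1]:
        acc = min(acc + L, total)
        cuts.append(acc)
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(cds[prev:c])
        prev = c
    pieces.append(cds[prev:])
    parts: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i, exon in enumerate(pieces):
        exons.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    return "".join(parts), exons


# ------------------------------------------------------------------ reads

def simulate_reads(
    sequences: dict[str, str],
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform single-end reads from both strands of a sequence set.

    Read count is ``floor(coverage * total_length / read_len)``; start
    positions are uniform over valid starts, scaffolds weighted by the
    number of valid starts.  Deterministic under a fixed seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len < 31:
        raise ValueError("read_len must be >= 31")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    names = list(sequences)
    valid = [len(sequences[n]) - read_len + 1 for n in names]
    usable = [(n, v) for n, v in zip(names, valid) if v > 0]
    if not usable:
        raise ValueError("read_len exceeds every scaffold length")
    total_len = sum(len(s) for s in sequences.values())
    n_reads = int(coverage * total_len // read_len)
    rng = np.random.default_rng(seed)
    weights = np.array([v for _, v in usable], dtype=float)
    weights /= weights.sum()
    scaf_choice = rng.choice(len(usable), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        name, v = usable[scaf_choice[i]]
        start = int(rng.integers(0, v))
        seq = sequences[name][start : start + read_len]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        if error_rate > 0:
            seq = mutate_dna(seq, error_rate, rng)
        reads.append((f"read_{i + 1:07d}", seq))
    return reads


def write_truth_table(path: str, truth: list[TruthRecord]) -> None:
    from .io import write_tsv

    write_tsv(
        path,
        [(t.gene_id, t.event.value, t.detail) for t in truth],
        ("gene_id", "event", "detail"),
    )


def read_truth_table(path: str) -> list[TruthRecord]:
    from .io import read_tsv

    _, rows = read_tsv(path)
    return [TruthRecord(r[0], Event(r[1]), r[2] if len(r) > 2 else "") for r in rows]
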