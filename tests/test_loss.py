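"""The four-filter loss pipeline: unit behavior and end-to-end truth recovery."""

import numpy as np
import pytest

from syntloss.genome import GeneModel
from syntloss.loss import (
    DepthSummary,
    FilterThresholds,
    LossCandidate,
    LossStatus,
    ResidueReport,
    SixFrameHit,
    call_candidates,
    classify,
    depth_validate,
    detect_losses,
    inspect_residues,
    map_reads,
    rescue_missannotation,
    rescue_unanchored,
    status_counts,
)
from syntloss.simulate import Event, translate_cds

BACK_TRANSLATE = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTT", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}


def back_translate(protein):
    return "".join(BACK_TRANSLATE[aa] for aa in protein)


def _gene(gene_id="g1", scaffold="s1", start=100, end=1600):
    return GeneModel(gene_id, scaffold, start, end, "+", [(start, end)], None)


class TestDepthValidate:
    def _track(self, values):
        return {"s1": np.asarray(values)}

    def test_all_zero_track_supports_loss(self):
        gene = _gene(start=0, end=1500)
        track = self._track(np.zeros(1500))
        summary, supports = depth_validate(gene, track, FilterThresholds())
        assert summary == DepthSummary(0.0, 0.0)
        assert supports

    def test_uniform_high_depth_rescues(self):
        gene = _gene(start=0, end=1500)
        track = self._track(np.full(1500, 30))
        summary, supports = depth_validate(gene, track, FilterThresholds())
        assert summary.mean_depth == 30.0
        assert summary.body_coverage == 1.0
        assert not supports

    def test_both_criteria_strict(self):
        # depth 1 over exactly 4% of the body: both strict inequalities hold
        body = np.zeros(1000)
        body[:40] = 1
        gene = _gene(start=0, end=1000)
        summary, supports = depth_validate(gene, self._track(body), FilterThresholds())
        assert summary.mean_depth == pytest.approx(0.04)
        assert summary.body_coverage == pytest.approx(0.04)
        assert supports

    def test_boundary_coverage_fails(self):
        # coverage exactly 5% violates the strict inequality
        body = np.zeros(1000)
        body[:50] = 1
        gene = _gene(start=0, end=1000)
        _, supports = depth_validate(gene, self._track(body), FilterThresholds())
        assert not supports

    def test_zero_length_body_rejected(self):
        gene = _gene(start=10, end=10)
        with pytest.raises(ValueError):
            depth_validate(gene, self._track(np.zeros(100)), FilterThresholds())


class TestMapReads:
    def test_empty_read_set_gives_zero_track(self):
        track, stats = map_reads([], {"s": "ACGT" * 100})
        assert track["s"].sum() == 0
        assert stats["mapped"] == 0

    def test_reads_from_self_give_expected_depth(self):
        from syntloss.simulate import random_dna, simulate_reads

        genome = {"s": random_dna(np.random.default_rng(5), 30_000)}
        reads = simulate_reads(genome, coverage=10, read_len=100, seed=6)
        track, stats = map_reads(reads, genome)
        interior = track["s"][2000:28000]
        assert stats["unmapped"] == 0
        assert abs(interior.mean() - 10) / 10 < 0.2

    def test_deleted_gene_body_near_zero_depth(
        self, genome_pair, fixture_depth, planted_events
    ):
        ref, _, _ = genome_pair
        for gid, ev in planted_events.items():
            if ev is Event.TRUE_DELETION:
                gene = ref.gene(gid)
                body = fixture_depth[gene.scaffold][gene.start : gene.end]
                assert body.mean() < 1.0
                assert (body > 0).mean() < 0.05


class TestSixFrameInspection:
    def test_exact_back_translation_is_perfect(self):
        protein = "MHEAGAWGHEEAEQLKRRNDCWYVPFSTMHEAGAWGHEE"
        dna = back_translate(protein)
        assert translate_cds(dna) == protein
        report = inspect_residues(protein, dna)
        assert report.identity == 1.0
        assert report.n_premature_stops == 0
        assert report.n_frameshifts == 0
        assert report.longest_conserved_run == len(protein)

    def test_planted_stop_and_frameshift_detected(self):
        rng = np.random.default_rng(11)
        aa = "ARNDCQEGHILKMFPSTWYV"
        protein = "M" + "".join(aa[i] for i in rng.integers(0, 20, 119))
        dna = back_translate(protein)
        # premature stop at codon 30, 1-bp deletion after codon 80
        dna = dna[:90] + "TAA" + dna[93:]
        dna = dna[: 80 * 3] + dna[80 * 3 + 1 :]
        report = inspect_residues(protein, dna, min_hit_score=30)
        assert report.n_premature_stops >= 1
        assert report.n_frameshifts >= 1
        assert report.longest_conserved_run >= 10

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            inspect_residues("MA", "AC")


class TestClassify:
    def _cand(self):
        return LossCandidate("g1", "blk_0001", ("s1", 0, 1000))

    def _hit(self):
        return SixFrameHit(100, 0.9, 0.9, 0, "+", (0, 90), (0, 270), 81, 90, 0, 40)

    def test_unanchored_takes_precedence(self):
        call = classify(
            self._cand(), ("un_1", self._hit()), self._hit(), None, None, None
        )
        assert call.status is LossStatus.RESCUED_UNANCHORED

    def test_read_evidence_rescue(self):
        call = classify(
            self._cand(), None, None, DepthSummary(5.0, 0.9), False, None
        )
        assert call.status is LossStatus.RESCUED_READ_EVIDENCE

    def test_conserved_run_threshold_splits_loss_classes(self):
        depth = DepthSummary(0.0, 0.0)
        below = ResidueReport(0.2, 9, 1, 1, 2)
        at = ResidueReport(0.5, 10, 1, 1, 2)
        c1 = classify(self._cand(), None, None, depth, True, below)
        c2 = classify(self._cand(), None, None, depth, True, at)
        assert c1.status is LossStatus.TRUE_LOSS_ABSENT
        assert c2.status is LossStatus.TRUE_LOSS_PSEUDOGENIZED

    def test_missing_evidence_rejected(self):
        with pytest.raises(ValueError):
            classify(self._cand(), None, None, None, None, None)


class TestCandidates:
    def test_zero_divergence_no_events_no_candidates(self):
        from syntloss.orthology import reciprocal_best_hits
        from syntloss.simulate import SimConfig, simulate_pair
        from syntloss.synteny import chain_anchors, rank_anchors

        cfg = SimConfig(
            n_genes=40,
            n_scaffolds=1,
            background_divergence=0.0,
            n_true_deletion=0,
            n_pseudogenization=0,
            n_annotation_dropout=0,
            n_moved_unanchored=0,
            n_inversions=0,
            seed=2,
        )
        ref, query, _ = simulate_pair(cfg)
        anchors = reciprocal_best_hits(ref.proteins(), query.proteins())
        blocks = chain_anchors(rank_anchors(anchors, ref, query))
        assert call_candidates(blocks, ref, query) == []

    def test_candidates_are_exactly_planted_events(
        self, genome_pair, fixture_blocks, planted_events
    ):
        ref, query, _ = genome_pair
        cands = call_candidates(fixture_blocks, ref, query)
        assert {c.ref_gene_id for c in cands} == set(planted_events)


class TestRescues:
    def test_moved_gene_rescued_from_unanchored(
        self, genome_pair, fixture_calls, planted_events
    ):
        by_gene = {c.candidate.ref_gene_id: c for c in fixture_calls}
        for gid, ev in planted_events.items():
            if ev is Event.MOVED_UNANCHORED:
                assert by_gene[gid].status is LossStatus.RESCUED_UNANCHORED
                assert by_gene[gid].unanchored_scaffold.startswith("scaffold_un_")

    def test_dropout_rescued_by_missannotation_filter(
        self, fixture_calls, planted_events
    ):
        by_gene = {c.candidate.ref_gene_id: c for c in fixture_calls}
        for gid, ev in planted_events.items():
            if ev is Event.ANNOTATION_DROPOUT:
                call = by_gene[gid]
                assert call.status is LossStatus.RESCUED_MISSANNOTATION
                assert call.missannotation_hit.identity >= 0.80
                assert call.missannotation_hit.coverage_protein >= 0.80

    def test_no_unanchored_scaffolds_is_noop(self, genome_pair):
        ref, _, _ = genome_pair
        cand = LossCandidate("g0019", "blk_0001", ("scaffold_1", 0, 1000))
        protein = ref.gene("g0019").protein
        assert rescue_unanchored(cand, protein, {}, FilterThresholds()) is None

    def test_perfect_copy_in_window_rescued_with_full_identity(self):
        protein = "MHEAGAWGHEEAEQLKRRNDCWYVPFST" * 3
        dna = "ACGTAC" + back_translate(protein) + "GTACGT"
        cand = LossCandidate("gX", "blk", ("s", 0, len(dna)))
        hit = rescue_missannotation(cand, protein, {"s": dna}, FilterThresholds())
        assert hit is not None
        assert hit.identity == 1.0

    def test_loosening_rescue_thresholds_monotone(
        self, genome_pair, fixture_blocks, fixture_depth
    ):
        ref, query, _ = genome_pair
        strict = detect_losses(ref, query, fixture_blocks, fixture_depth,
                               FilterThresholds())
        loose = detect_losses(
            ref, query, fixture_blocks, fixture_depth,
            FilterThresholds(rescue_min_identity=0.60, rescue_min_coverage=0.60),
        )
        rescued = lambda calls: {
            c.candidate.ref_gene_id
            for c in calls
            if c.status in (LossStatus.RESCUED_UNANCHORED, LossStatus.RESCUED_MISSANNOTATION)
        }
        assert rescued(strict) <= rescued(loose)


class TestEndToEnd:
    def test_statuses_partition_candidates(self, fixture_calls):
        counts = status_counts(fixture_calls)
        assert sum(counts.values()) == len(fixture_calls)

    def test_every_planted_event_classified_correctly(
        self, fixture_calls, planted_events
    ):
        """Loss precision = recall = 1.0 on the default fixture and every
        artifact class is caught by its designated filter."""
        expected_status = {
            Event.TRUE_DELETION: LossStatus.TRUE_LOSS_ABSENT,
            Event.PSEUDOGENIZATION: LossStatus.TRUE_LOSS_PSEUDOGENIZED,
            Event.ANNOTATION_DROPOUT: LossStatus.RESCUED_MISSANNOTATION,
            Event.MOVED_UNANCHORED: LossStatus.RESCUED_UNANCHORED,
        }
        by_gene = {c.candidate.ref_gene_id: c.status for c in fixture_calls}
        assert set(by_gene) == set(planted_events)  # zero unplanted calls
        for gid, ev in planted_events.items():
            assert by_gene[gid] is expected_status[ev], (gid, ev, by_gene[gid])

    def test_expected_status_counts(self, fixture_calls, default_config):
        counts = status_counts(fixture_calls)
        assert counts == {
            "TRUE_LOSS_ABSENT": default_config.n_true_deletion,
            "TRUE_LOSS_PSEUDOGENIZED": default_config.n_pseudogenization,
            "RESCUED_MISSANNOTATION": default_config.n_annotation_dropout,
            "RESCUED_UNANCHORED": default_config.n_moved_unanchored,
            "RESCUED_READ_EVIDENCE": 0,
        }
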