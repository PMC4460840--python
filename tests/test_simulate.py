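"""Synthetic genome generator: determinism, calibration, recoverability."""

import numpy as np
import pytest
from scipy import stats

from mitofrag import vocab
from mitofrag.divergence import divergence_between, paralog_divergence
from mitofrag.genome import ValidationError, at_content
from mitofrag.rearrange import (RearrangementEvent, base, classify_events,
                                extract_order)
from mitofrag.simulate import (GeneratorConfig, evolve_pair, fission_minicircle,
                               generate_ancestor, random_synthetic_pair,
                               simulate_contig)
from conftest import STUDY_EVENTS


class TestGenerateAncestor:
    def test_default_config_is_complete(self, ancestor):
        assert ancestor.is_complete()
        assert len(ancestor.chromosomes) == 1
        assert ancestor.chromosomes[0].record.topology == "circular"

    def test_determinism(self):
        g1 = generate_ancestor(GeneratorConfig(seed=42))
        g2 = generate_ancestor(GeneratorConfig(seed=42))
        assert g1.chromosomes[0].record.residues == \
            g2.chromosomes[0].record.residues
        assert g1.chromosomes[0].features == g2.chromosomes[0].features

    @pytest.mark.parametrize("target", [65.0, 80.0, 90.0])
    def test_at_target_realized_within_two_points(self, target):
        g = generate_ancestor(GeneratorConfig(seed=3, at_target=target))
        realized = at_content(g.chromosomes[0].record)
        assert abs(realized - target) <= 2.0

    def test_control_region_carries_t_stretch(self, ancestor):
        chrom = ancestor.chromosomes[0]
        (feat,) = [f for f in chrom.features if f.name == vocab.CONTROL]
        assert "T" * 8 in chrom.feature_sequence(feat)

    def test_seed_is_mandatory_and_lengths_validated(self):
        with pytest.raises(TypeError):
            GeneratorConfig()
        with pytest.raises(ValidationError):
            GeneratorConfig(seed=1, gene_lengths={"cox1": 0})
        with pytest.raises(ValidationError):
            GeneratorConfig(seed=1, at_target=40.0)


class TestEvolvePair:
    def test_no_events_no_divergence_identical(self, ancestor):
        a, b, truth = evolve_pair(ancestor, [], {}, seed=1)
        assert a.chromosomes[0].record.residues == \
            b.chromosomes[0].record.residues
        assert truth.planted_events == []

    def test_divergence_targets_recovered_within_one_point(self, ancestor):
        targets = {"nad2": 20.0, "cox1": 10.0, "trnW": 5.0, "rrnL": 12.0}
        a, b, _ = evolve_pair(ancestor, [], targets, seed=8)
        for gene, target in targets.items():
            (ca, fa), = a.find_features(gene)
            (cb, fb), = b.find_features(gene)
            realized = divergence_between(ca.feature_sequence(fa),
                                          cb.feature_sequence(fb),
                                          kind=fa.kind).percent
            assert abs(realized - target) <= 1.0, gene

    def test_study_events_recovered_exactly(self, study_pair):
        a, b, truth = study_pair
        recovered = classify_events(extract_order(a), extract_order(b))
        assert {(e.kind, e.genes, e.duplicated) for e in recovered} == \
            {(e.kind, e.genes, e.duplicated) for e in truth.planted_events}

    def test_conflicting_events_rejected(self, ancestor):
        events = [RearrangementEvent(kind="inversion", genes=frozenset(("trnF",))),
                  RearrangementEvent(kind="translocation", genes=frozenset(("trnF",)))]
        with pytest.raises(ValidationError):
            evolve_pair(ancestor, events, {}, seed=1)

    def test_absent_gene_event_rejected(self, ancestor):
        events = [RearrangementEvent(kind="inversion", genes=frozenset(("trnZZ",)))]
        with pytest.raises(ValidationError):
            evolve_pair(ancestor, events, {}, seed=1)


class TestFission:
    def test_canonical_minicircle(self, ancestor):
        g = fission_minicircle(ancestor, {"nad6", "trnC"},
                               {vocab.CONTROL, "trnS1"},
                               {vocab.CONTROL: 1.65, "trnS1": 0.0}, seed=4)
        assert len(g.chromosomes) == 2
        mini = min(g.chromosomes, key=lambda c: len(c.record))
        assert {f.name for f in mini.features} == \
            {"nad6", "trnC", "trnS1", vocab.CONTROL}
        assert g.is_complete()
        assert 800 <= len(mini.record) <= 1100
        assert abs(paralog_divergence(g, vocab.CONTROL).percent - 1.65) <= 0.5
        assert paralog_divergence(g, "trnS1").percent == 0.0

    def test_empty_move_and_duplicate_is_identity(self, ancestor):
        assert fission_minicircle(ancestor, set(), set(), 0.0, seed=1) is ancestor

    def test_zero_paralog_divergence_is_byte_identical(self, ancestor):
        g = fission_minicircle(ancestor, {"nad6", "trnC"},
                               {vocab.CONTROL, "trnS1"}, 0.0, seed=4)
        copies = g.find_features("trnS1")
        seqs = {c.feature_sequence(f) for c, f in copies}
        assert len(copies) == 2 and len(seqs) == 1

    def test_absent_gene_rejected(self, ancestor):
        with pytest.raises(ValidationError):
            fission_minicircle(ancestor, {"trnZZ"}, set(), 0.0, seed=1)


class TestSimulateContig:
    def test_determinism(self, minicircle):
        c1, t1 = simulate_contig(minicircle, seed=12)
        c2, t2 = simulate_contig(minicircle, seed=12)
        assert c1 == c2 and t1.planted_changes == t2.planted_changes

    def test_uniform_error_positions_without_multipliers(self, minicircle):
        """With both multipliers at 1 the error positions are uniform."""
        positions = []
        for seed in range(300):
            _, truth = simulate_contig(minicircle, base_error=0.01,
                                       terminal_multiplier=1.0,
                                       homopolymer_multiplier=1.0, seed=seed)
            positions.extend(c.ref_pos for c in truth.planted_changes)
        n = len(minicircle.record)
        observed, _ = np.histogram(positions, bins=10, range=(0, n))
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 1e-3

    def test_strong_homopolymer_multiplier_dominates_flags(self, minicircle):
        flagged = total = 0
        for seed in range(25):
            _, truth = simulate_contig(minicircle, base_error=0.008,
                                       terminal_multiplier=1.0,
                                       homopolymer_multiplier=10.0, seed=seed)
            total += len(truth.planted_changes)
            flagged += sum(c.homopolymer for c in truth.planted_changes)
        assert flagged > total / 2

    def test_multiplier_validation(self, minicircle):
        with pytest.raises(ValidationError):
            simulate_contig(minicircle, terminal_multiplier=0.5, seed=1)


class TestPlantedRecoveryAtScale:
    def test_events_recovered_over_100_random_pairs(self):
        """Planted rearrangements are recovered exactly across >=100 random
        synthetic genome pairs with up to 4 non-overlapping events."""
        for seed in range(100):
            n_events = 1 + seed % 4
            a, b, truth = random_synthetic_pair(seed, n_events=n_events,
                                                divergence_range=(0.0, 0.0))
            recovered = classify_events(extract_order(a), extract_order(b))
            assert {(e.kind, e.genes, e.duplicated) for e in recovered} == \
                {(e.kind, e.genes, e.duplicated) for e in truth.planted_events}, seed

    def test_divergence_recovered_over_random_configs(self):
        """Realized per-homolog divergence sits within one point of target
        across random pairs (all 38 homologs each)."""
        for seed in range(8):
            a, b, truth = random_synthetic_pair(seed + 500, n_events=0)
            for gene, target in truth.planted_divergence.items():
                (ca, fa) = a.find_features(gene)[0]
                (cb, fb) = b.find_features(gene)[0]
                realized = divergence_between(ca.feature_sequence(fa),
                                              cb.feature_sequence(fb),
                                              kind=fa.kind).percent
                assert abs(realized - target) <= 1.0, (seed, gene)
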