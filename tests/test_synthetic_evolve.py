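"""Generator determinism, ground truth, and qualitative evolutionary signals."""

import numpy as np
import pytest

from kmerdist import (
    EvolutionScenario,
    apply_masking,
    count_kmers,
    d1,
    d2,
    diverged_masked_pair,
    evolve_strain,
    plant_low_complexity,
    proximities,
    random_genome,
    reverse_complement,
    true_blocks,
)


class TestRandomGenome:
    def test_composition_within_binomial_bounds(self):
        genome = random_genome(10_000, (0.25, 0.25, 0.25, 0.25), seed=1)
        for base in "ACGT":
            freq = genome.sequence.count(base) / genome.length
            # 5 s.d. of a binomial proportion at p = 0.25, n = 10000
            assert abs(freq - 0.25) < 5 * np.sqrt(0.25 * 0.75 / 10_000)

    def test_degenerate_composition(self):
        assert random_genome(50, (1, 0, 0, 0), seed=1).sequence == "A" * 50

    def test_determinism(self):
        a = random_genome(1000, seed=42)
        b = random_genome(1000, seed=42)
        assert a.sequence == b.sequence
        assert a.sequence != random_genome(1000, seed=43).sequence

    def test_invalid_composition(self):
        with pytest.raises(ValueError, match="base_composition"):
            random_genome(100, (0.5, 0.5, 0.5, 0.5))


class TestEvolveStrain:
    def test_zero_events_identity(self):
        ancestor = random_genome(5000, seed=3)
        descendant, truth = evolve_strain(ancestor, EvolutionScenario(ancestor_length=5000))
        assert descendant.sequence == ancestor.sequence
        assert truth.inverted_intervals == [] and truth.substituted_positions == []

    def test_whole_sequence_inversion(self):
        ancestor = random_genome(2000, seed=4)
        scenario = EvolutionScenario(
            ancestor_length=2000, n_inversions=1, inversion_length_range=(2000, 2000)
        )
        descendant, truth = evolve_strain(ancestor, scenario)
        assert descendant.sequence == reverse_complement(ancestor.sequence)
        assert truth.inverted_intervals == [(1, 2000)]

    def test_substitution_count_within_binomial_bounds(self):
        ancestor = random_genome(100_000, seed=5)
        scenario = EvolutionScenario(ancestor_length=100_000, substitution_rate=0.01)
        descendant, truth = evolve_strain(ancestor, scenario)
        n = len(truth.substituted_positions)
        assert abs(n - 1000) < 5 * np.sqrt(1000 * 0.99)
        # every recorded position really differs; un-recorded positions match
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(ancestor.sequence, descendant.sequence))
            if a != b
        ]
        assert diffs == truth.substituted_positions
        k7 = lambda rec: count_kmers(rec, 7)
        assert d1(k7(ancestor), k7(descendant)).value > 0

    def test_inversions_recorded_and_nonoverlapping(self):
        ancestor = random_genome(50_000, seed=6)
        scenario = EvolutionScenario(
            ancestor_length=50_000, n_inversions=8, inversion_length_range=(500, 2000)
        )
        _, truth = evolve_strain(ancestor, scenario)
        ivs = truth.inverted_intervals
        assert len(ivs) == 8
        assert all(e1 < s2 for (_, e1), (s2, _) in zip(ivs, ivs[1:]))

    def test_impossible_placement_raises(self):
        ancestor = random_genome(1000, seed=7)
        scenario = EvolutionScenario(
            ancestor_length=1000, n_inversions=5, inversion_length_range=(900, 999)
        )
        with pytest.raises(RuntimeError, match="fewer or shorter"):
            evolve_strain(ancestor, scenario)

    def test_determinism(self):
        ancestor = random_genome(10_000, seed=8)
        scenario = EvolutionScenario(
            ancestor_length=10_000, substitution_rate=0.02, n_inversions=2,
            inversion_length_range=(100, 500), seed=11,
        )
        d_1, t_1 = evolve_strain(ancestor, scenario)
        d_2, t_2 = evolve_strain(ancestor, scenario)
        assert d_1.sequence == d_2.sequence
        assert t_1.inverted_intervals == t_2.inverted_intervals
        assert t_1.substituted_positions == t_2.substituted_positions


class TestTrueBlocks:
    def test_no_events_single_direct_block(self):
        from kmerdist import GroundTruth

        blocks = true_blocks(GroundTruth(), 10_000)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start, b.end, b.orientation, b.identity_pct) == (1, 10_000, "direct", 100.0)
        r = proximities(blocks, 10_000, 10_000)
        assert r.p_syn == 1.0 and r.p_dsyn == 1.0

    def test_internal_inversion_splits_blocks(self):
        from kmerdist import GroundTruth

        truth = GroundTruth(inverted_intervals=[(1001, 2000)])
        blocks = true_blocks(truth, 5000)
        assert [(b.start, b.end, b.orientation) for b in blocks] == [
            (1, 1000, "direct"),
            (1001, 2000, "inverse"),
            (2001, 5000, "direct"),
        ]
        r = proximities(blocks, 5000, 5000)
        assert r.p_syn == 1.0
        assert r.p_dsyn == pytest.approx(4000 / 5000)

    def test_identity_reflects_local_substitution_density(self):
        from kmerdist import GroundTruth

        truth = GroundTruth(
            inverted_intervals=[(101, 200)],
            substituted_positions=[150, 151, 152, 153, 154, 250],
        )
        blocks = true_blocks(truth, 1000)
        inverse = next(b for b in blocks if b.orientation == "inverse")
        assert inverse.identity_pct == pytest.approx(100 * (1 - 5 / 100))
        tail = next(b for b in blocks if b.start == 201)
        assert tail.identity_pct == pytest.approx(100 * (1 - 1 / 800))

    def test_min_block_drops_short_segments(self):
        from kmerdist import GroundTruth

        truth = GroundTruth(inverted_intervals=[(11, 990)])
        blocks = true_blocks(truth, 1000, min_block=50)
        assert [(b.start, b.end) for b in blocks] == [(11, 990)]


class TestPlantLowComplexity:
    def test_zero_tracts_unchanged(self):
        genome = random_genome(5000, seed=9)
        planted, truth = plant_low_complexity(
            genome, EvolutionScenario(ancestor_length=5000)
        )
        assert planted.sequence == genome.sequence
        assert truth.masked_intervals == []

    def test_tracts_are_lowercase_and_repeat(self):
        genome = random_genome(20_000, seed=10)
        scenario = EvolutionScenario(
            ancestor_length=20_000, n_low_complexity_tracts=4,
            tract_length_range=(300, 600),
        )
        planted, truth = plant_low_complexity(genome, scenario)
        assert len(truth.masked_intervals) == 4
        for start, end in truth.masked_intervals:
            tract = planted.sequence[start - 1 : end]
            assert tract.islower()
            # tandem repeat of motif length 1-3: period divides into the tract
            assert any(
                tract == (tract[:m] * (len(tract) // m + 1))[: len(tract)]
                for m in (1, 2, 3)
            )
        # outside the tracts nothing changed
        masked = set()
        for start, end in truth.masked_intervals:
            masked.update(range(start - 1, end))
        for i, (a, b) in enumerate(zip(genome.sequence, planted.sequence)):
            if i not in masked:
                assert a == b

    def test_masked_mode_excludes_exactly_tract_windows(self):
        genome = random_genome(10_000, seed=11)
        scenario = EvolutionScenario(
            ancestor_length=10_000, n_low_complexity_tracts=3,
            tract_length_range=(200, 500),
        )
        planted, truth = plant_low_complexity(genome, scenario)
        k = 5
        spec = count_kmers(apply_masking(planted, "masked"), k)
        # windows overlapping any tract position, by interval arithmetic
        expected_skipped = 0
        L = genome.length
        bad = np.zeros(L, dtype=bool)
        for start, end in truth.masked_intervals:
            bad[start - 1 : end] = True
        for i in range(L - k + 1):
            if bad[i : i + k].any():
                expected_skipped += 1
        assert spec.skipped_windows == expected_skipped
        assert spec.total_valid == (L - k + 1) - expected_skipped


class TestDoseResponse:
    def test_distance_up_proximity_not_up(self):
        """Median D1(k=7) rises with substitution load; P_SYN never rises."""
        rates = [0.0, 0.005, 0.01, 0.02, 0.05]
        medians = []
        psyns = []
        for rate in rates:
            d1_values = []
            psyn_values = []
            for rep in range(3):
                ancestor = random_genome(20_000, seed=1000 + rep)
                scenario = EvolutionScenario(
                    ancestor_length=20_000, substitution_rate=rate,
                    seed=2000 + rep,
                )
                descendant, truth = evolve_strain(ancestor, scenario)
                d1_values.append(
                    d1(count_kmers(ancestor, 7), count_kmers(descendant, 7)).value
                )
                from kmerdist.synteny import filter_blocks

                blocks = filter_blocks(
                    true_blocks(truth, 20_000), identity_threshold=90.0
                )
                psyn_values.append(proximities(blocks, 20_000, 20_000).p_syn)
            medians.append(float(np.median(d1_values)))
            psyns.append(float(np.median(psyn_values)))
        assert all(a < b for a, b in zip(medians, medians[1:]))
        assert all(a >= b for a, b in zip(psyns, psyns[1:]))


class TestDivergedMaskedPair:
    def test_shared_tracts_divergent_content(self):
        scenario = EvolutionScenario(
            ancestor_length=30_000, substitution_rate=0.02,
            n_low_complexity_tracts=5, tract_length_range=(400, 1600),
        )
        (rec_a, truth_a), (rec_b, truth_b) = diverged_masked_pair(scenario, seed=12)
        assert truth_a.masked_intervals == truth_b.masked_intervals
        assert rec_a.length == rec_b.length == 30_000

    def test_unmasked_distance_exceeds_masked(self):
        scenario = EvolutionScenario(
            ancestor_length=30_000, substitution_rate=0.02,
            n_low_complexity_tracts=5, tract_length_range=(400, 1600),
        )
        (rec_a, _), (rec_b, _) = diverged_masked_pair(scenario, seed=13)
        k = 8
        values = {}
        for mode in ("unmasked", "masked"):
            sa = count_kmers(apply_masking(rec_a, mode), k)
            sb = count_kmers(apply_masking(rec_b, mode), k)
            values[mode] = d2(sa, sb).value
        assert values["unmasked"] > values["masked"]
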