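"""Synthetic genome/expression generator: determinism, structure, recovery."""

import numpy as np
import pytest

from adjacoreg import (
    SimulationConfig,
    find_coregulated_sets,
    select_deregulated,
    simulate_expression,
    simulate_genome,
    simulate_segregation,
    segregation_chi2,
)
from adjacoreg.simulate import make_splice_fixture


SMALL = SimulationConfig(n_chromosomes=2, genes_per_chromosome=150, seed=4)


class TestSimulateGenome:
    def test_zero_genes_gives_empty_catalogue(self):
        cfg = SimulationConfig(genes_per_chromosome=0, n_injected_blocks=0, seed=1)
        assert len(simulate_genome(cfg)) == 0

    def test_same_seed_identical(self):
        assert simulate_genome(SMALL) == simulate_genome(SMALL)

    def test_different_seed_differs(self):
        other = SimulationConfig(n_chromosomes=2, genes_per_chromosome=150, seed=5)
        assert simulate_genome(SMALL) != simulate_genome(other)

    def test_genes_non_overlapping_and_ordered(self):
        cat = simulate_genome(SMALL)
        for chrom in cat.chromosomes:
            genes = cat.genes_on(chrom)
            for a, b in zip(genes, genes[1:]):
                assert a.end < b.start

    def test_mean_gap_tracks_lognormal_target(self):
        # gap ~ logN(mu, sigma): mean = exp(mu + sigma^2/2)
        cfg0 = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=1000,
            gap_meanlog=np.log(2000) - 0.18, gap_sdlog=0.6,
            n_injected_blocks=0,
        )
        gaps = []
        for seed in range(20):
            cat = simulate_genome(
                SimulationConfig(**{**cfg0.__dict__, "seed": seed})
            )
            genes = cat.genes_on("chr1")
            gaps.extend(b.start - a.end - 1 for a, b in zip(genes, genes[1:]))
        assert np.mean(gaps) == pytest.approx(2000, rel=0.10)

    def test_strand_probability_respected(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=2000,
            strand_probability=0.7, n_injected_blocks=0, seed=2,
        )
        cat = simulate_genome(cfg)
        frac_plus = np.mean([g.strand == "+" for g in cat])
        assert frac_plus == pytest.approx(0.7, abs=0.03)


class TestSimulateExpression:
    def test_zero_injection_truth_is_all_null(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=200, n_injected_blocks=0, seed=3
        )
        cat = simulate_genome(cfg)
        _, truth = simulate_expression(cat, cfg)
        assert set(truth.labels.values()) == {"null"}
        assert truth.blocks == ()

    def test_fixed_seed_bit_identical_table(self):
        cat = simulate_genome(SMALL)
        t1, _ = simulate_expression(cat, SMALL)
        t2, _ = simulate_expression(cat, SMALL)
        assert t1.equals(t2)

    def test_blocks_occupy_consecutive_ranks(self):
        cfg = SimulationConfig(
            n_chromosomes=2, genes_per_chromosome=200, n_injected_blocks=8,
            block_size=3, seed=6,
        )
        cat = simulate_genome(cfg)
        _, truth = simulate_expression(cat, cfg)
        assert len(truth.blocks) == 8
        for block in truth.blocks:
            for a, b in zip(block, block[1:]):
                assert cat.immediate_neighbours(a)[1] == b

    def test_injected_members_recovered_by_default_thresholds(self):
        hits = total = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_chromosomes=2, genes_per_chromosome=250,
                n_injected_blocks=10, block_size=2,
                block_effect=2.0, block_p_scale=1e-4, seed=seed,
            )
            cat = simulate_genome(cfg)
            table, truth = simulate_expression(cat, cfg)
            de = select_deregulated(table)
            injected = [g for g, lab in truth.labels.items() if lab.startswith("injected")]
            hits += sum(1 for g in injected if g in de)
            total += len(injected)
        assert hits / total >= 0.95

    def test_duplicate_pairs_adjacent_and_familied(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=300,
            n_injected_blocks=0, n_duplicate_pairs=5, seed=8,
        )
        cat = simulate_genome(cfg)
        _, truth = simulate_expression(cat, cfg)
        assert len(truth.duplicate_pairs) == 5
        for a, b in truth.duplicate_pairs:
            assert cat.immediate_neighbours(a)[1] == b
            assert truth.family_map[a] == truth.family_map[b]

    def test_duplicate_exclusion_removes_injected_duplicates(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=300,
            n_injected_blocks=0, n_duplicate_pairs=6, seed=9,
        )
        cat = simulate_genome(cfg)
        table, truth = simulate_expression(cat, cfg)
        de = select_deregulated(table)
        sets_with, _, n_excluded = find_coregulated_sets(cat, de, truth.family_map)
        assert n_excluded == 6
        assert all(
            set(s.members) & set(p) == set()
            for s in sets_with
            for p in truth.duplicate_pairs
        )

    def test_capacity_exceeded_rejected(self):
        cfg = SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=10, n_injected_blocks=20, seed=1
        )
        cat = simulate_genome(cfg)
        with pytest.raises(ValueError, match="capacity|slots"):
            simulate_expression(cat, cfg)

    def test_power_nondecreasing_in_block_count(self):
        detected = []
        for n_blocks in (0, 5, 15):
            cfg = SimulationConfig(
                n_chromosomes=2, genes_per_chromosome=300,
                n_injected_blocks=n_blocks, block_effect=2.0, seed=12,
            )
            cat = simulate_genome(cfg)
            table, truth = simulate_expression(cat, cfg)
            sets, _, _ = find_coregulated_sets(cat, select_deregulated(table), truth.family_map)
            detected.append(len(sets))
        assert detected[0] <= detected[1] <= detected[2]
        assert detected[1] >= 5 and detected[2] >= 15


class TestSimulateSegregation:
    def test_extreme_probabilities(self):
        assert simulate_segregation(50, 0.0, seed=1) == (0, 50)
        assert simulate_segregation(50, 1.0, seed=1) == (50, 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_segregation(0, 0.25)
        with pytest.raises(ValueError):
            simulate_segregation(10, 1.5)

    def test_chi2_rejects_at_alpha_under_true_ratio(self):
        rejections = 0
        n_rep = 400
        for seed in range(n_rep):
            mut, wt = simulate_segregation(195, 0.25, seed=seed)
            _, _, p = segregation_chi2((mut, wt), (1, 3))
            rejections += p <= 0.05
        # 3-sigma binomial band around 0.05
        band = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) <= band + 0.01


class TestSpliceFixture:
    def test_same_seed_identical_fixture(self):
        m1, e1 = make_splice_fixture(seed=3)
        m2, e2 = make_splice_fixture(seed=3)
        assert m1 == m2 and e1 == e2

    def test_expectation_is_self_consistent(self):
        from adjacoreg import predict_truncation

        for seed in (0, 1, 2):
            model, expected = make_splice_fixture(seed=seed)
            assert predict_truncation(model, 1) == expected
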