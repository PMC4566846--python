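import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from magicpop.breeding_sim import (
    EIGHT_FOUNDERS,
    FunnelDesign,
    design_expectations,
    enumerate_design,
    expected_contributions,
    genotype_mosaics,
    simulate_founder_panel,
    simulate_funnel_population,
    synthetic_map,
)
from magicpop.breeding_sim import _ChromFrame, simulate_meiosis


class TestDesignCombinatorics:
    def test_eight_founder_counts(self):
        s = enumerate_design(8)
        assert s.n_two_way == 28
        assert s.n_four_way_crosses == 210
        assert s.n_pools == 70
        assert s.n_funnel_pairs == 35

    def test_four_founder_counts_vs_exhaustive(self):
        # oracle: enumerate unordered pairs of disjoint founder pairs
        founders = list(range(4))
        two_ways = list(itertools.combinations(founders, 2))
        four_ways = {
            frozenset((a, b))
            for a, b in itertools.combinations(two_ways, 2)
            if not set(a) & set(b)
        }
        s = enumerate_design(4)
        assert s.n_two_way == len(two_ways) == 6
        assert s.n_four_way_crosses == len(four_ways) == 3
        assert s.n_pools == 1

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_degenerate_designs_rejected(self, n):
        with pytest.raises(ValueError):
            enumerate_design(n)


class TestExpectedContributions:
    def test_symmetric_without_substitution(self):
        c = expected_contributions(FunnelDesign(substitution=False))
        assert all(v == Fraction(1, 8) for v in c.values())

    def test_substitution_rationals(self):
        c = expected_contributions(FunnelDesign(substitution=True))
        assert c["B"] == Fraction(1, 7)  # B73 takes the substitute slots
        assert c["I"] == Fraction(1, 56)  # CML91
        assert c["C"] == c["F"] == Fraction(3, 28)  # B96, HP301 lose
        for f in "ADEGH":
            assert c[f] == Fraction(1, 8)

    def test_conservation(self):
        c = expected_contributions(FunnelDesign(substitution=True))
        assert sum(c.values()) == 1

    def test_monte_carlo_agrees_with_rationals(self):
        # share of genome is map-independent: use a small fast map
        gmap = synthetic_map(n_markers=40, total_cm=400, n_chromosomes=2, seed=3)
        design = FunnelDesign(n_funnels=35, lines_per_funnel=30)
        pop = simulate_funnel_population(design, gmap, rng=33)
        shares = np.array([m.founder_shares(9) for m in pop])
        exact = expected_contributions(design)
        labels = EIGHT_FOUNDERS + ["I"]
        for i, f in enumerate(labels):
            se = shares[:, i].std() / math.sqrt(len(pop))
            assert abs(shares[:, i].mean() - float(exact[f])) < 3 * se + 1e-9


class TestDesignExpectations:
    def test_junctions_heterozygosity_rix(self):
        s = design_expectations(19.96, generation=6, n_lines=1636)
        assert s.expected_junctions == pytest.approx(79.84)
        assert s.expected_heterozygosity == pytest.approx(0.03125)
        assert s.rix_count == 1_337_430

    def test_rix_two_lines(self):
        assert design_expectations(19.96, 6, 2).rix_count == 1

    def test_f1_generation_rejected(self):
        with pytest.raises(ValueError):
            design_expectations(19.96, 1, 10)


class TestMeiosis:
    def test_homozygous_parent_invariant(self, magic_map):
        from magicpop.breeding_sim import _founder_genome

        frame = _ChromFrame(magic_map)
        parent = _founder_genome(frame, 3)
        rng = np.random.default_rng(0)
        gam = simulate_meiosis(parent, frame, rng)
        for c, h in gam.items():
            assert (h.founders == 3).all()

    def test_crossover_count_matches_poisson_mean(self):
        # Monte-Carlo oracle: 1-Morgan chromosome -> mean 1 crossover
        import pandas as pd

        from magicpop.breeding_sim import _founder_genome
        from magicpop.genome_model import GeneticMap

        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker_id": ["a", "b"],
                    "chromosome": [1, 1],
                    "position_bp": [1, 10_000_000],
                    "position_cM": [0.0, 100.0],
                }
            )
        )
        frame = _ChromFrame(gmap)
        rng = np.random.default_rng(5)
        n = 10_000
        counts = [len(frame.crossover_positions(1, rng)) for _ in range(n)]
        mean = np.mean(counts)
        se = np.std(counts) / math.sqrt(n)
        assert abs(mean - 1.0) < 3 * se

    def test_zero_length_chromosome_gives_parental_homolog(self):
        import pandas as pd

        from magicpop.breeding_sim import MosaicGenome, constant_homolog
        from magicpop.genome_model import GeneticMap

        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "marker_id": ["a", "b"],
                    "chromosome": [1, 1],
                    "position_bp": [1, 1000],
                    "position_cM": [0.0, 0.0],
                }
            )
        )
        frame = _ChromFrame(gmap)
        parent = MosaicGenome(
            {1: (constant_homolog(1000, 0), constant_homolog(1000, 1))}
        )
        rng = np.random.default_rng(1)
        for _ in range(20):
            gam = simulate_meiosis(parent, frame, rng)
            assert len(gam[1].founders) == 1  # one parental homolog, intact


class TestFunnelPopulation:
    def test_f1_two_way_is_fully_heterozygous(self, magic_map):
        from magicpop.breeding_sim import _ChromFrame, _cross, _founder_genome

        frame = _ChromFrame(magic_map)
        a = _founder_genome(frame, 0)
        b = _founder_genome(frame, 1)
        rng = np.random.default_rng(2)
        f1 = _cross(a, b, frame, rng)
        assert f1.heterozygosity() == pytest.approx(1.0)
        shares = f1.founder_shares(9)
        assert shares[0] == pytest.approx(0.5)
        assert shares[1] == pytest.approx(0.5)

    def test_junction_count_in_expected_band(self, population, magic_map):
        L = magic_map.total_length_morgans()
        mean_j = np.mean([m.junction_count() for m in population])
        assert 0.9 * 4 * L <= mean_j <= 1.0 * 4 * L

    def test_heterozygosity_near_ssd_expectation(self, population):
        het = np.mean([m.heterozygosity() for m in population])
        se = np.std([m.heterozygosity() for m in population]) / math.sqrt(
            len(population)
        )
        assert abs(het - 0.03125) < max(3 * se, 0.004)

    def test_heterozygosity_halves_per_generation(self, magic_map):
        means = []
        for k in (1, 3):
            pop = simulate_funnel_population(
                FunnelDesign(
                    n_funnels=10, lines_per_funnel=6, ssd_generations=k
                ),
                magic_map,
                rng=7,
            )
            means.append(np.mean([m.heterozygosity() for m in pop]))
        ratio = means[1] / means[0]
        assert ratio == pytest.approx(0.25, abs=0.06)

    def test_funnel_and_pedigree_metadata(self, population, design):
        assert len(population) == design.n_funnels * design.lines_per_funnel
        assert population[0].line_id == "1_1"
        flags = [m.nine_founder for m in population]
        assert any(flags) and not all(flags)


class TestGenotyping:
    def test_identity_for_pure_inbred_line(self, magic_map, founders):
        from magicpop.breeding_sim import _ChromFrame, _founder_genome

        frame = _ChromFrame(magic_map)
        mos = _founder_genome(frame, 0)
        mos.line_id = "pure_A"
        geno = genotype_mosaics(
            [mos], founders, magic_map, error_rate=0, missing_rate=0, rng=1
        )
        expected = founders.calls[0]
        ok = expected != 1  # heterozygous founder calls resolve randomly
        assert (geno.calls[0, ok] == expected[ok]).all()

    def test_het_segment_pair_codes_one(self, magic_map, founders):
        from magicpop.breeding_sim import (
            MosaicGenome,
            _ChromFrame,
            constant_homolog,
        )

        frame = _ChromFrame(magic_map)
        mos = MosaicGenome(
            {
                c: (
                    constant_homolog(frame.chrom_end(c), 0),
                    constant_homolog(frame.chrom_end(c), 1),
                )
                for c in frame.chroms
            }
        )
        mos.line_id = "AB"
        geno = genotype_mosaics(
            [mos], founders, magic_map, error_rate=0, missing_rate=0, rng=1
        )
        fA, fB = founders.calls[0], founders.calls[1]
        informative = (
            ((fA == 0) & (fB == 2)) | ((fA == 2) & (fB == 0))
        )
        assert (geno.calls[0, informative] == 1).all()

    def test_call_rate_tracks_missing_rate(self, genotypes):
        rates = genotypes.call_rate()
        se = rates.std() / math.sqrt(len(rates))
        assert abs(rates.mean() - 0.85) < max(3 * se, 0.01)

    def test_maf_concentrates_near_eighths(self, genotypes, founders):
        # design property: RIL allele frequencies pile up near k/8
        calls = genotypes.calls
        called = calls != -1
        p = np.where(called, calls, 0).sum(0) / np.maximum(
            2.0 * called.sum(0), 1
        )
        maf = np.minimum(p, 1 - p)
        dist_to_grid = np.min(
            np.abs(maf[:, None] - np.arange(5)[None, :] / 8), axis=1
        )
        assert np.median(dist_to_grid) < 0.03


def test_synthetic_map_properties():
    gmap = synthetic_map(n_markers=800, seed=4)
    assert gmap.n_markers >= 800 - 5
    assert len(gmap.chromosomes) == 10
    assert gmap.total_length_morgans() == pytest.approx(19.96, abs=1e-6)
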