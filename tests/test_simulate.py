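"""Forward-time simulator: mutagenesis, selection, mating, meiosis,
whole-protocol behaviour and the observation layers."""

import numpy as np
import pytest

from gshuffle.catalogue import Locus, LocusCatalogue
from gshuffle.simulate import (
    MATING_TYPE_A,
    MATING_TYPE_ALPHA,
    PopulationSample,
    SimulationConfig,
    founder_pool,
    haldane_recombination_fraction,
    mate_pool,
    run_gs_rounds,
    select_population,
    simulate_amplicon_counts,
    simulate_isolates,
    sporulate_pool,
    uv_mutagenize,
    wild_type_pool,
)

from conftest import make_catalogue


def haploid_pool(genotypes, mating_types, label="UV"):
    return PopulationSample(
        label,
        np.asarray(genotypes, dtype=np.uint8),
        mating_types=np.asarray(mating_types, dtype=np.uint8),
    )


def diploid_pool(hap1, hap2, label="R1"):
    g = np.stack(
        [np.asarray(hap1, dtype=np.uint8), np.asarray(hap2, dtype=np.uint8)], axis=1
    )
    return PopulationSample(label, g)


class TestUvMutagenize:
    def test_zero_rate_is_identity(self, neutral_catalogue, rng):
        pool = wild_type_pool(neutral_catalogue, 50)
        cfg = SimulationConfig(uv_mutation_rate=0.0, seed=0)
        out = uv_mutagenize(pool, neutral_catalogue, cfg, rng)
        assert (out.genotypes == pool.genotypes).all()
        assert (out.mating_types == pool.mating_types).all()

    def test_poisson_mean_mutations_per_genome(self, rng):
        cat = make_catalogue(n_loci=21)
        pool = wild_type_pool(cat, 10_000)
        cfg = SimulationConfig(uv_mutation_rate=6.0, seed=0)
        out = uv_mutagenize(pool, cat, cfg, rng)
        per_genome = out.genotypes.sum(axis=1)
        se = np.sqrt(6.0 / 10_000)  # Poisson variance / n
        assert abs(per_genome.mean() - 6.0) < 3 * se + 0.05  # slack: draws truncated at 21

    def test_rate_exceeding_catalogue_size_rejected(self, rng):
        cat = make_catalogue(n_loci=21)
        pool = wild_type_pool(cat, 10)
        cfg = SimulationConfig(uv_mutation_rate=30.0, seed=0)
        with pytest.raises(ValueError, match="exceeds catalogue size"):
            uv_mutagenize(pool, cat, cfg, rng)


class TestSelectPopulation:
    def test_no_selection_preserves_expected_frequencies(self, neutral_catalogue):
        # fraction 1.0, zero effects, zero noise: a pure multinomial resample
        reps, freqs = 200, []
        p_true = 0.3
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            genotypes = (rng.random((200, 5)) < p_true).astype(np.uint8)
            pool = haploid_pool(genotypes, [0, 1] * 100)
            cfg = SimulationConfig(population_size=200, selection_fraction=1.0,
                                   fitness_noise_sd=0.0, seed=0)
            out = select_population(pool, neutral_catalogue, cfg, rng)
            freqs.append(out.allele_frequencies() - pool.allele_frequencies())
        mean_shift = np.mean(freqs)
        se = np.sqrt(p_true * (1 - p_true) / 200 / reps / 5)
        assert abs(mean_shift) < 3 * se

    def test_selection_never_decreases_driver_frequency(self):
        cat = make_catalogue(n_loci=3, effects=[1.0, 0.0, 0.0])
        cfg = SimulationConfig(population_size=200, selection_fraction=0.1,
                               fitness_noise_sd=0.0, seed=0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            genotypes = (rng.random((200, 3)) < 0.3).astype(np.uint8)
            pool = haploid_pool(genotypes, [0, 1] * 100)
            before = pool.allele_frequencies()[0]
            after = select_population(pool, cat, cfg, rng).allele_frequencies()[0]
            assert after >= before

    def test_empty_population_rejected(self, neutral_catalogue):
        with pytest.raises(ValueError, match="empty"):
            PopulationSample("UV", np.zeros((0, 5), dtype=np.uint8),
                             mating_types=np.zeros(0, dtype=np.uint8))

    def test_diploid_dominance_scaling(self, rng):
        # heterozygote with dominance 0 scores 0; with dominance 1 scores full
        for dom, expected in [(0.0, 0.0), (1.0, 1.0), (0.5, 0.5)]:
            cat = make_catalogue(n_loci=1, effects=[1.0], dominance=dom)
            pool = diploid_pool([[1]], [[0]])
            from gshuffle.simulate import population_fitness

            assert population_fitness(pool, cat) == pytest.approx(expected)


class TestMatePool:
    def test_single_pair_mates_exactly(self, rng):
        pool = haploid_pool([[1, 0], [0, 1]], [MATING_TYPE_A, MATING_TYPE_ALPHA])
        out = mate_pool(pool, rng)
        assert out.ploidy == 2 and out.n_members == 1
        haps = {tuple(out.genotypes[0, 0]), tuple(out.genotypes[0, 1])}
        assert haps == {(1, 0), (0, 1)}

    def test_hardy_weinberg_after_one_mating(self):
        # large panmictic pool at allele frequency p: genotypes p^2/2pq/q^2
        p, n = 0.4, 40_000
        rng = np.random.default_rng(7)
        genotypes = (rng.random((n, 1)) < p).astype(np.uint8)
        pool = haploid_pool(genotypes, [0, 1] * (n // 2))
        out = mate_pool(pool, rng)
        doses = out.allele_doses()[:, 0]
        n_dip = len(doses)
        for dose, expected in [(2, p * p), (1, 2 * p * (1 - p)), (0, (1 - p) ** 2)]:
            frac = (doses == dose).mean()
            se = np.sqrt(expected * (1 - expected) / n_dip)
            assert abs(frac - expected) < 3 * se + 0.01  # small slack: p estimated

    def test_single_mating_type_rejected(self, rng):
        pool = haploid_pool([[0], [1]], [MATING_TYPE_A, MATING_TYPE_A])
        with pytest.raises(ValueError, match="both mating types"):
            mate_pool(pool, rng)

    def test_surplus_majority_type_discarded(self, rng):
        pool = haploid_pool([[0]] * 7 + [[1]] * 3, [0] * 7 + [1] * 3)
        out = mate_pool(pool, rng)
        assert out.n_members == 3


class TestSporulatePool:
    def cfg(self, **kw):
        return SimulationConfig(seed=0, **kw)

    def test_mendelian_segregation_is_exact_per_tetrad(self, rng):
        cat = make_catalogue(n_loci=1)
        dip = diploid_pool([[1]] * 10_000, [[0]] * 10_000)
        spores = sporulate_pool(dip, cat, self.cfg(), rng)
        # every tetrad segregates 2:2
        per_tetrad = spores.genotypes.reshape(10_000, 4).sum(axis=1)
        assert (per_tetrad == 2).all()
        assert spores.allele_frequencies()[0] == pytest.approx(0.5)

    def test_haldane_recombinant_fraction_at_50cm(self):
        cat = make_catalogue(n_loci=2, spacing_cm=50.0)
        n = 10_000
        dip = diploid_pool([[1, 1]] * n, [[0, 0]] * n)  # cis double het
        rng = np.random.default_rng(3)
        spores = sporulate_pool(dip, cat, self.cfg(), rng)
        # one spore per independent crossover pattern
        patterns = spores.genotypes.reshape(n, 4, 2)[:, [0, 2], :].reshape(2 * n, 2)
        rec_frac = (patterns[:, 0] != patterns[:, 1]).mean()
        r = haldane_recombination_fraction(50.0)
        se = np.sqrt(r * (1 - r) / (2 * n))
        assert abs(rec_frac - r) < 3 * se
        assert r == pytest.approx((1 - np.exp(-1.0)) / 2)

    def test_independent_assortment_across_chromosomes(self):
        loci = [Locus("a", 1, 0.0, "A", "G"), Locus("b", 2, 0.0, "A", "G")]
        cat = LocusCatalogue(loci)
        n = 10_000
        dip = diploid_pool([[1, 1]] * n, [[0, 0]] * n)
        rng = np.random.default_rng(4)
        spores = sporulate_pool(dip, cat, self.cfg(), rng)
        patterns = spores.genotypes.reshape(n, 4, 2)[:, [0, 2], :].reshape(2 * n, 2)
        rec_frac = (patterns[:, 0] != patterns[:, 1]).mean()
        se = np.sqrt(0.25 / (2 * n))
        assert abs(rec_frac - 0.5) < 3 * se

    def test_haploid_input_rejected(self, neutral_catalogue, rng):
        pool = wild_type_pool(neutral_catalogue, 4)
        with pytest.raises(ValueError, match="diploid"):
            sporulate_pool(pool, neutral_catalogue, self.cfg(), rng)

    def test_tetrads_balance_mating_types(self, neutral_catalogue, rng):
        dip = diploid_pool([[1] * 5] * 3, [[0] * 5] * 3)
        spores = sporulate_pool(dip, neutral_catalogue, self.cfg(), rng)
        mt = spores.mating_types.reshape(3, 4)
        assert (mt.sum(axis=1) == 2).all()

    def test_selfing_probability_one_tags_every_tetrad(self, neutral_catalogue, rng):
        dip = diploid_pool([[1] * 5] * 5, [[0] * 5] * 5)
        spores = sporulate_pool(dip, neutral_catalogue,
                                self.cfg(selfing_probability=1.0), rng)
        assert (spores.meiosis_tags >= 0).all()
        # sister spores mate preferentially: every diploid is a selfing product
        out = mate_pool(spores, rng)
        assert out.n_members == 10
        tags = spores.meiosis_tags.reshape(5, 4)
        assert (tags == tags[:, :1]).all()


class TestRunGsRounds:
    def test_zero_rounds_returns_only_uv(self, neutral_catalogue, neutral_config):
        import dataclasses

        cfg = dataclasses.replace(neutral_config, rounds=0)
        samples = run_gs_rounds(cfg, neutral_catalogue)
        assert [s.round_label for s in samples] == ["UV"]
        assert samples[0].ploidy == 1

    def test_round_samples_are_diploid_and_labelled(self, neutral_catalogue, neutral_config):
        samples = run_gs_rounds(neutral_config, neutral_catalogue)
        assert [s.round_label for s in samples] == ["UV", "R1", "R2"]
        assert [s.ploidy for s in samples] == [1, 2, 2]

    def test_neutral_drift_conserves_expected_frequencies(self, neutral_catalogue):
        import dataclasses

        shifts = []
        for seed in range(200):
            cfg = SimulationConfig(
                population_size=300, uv_mutation_rate=1.0, founder_boost=0,
                selection_fraction=1.0, fitness_noise_sd=0.0,
                selfing_probability=0.0, rounds=2, seed=seed,
            )
            samples = run_gs_rounds(cfg, neutral_catalogue)
            shifts.append(
                samples[-1].allele_frequencies() - samples[0].allele_frequencies()
            )
        shifts = np.asarray(shifts)
        # mean over reps and loci should vanish; SE from observed spread
        se = shifts.std() / np.sqrt(shifts.size)
        assert abs(shifts.mean()) < 3 * se

    def test_determinism_bit_identical(self, neutral_catalogue, neutral_config):
        a = run_gs_rounds(neutral_config, neutral_catalogue)
        b = run_gs_rounds(neutral_config, neutral_catalogue)
        for sa, sb in zip(a, b):
            assert (sa.genotypes == sb.genotypes).all()
            assert sa.round_label == sb.round_label

    def test_linkage_decay_r2_non_increasing(self):
        """Mean r^2 between two neutral linked loci decays across rounds."""
        cat = make_catalogue(n_loci=2, spacing_cm=20.0)
        r2_by_round = []
        for seed in range(40):
            cfg = SimulationConfig(
                population_size=500, uv_mutation_rate=0.0, founder_boost=0,
                selection_fraction=1.0, fitness_noise_sd=0.0,
                selfing_probability=0.0, rounds=4, seed=seed,
            )
            rng = cfg.rng()
            uv = founder_pool(cat, cfg, ["L0", "L1"], 0.5, rng, background_rate=0.0)
            samples = run_gs_rounds(cfg, cat, rng=rng, initial_pool=uv)
            r2s = []
            for s in samples:
                if s.ploidy == 2:
                    haps = s.genotypes.reshape(-1, 2)
                else:
                    haps = s.genotypes
                with np.errstate(invalid="ignore"):
                    c = np.corrcoef(haps[:, 0], haps[:, 1])[0, 1]
                r2s.append(0.0 if np.isnan(c) else c * c)
            r2_by_round.append(r2s)
        mean_r2 = np.asarray(r2_by_round).mean(axis=0)
        assert mean_r2[0] > 0.9  # founder clone: near-perfect association
        assert all(mean_r2[i + 1] <= mean_r2[i] + 0.02 for i in range(len(mean_r2) - 1))
        assert mean_r2[-1] < mean_r2[0]


class TestAmpliconCounts:
    def test_monomorphic_pool_without_error_yields_zero_alt(self, neutral_catalogue, rng):
        pool = wild_type_pool(neutral_catalogue, 100)
        counts = simulate_amplicon_counts(pool, neutral_catalogue, 1000, 0.0, rng)
        assert (counts["alt_reads"] == 0).all()

    def test_binomial_sampling_error_at_half(self, neutral_catalogue, rng):
        genotypes = np.zeros((100, 5), dtype=np.uint8)
        genotypes[:50] = 1
        pool = haploid_pool(genotypes, [0, 1] * 50)
        counts = simulate_amplicon_counts(pool, neutral_catalogue, 1e5, 0.0, rng)
        f = counts["alt_reads"] / counts["total_reads"]
        assert (abs(f - 0.5) < 3 * np.sqrt(0.25 / 1e5)).all()

    def test_error_model_expected_false_positive_rate(self, neutral_catalogue):
        # p=0 with error e: expected alt fraction e/3
        pool = wild_type_pool(neutral_catalogue, 10)
        rng = np.random.default_rng(0)
        counts = simulate_amplicon_counts(pool, neutral_catalogue, 1e6, 0.003, rng)
        f = (counts["alt_reads"] / counts["total_reads"]).mean()
        se = np.sqrt(0.001 * 0.999 / 1e6 / 5)
        assert abs(f - 0.001) < 3 * se

    def test_nonpositive_coverage_rejected(self, neutral_catalogue, rng):
        pool = wild_type_pool(neutral_catalogue, 10)
        with pytest.raises(ValueError, match="mean_coverage"):
            simulate_amplicon_counts(pool, neutral_catalogue, 0, 0.0, rng)


class TestSimulateIsolates:
    def test_single_clone_population_all_homozygous(self, neutral_catalogue, rng):
        g = np.ones((10, 2, 5), dtype=np.uint8)
        pool = PopulationSample("R5", g)
        matrix = simulate_isolates(pool, neutral_catalogue, 5, 0.0, rng)
        assert (matrix.calls.to_numpy() == "homo").all()
        assert len(matrix.isolates) == 5

    def test_zero_isolates_rejected(self, neutral_catalogue, rng):
        pool = PopulationSample("R5", np.ones((10, 2, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="positive"):
            simulate_isolates(pool, neutral_catalogue, 0, 0.0, rng)

    def test_more_isolates_than_members_rejected(self, neutral_catalogue, rng):
        pool = PopulationSample("R5", np.ones((4, 2, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="cannot draw"):
            simulate_isolates(pool, neutral_catalogue, 5, 0.0, rng)

    def test_unbiased_draw_is_uniform(self, rng):
        """With fitness_bias 0 the isolate draw is uniform over members:
        chi-square goodness of fit across replicates not rejected."""
        from scipy.stats import chisquare

        cat = make_catalogue(n_loci=1, effects=[1.0])
        n_members = 10
        g = np.zeros((n_members, 2, 1), dtype=np.uint8)
        g[0] = 1  # one fit member that would dominate a biased draw
        pool = PopulationSample("R5", g)
        reps, homo = 2000, 0
        for _ in range(reps):
            m = simulate_isolates(pool, cat, 1, 0.0, rng)
            homo += m.calls.iloc[0, 0] == "homo"
        expected = reps / n_members  # member 0 is the only homozygote
        _, p = chisquare([homo, reps - homo], [expected, reps - expected])
        assert p > 0.01
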