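"""Continuous-space Wright-Fisher simulator: kernels, dispersal, dynamics."""

import dataclasses
import math

import numpy as np
import pytest

from driftscape import spacesim as sim

TINY = sim.SimConfig(N=150, n_sites=400, burnin_gens=5, lrd_gens=0, seed=1)


class TestKernels:
    def test_gaussian_kernel_values(self):
        k = sim.MATE_KERNEL
        assert k.value(0.0) == pytest.approx(1.0)
        assert k.value(0.1) == pytest.approx(math.exp(-12.5), rel=1e-9)
        assert k.value(0.11) == 0.0

    def test_competition_kernel_strength(self):
        k = sim.COMP_KERNEL
        assert k.value(0.0) == pytest.approx(3.0)
        assert k.value(0.31) == 0.0

    def test_invalid_kernel_rejected(self):
        with pytest.raises(sim.SimError):
            sim.KernelParams(0.1, 0.0, 0.02)


class TestInitPopulation:
    def test_no_initial_spatial_structure(self):
        cfg = dataclasses.replace(TINY, N=600, n_sites=2_000)
        state = sim.init_population(cfg)
        fst_max, fst_min = sim.fst_extremes(state, cfg)
        assert abs(fst_max) < 0.005 and abs(fst_min) < 0.005

    def test_site_frequency_spectrum_decreasing(self):
        cfg = dataclasses.replace(TINY, N=400, n_sites=5_000)
        state = sim.init_population(cfg)
        freq = state.genomes.sum(axis=(0, 1)) / (2 * cfg.N)
        hist, _ = np.histogram(freq, bins=np.linspace(0.01, 0.99, 11))
        from scipy.stats import spearmanr
        rho, _ = spearmanr(np.arange(len(hist)), hist)
        assert rho < 0

    def test_deterministic_under_seed(self):
        a = sim.init_population(TINY)
        b = sim.init_population(TINY)
        np.testing.assert_array_equal(a.genomes, b.genomes)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestMateChoiceAndCompetition:
    def test_out_of_range_individual_never_chosen(self):
        positions = np.array([[0.5, 0.5], [0.51, 0.5], [0.95, 0.95]])
        rng = np.random.default_rng(0)
        fathers = {sim.mate_choice(0, positions, rng=rng) for _ in range(50)}
        assert fathers == {1}

    def test_no_candidate_returns_none(self):
        positions = np.array([[0.1, 0.1], [0.9, 0.9]])
        assert sim.mate_choice(0, positions, rng=np.random.default_rng(0)) is None

    def test_isolated_individual_fitness(self):
        positions = np.array([[0.1, 0.1], [0.9, 0.9]])
        fitness = sim.competition_fitness(positions, N=2)
        np.testing.assert_allclose(fitness, [1.1, 1.1])

    def test_fitness_formula_at_known_competition(self):
        # two coincident individuals: competition = max_strength = 3.0 each
        positions = np.array([[0.5, 0.5], [0.5, 0.5]])
        fitness = sim.competition_fitness(positions, N=10)
        np.testing.assert_allclose(fitness, [1.1 - 0.3, 1.1 - 0.3])
        # fitness floors at zero once competition reaches 1.1 N; a whole
        # population at zero fitness is a configuration error
        crowd = np.tile([[0.5, 0.5]], (4, 1))
        with pytest.raises(sim.SimError):
            sim.competition_fitness(crowd, N=2)

    def test_density_doubling_doubles_competition(self):
        rng = np.random.default_rng(3)
        base = rng.random((150, 2)) * 0.2 + 0.4
        double = np.vstack([base, rng.random((150, 2)) * 0.2 + 0.4])
        comp_base = (1.1 - sim.competition_fitness(base, N=10_000)) * 10_000
        comp_double = (1.1 - sim.competition_fitness(double, N=10_000)) * 10_000
        ratio = comp_double[:150].mean() / comp_base.mean()
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestDisperse:
    def test_r99_closed_form(self):
        cfg = dataclasses.replace(TINY, sigma_disp=0.02)
        assert cfg.r99 == pytest.approx(0.060697, abs=1e-5)

    def test_base_dispersal_sd(self):
        cfg = dataclasses.replace(TINY, sigma_disp=0.02, p_lr=0.0)
        rng = np.random.default_rng(4)
        pts = np.full((100_000, 2), 0.5)
        out = sim.disperse(pts, cfg, rng)
        disp = out - 0.5
        assert disp.std(axis=0) == pytest.approx([0.02, 0.02], rel=0.05)

    def test_long_range_always_beyond_r99(self):
        cfg = dataclasses.replace(TINY, sigma_disp=0.02, sigma_lr=0.2, p_lr=1.0)
        rng = np.random.default_rng(5)
        pts = np.full((5_000, 2), 0.5)
        out = sim.disperse(pts, cfg, rng)
        # reflection can only shorten apparent displacement; use generous
        # margin by centring start away from boundaries
        d = np.linalg.norm(out - 0.5, axis=1)
        assert (d > cfg.r99 * 0.5).all()
        assert np.median(d) > cfg.r99

    def test_positions_stay_in_habitat(self):
        cfg = dataclasses.replace(TINY, sigma_disp=0.3, sigma_lr=0.9, p_lr=0.5)
        rng = np.random.default_rng(6)
        pts = rng.random((2_000, 2))
        out = sim.disperse(pts, cfg, rng)
        assert (out >= 0).all() and (out <= 1).all()


class TestStepGeneration:
    def test_population_size_conserved(self):
        state = sim.init_population(TINY)
        nxt = sim.step_generation(state, TINY)
        assert nxt.genomes.shape == state.genomes.shape
        assert nxt.positions.shape == (TINY.N, 2)
        assert nxt.generation == 1

    def test_no_mutation_no_recombination_copies_parents(self):
        cfg = dataclasses.replace(TINY, mu_per_site=0.0, r_per_bp=0.0)
        state = sim.init_population(cfg)
        parental = {h.tobytes() for ind in state.genomes for h in ind}
        nxt = sim.step_generation(state, cfg)
        for ind in nxt.genomes:
            for hap in ind:
                assert hap.tobytes() in parental

    def test_crossover_rate_matches_poisson_mean(self):
        cfg = dataclasses.replace(TINY, r_per_bp=2.5e-7, genome_length_bp=2e7)
        rng = np.random.default_rng(8)
        expected = cfg.r_per_bp * cfg.genome_length_bp
        k = rng.poisson(expected, size=10_000)
        assert k.mean() == pytest.approx(expected, rel=0.05)
        # and the transmission machinery consumes exactly that rate
        genomes = np.zeros((4, 2, 50), dtype=np.uint8)
        genomes[:, 1, :] = 1  # haplotype index readable from output
        site_pos = np.linspace(0, 2e7, 50, endpoint=False)
        g = sim._transmit(genomes, np.zeros(4_000, dtype=np.int64), site_pos,
                          cfg.genome_length_bp, cfg.r_per_bp, rng)
        switches = (np.abs(np.diff(g.astype(int), axis=1)) == 1).sum(axis=1)
        # switches per meiosis <= crossovers; mean within a factor reflecting
        # multiple crossovers between adjacent sites
        assert 0.5 * expected < switches.mean() <= expected * 1.05


class TestTrendTest:
    def test_mann_kendall_detects_monotone_decline(self):
        y = np.linspace(1.0, 0.0, 15)
        _, p = sim.mann_kendall(y, "decreasing")
        assert p < 1e-4

    def test_mann_kendall_flat_not_significant(self):
        rng = np.random.default_rng(10)
        y = rng.normal(0, 1, 15)
        _, p = sim.mann_kendall(y, "decreasing")
        assert p > 0.05


class TestRunSimulation:
    def test_fixed_seed_identical_trajectory(self):
        cfg = dataclasses.replace(TINY, burnin_gens=4, lrd_gens=3, record_every=1)
        a = sim.run_simulation(cfg)
        b = sim.run_simulation(cfg)
        assert a.summary.equals(b.summary)
        np.testing.assert_array_equal(a.final_state.genomes, b.final_state.genomes)

    def test_isolation_by_distance_established(self):
        cfg = sim.SimConfig(N=500, n_sites=1_500, sigma_disp=0.08,
                            burnin_gens=200, lrd_gens=0, seed=9)
        res = sim.run_simulation(cfg)
        bands = sim.grid_fst_table(res.final_state, cfg)
        band_max, band_min = sim.fst_extremes(bands)
        assert band_max > 10 * band_min
        from scipy.stats import spearmanr
        rho, _ = spearmanr(bands["mean_dist"], bands["fst"])
        assert rho > 0.8

    def test_export_genotypes_shapes_and_metadata(self):
        res = sim.run_simulation(TINY)
        matrix, meta = sim.export_genotypes(res.final_state, TINY)
        assert matrix.ploidy_mode == "diploid"
        assert matrix.n_samples == TINY.N
        freqs = matrix.calls.mean(axis=1) / 2
        assert (np.minimum(freqs, 1 - freqs) >= TINY.maf_min).all()
        assert set(meta["id"]) == set(matrix.samples)
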