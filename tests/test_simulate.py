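"""Wright-Fisher simulator: drift moments, crossover process, plan-II
sampling and determinism."""

import numpy as np
import pytest

from templink import (
    SimConfig,
    TwoLocusState,
    sample_plan_ii,
    simulate_chromosome,
    simulate_two_locus,
    simulated_pair_c,
    step_two_locus,
    unphase,
)
from templink.simulate import _gamete_freqs, _interval_intensities, _next_generation, run_replicate_study


class TestTwoLocusStep:
    def test_recombination_noop_at_linkage_equilibrium(self):
        state = TwoLocusState.from_freqs(0.4, 0.6, 0.0).as_array()
        assert np.allclose(_gamete_freqs(state, 0.3), state)

    def test_c_zero_keeps_gamete_freqs(self):
        state = TwoLocusState.from_freqs(0.4, 0.6, 0.1).as_array()
        assert np.allclose(_gamete_freqs(state, 0.0), state)

    def test_recombination_moves_toward_equilibrium(self):
        state = TwoLocusState.from_freqs(0.5, 0.5, 0.1)
        gam = _gamete_freqs(state.as_array(), 0.5)
        d_new = gam[0] * gam[3] - gam[1] * gam[2]
        assert abs(d_new) == pytest.approx(0.05, abs=1e-12)

    def test_martingale(self, rng):
        """Allele frequency is a martingale under drift."""
        reps = 20_000
        state = np.broadcast_to(
            TwoLocusState.from_freqs(0.3, 0.5, 0.05).as_array(), (reps, 4)
        ).copy()
        for _ in range(5):
            state = step_two_locus(state, 0.1, 200, rng)
        p_i = state[:, 0] + state[:, 1]
        se = p_i.std(ddof=1) / np.sqrt(reps)
        assert abs(p_i.mean() - 0.3) < 3 * se

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            TwoLocusState(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            TwoLocusState.from_freqs(0.1, 0.1, 0.5)


class TestTwoLocusOracle:
    """Scaled-down oracle runs; the full-strength comparison against the
    closed forms lives in the acceptance suite."""

    def test_t_zero_no_covariance(self):
        out = simulate_two_locus(TwoLocusState.from_freqs(0.5, 0.5, 0.05), 0.1, 500, 0, 100, seed=1)
        p_i = out[:, 0] + out[:, 1]
        assert np.all(p_i == p_i[0])

    def test_unlinked_equilibrium_no_covariance(self):
        out = simulate_two_locus(
            TwoLocusState.from_freqs(0.5, 0.5, 0.0), 0.5, 200, 5, 30_000, seed=2
        )
        p_i = out[:, 0] + out[:, 1]
        p_j = out[:, 0] + out[:, 2]
        cov = np.cov(p_i, p_j)[0, 1]
        prod_var = p_i.var() * p_j.var()
        se = np.sqrt(prod_var / 30_000) + 1e-6
        assert abs(cov) < 4 * se

    def test_d_decay_matches_formula_small(self):
        from templink import expected_d_decay

        out = simulate_two_locus(
            TwoLocusState.from_freqs(0.5, 0.5, 0.05), 0.01, 1000, 10, 30_000, seed=3
        )
        d = out[:, 0] * out[:, 3] - out[:, 1] * out[:, 2]
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - expected_d_decay(0.05, 0.01, 1000, 10)) < 3 * se


class TestCrossoverProcess:
    def test_pairwise_switch_probability(self):
        """The probability of an odd number of crossovers between two
        markers equals the geometric compounding of the per-bp rate."""
        positions = np.array([1, 2_000, 30_000, 100_000])
        per_bp = 1e-5
        cum_d = _interval_intensities(positions, per_bp)
        n = 4000
        # population of two distinguishable haplotype types
        hap = np.zeros((n, len(positions)), dtype=np.uint8)
        hap[n // 2 :] = 1
        rng = np.random.default_rng(99)
        diff_counts = np.zeros(len(positions) - 1)
        reps = 60
        for _ in range(reps):
            out = _next_generation(hap, cum_d, rng)
            diff_counts += (out[:, :-1] != out[:, 1:]).mean(axis=0)
        # switches observable only when the two parents differ (prob 1/2)
        observed_c = 2 * diff_counts / reps
        expected = simulated_pair_c(np.diff(positions), per_bp)
        se = 2 * np.sqrt(expected * (1 - expected) / (n * reps / 2))
        assert np.all(np.abs(observed_c - expected) < 3 * se + 1e-4)

    def test_no_recombination_preserves_haplotypes(self):
        hap = np.array([[0, 0, 0], [1, 1, 1]] * 50, dtype=np.uint8)
        cum_d = np.zeros(2)
        out = _next_generation(hap, cum_d, np.random.default_rng(1))
        assert set(map(tuple, out)) <= {(0, 0, 0), (1, 1, 1)}


class TestChromosomeSim:
    def test_shapes_and_retention(self, tiny_sim):
        assert tiny_sim.hap0.shape == (2 * tiny_sim.config.ne, tiny_sim.k)
        assert tiny_sim.hap_t.shape == tiny_sim.hap0.shape
        assert tiny_sim.k <= tiny_sim.config.k_target
        assert np.all(np.diff(tiny_sim.positions) > 0)
        # retained loci pass the population MAF threshold at generation 0
        maf0 = np.minimum(tiny_sim.p0, 1 - tiny_sim.p0)
        assert np.all(maf0 >= tiny_sim.config.maf)

    def test_mean_frequency_roughly_conserved(self, tiny_sim):
        """Drift is directionless: the mean frequency change across loci is
        small relative to the per-locus drift scale."""
        delta = tiny_sim.p_t - tiny_sim.p0
        scale = delta.std(ddof=1) / np.sqrt(tiny_sim.k)
        # linked loci are correlated, so allow a generous factor
        assert abs(delta.mean()) < 6 * scale + 0.01

    def test_deterministic_given_seed(self):
        cfg = SimConfig(ne=100, length_bp=5000, k_target=20, k_init=60, burn_in=30, t=3,
                        s0=10, st=10, seed=5, initialization="forward")
        a = simulate_chromosome(cfg)
        b = simulate_chromosome(cfg)
        assert np.array_equal(a.hap0, b.hap0)
        assert np.array_equal(a.hap_t, b.hap_t)
        assert np.array_equal(a.positions, b.positions)

    def test_coalescent_initialization(self):
        """Default initialization draws the whole population from the
        coalescent at mutation-drift-recombination equilibrium."""
        cfg = SimConfig(ne=150, length_bp=30_000, k_target=40, t=5, s0=20, st=20,
                        mu=5e-6, seed=13)
        sim = simulate_chromosome(cfg)
        assert sim.hap0.shape == (300, sim.k)
        assert 1 <= sim.k <= 40
        maf0 = np.minimum(sim.p0, 1 - sim.p0)
        assert np.all(maf0 >= cfg.maf)
        # deterministic under the same seed
        sim2 = simulate_chromosome(cfg)
        assert np.array_equal(sim.hap_t, sim2.hap_t)

    def test_coalescent_has_baseline_ld(self):
        """Equilibrium initialization carries LD decaying with distance."""
        cfg = SimConfig(seed=29)
        sim = simulate_chromosome(cfg)
        r = np.corrcoef(sim.hap0.astype(float), rowvar=False)
        d = np.abs(sim.positions[:, None] - sim.positions[None, :])
        iu = np.triu_indices(sim.k, 1)
        r2, dd = r[iu] ** 2, d[iu]
        assert np.mean(r2[dd < 2000]) > 2 * np.mean(r2[dd > 20_000])

    def test_tight_linkage_raises_r2(self):
        """With zero recombination, LD after burn-in is much higher than
        with free-ish recombination."""
        base = dict(ne=100, length_bp=10_000, k_target=30, k_init=100, burn_in=150,
                    t=1, s0=20, st=20, mu=1e-5, initialization="forward")
        rng = np.random.default_rng(21)
        linked = simulate_chromosome(SimConfig(per_bp_rate=0.0, **base), rng=rng)
        free = simulate_chromosome(SimConfig(per_bp_rate=1e-3, **base), rng=rng)

        def mean_r2(sim):
            r = np.corrcoef(sim.hap0.astype(float), rowvar=False)
            iu = np.triu_indices(sim.k, 1)
            return np.nanmean(r[iu] ** 2)

        assert mean_r2(linked) > 3 * mean_r2(free)


class TestSampling:
    def test_plan_ii_unbiased(self, tiny_sim, rng):
        reps = 200
        err = np.zeros(tiny_sim.k)
        for _ in range(reps):
            samp = sample_plan_ii(tiny_sim.hap0, tiny_sim.config.s0, rng)
            err += samp.mean(axis=0) - tiny_sim.p0
        err /= reps
        s = tiny_sim.config.s0
        se = np.sqrt(0.25 / (2 * s * reps))
        assert np.all(np.abs(err) < 4 * se)

    def test_population_untouched(self, tiny_sim, rng):
        before = tiny_sim.hap0.copy()
        sample_plan_ii(tiny_sim.hap0, 10, rng)
        assert np.array_equal(before, tiny_sim.hap0)

    def test_unphase_preserves_frequencies(self, tiny_sim, rng):
        samp = sample_plan_ii(tiny_sim.hap0, 20, rng)
        geno = unphase(samp, rng)
        assert geno.shape == (20, tiny_sim.k)
        assert np.allclose(geno.mean(axis=0) / 2, samp.mean(axis=0))
        assert geno.min() >= 0 and geno.max() <= 2

    def test_unphase_rejects_odd(self, rng):
        with pytest.raises(ValueError):
            unphase(np.zeros((5, 3), dtype=np.uint8), rng)


class TestReplicateStudy:
    def test_single_replicate_coverage_binary(self):
        cfg = SimConfig(ne=100, length_bp=10_000, k_target=40, k_init=120, burn_in=50,
                        t=5, s0=25, st=25, initialization="forward")
        study = run_replicate_study(cfg, n_reps=1, n_draws=2000, seed=4)
        s = study["summary"]["phased"]
        assert s["coverage_adjusted"] in (0.0, 1.0)
        assert s["coverage_chisq"] in (0.0, 1.0)
        assert study["table"].shape[0] == 1

    def test_phased_and_unphased_paths(self):
        cfg = SimConfig(ne=100, length_bp=10_000, k_target=30, k_init=100, burn_in=50,
                        t=5, s0=25, st=25, initialization="forward")
        study = run_replicate_study(cfg, n_reps=2, n_draws=2000, seed=6, unphased=True)
        assert set(study["summary"]) >= {"phased", "unphased"}
        assert study["table"].shape[0] == 4

    def test_reproducible(self):
        cfg = SimConfig(ne=80, length_bp=8000, k_target=25, k_init=80, burn_in=40,
                        t=4, s0=20, st=20, initialization="forward")
        a = run_replicate_study(cfg, n_reps=2, n_draws=1500, seed=9)["table"]
        b = run_replicate_study(cfg, n_reps=2, n_draws=1500, seed=9)["table"]
        assert a.equals(b)
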