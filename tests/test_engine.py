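"""Engine: period loop, burn-in, full runs, replicates."""

from dataclasses import replace

import numpy as np
import pytest

from matesim import (
    FEMALE,
    MALE,
    LifeTables,
    LocusSpec,
    Population,
    SimConfig,
    build_matrix,
    burn_in,
    init_population,
    matrix_in_force,
    run,
    run_replicates,
    run_to_absorption,
    step,
)
from matesim.engine import _end_state_curves
from matesim.io import make_fixture


def toy_config(**overrides):
    pop, config = make_fixture("tiny_pop", seed=overrides.pop("seed", 0))
    return replace(config, **overrides)


class TestInit:
    def test_starts_mutation_free_and_at_census(self):
        config = toy_config(N=50)
        pop = init_population(config, np.random.default_rng(3))
        assert pop.n_per_sex == (50, 50)
        assert (pop.allele_frequencies() == 0).all()
        assert all(1 <= a.min() and a.max() <= 6 for a in pop.ages)

    def test_same_seed_same_population(self):
        config = toy_config(N=30)
        a = init_population(config, np.random.default_rng(9))
        b = init_population(config, np.random.default_rng(9))
        assert all(np.array_equal(a.ages[s], b.ages[s]) for s in (MALE, FEMALE))
        assert all(np.array_equal(a.geno[s], b.geno[s]) for s in (MALE, FEMALE))

    def test_rejects_tiny_population(self):
        with pytest.raises(ValueError):
            toy_config(N=1)

    def test_initial_frequency_assignment(self):
        config = toy_config(
            N=2000,
            loci=[LocusSpec(1, "mortality", "both", 5, mu=0.0, init_freq=0.5)],
        )
        pop = init_population(config, np.random.default_rng(5))
        assert abs(pop.allele_frequencies().mean() - 0.5) < 0.03


def immortal_until_terminal_config(n_terminal):
    """6-class tables with survival 1 below the final class, so the only
    deaths each period are the forced terminal-class ones."""
    surv = np.ones((2, 6))
    surv[:, -1] = 0.0
    fert = np.zeros((2, 6))
    fert[:, 1:5] = 1.0
    tables = LifeTables(surv, fert)
    config = SimConfig(
        N=40,
        loci=[LocusSpec(1, "mortality", "both", 5, e=0.0, mu=0.0)],
        tables=tables,
        matrix=build_matrix("AP", young_min=2, young_max=4, adult_min=3, n_classes=6),
        n_periods=5,
        burn_in=0,
        seed=1,
    )
    rng = np.random.default_rng(2)
    pop = init_population(config, rng)
    # place a known number of individuals in the terminal class
    for sex in (MALE, FEMALE):
        pop.ages[sex][:] = 3
        pop.ages[sex][:n_terminal] = 6
    return pop, config, rng


class TestStep:
    def test_terminal_deaths_exactly_replaced(self):
        k = 7
        pop, config, rng = immortal_until_terminal_config(k)
        step(pop, config, rng)
        assert pop.n_per_sex == (40, 40)
        # exactly k newborns per sex, all in class 1
        for sex in (MALE, FEMALE):
            assert (pop.ages[sex] == 1).sum() == k
            assert pop.ages[sex].max() <= 6

    def test_census_and_age_bounds_hold_every_period(self):
        config = toy_config(N=25, seed=4)
        rng = np.random.default_rng(4)
        pop = init_population(config, rng)
        for _ in range(200):
            step(pop, config, rng)
            assert pop.n_per_sex == (25, 25)
            for sex in (MALE, FEMALE):
                assert pop.ages[sex].min() >= 1
                assert pop.ages[sex].max() <= 6

    def test_no_mutation_stays_wild_type(self):
        config = toy_config(
            N=30, loci=[LocusSpec(1, "mortality", "both", 5, e=0.1, mu=0.0)]
        )
        rng = np.random.default_rng(7)
        pop = init_population(config, rng)
        for _ in range(50):
            step(pop, config, rng)
        assert (pop.allele_frequencies() == 0).all()


class TestBurnIn:
    def test_zero_burn_in_is_identity(self):
        config = toy_config(N=20, burn_in=0)
        rng = np.random.default_rng(1)
        pop = init_population(config, rng)
        before = pop.copy()
        burn_in(pop, config, rng)
        assert all(np.array_equal(before.ages[s], pop.ages[s]) for s in (MALE, FEMALE))

    def test_burn_in_introduces_no_mutations(self):
        config = toy_config(N=50, burn_in=80)
        rng = np.random.default_rng(2)
        pop = burn_in(init_population(config, rng), config, rng)
        assert (pop.allele_frequencies() == 0).all()

    def test_age_distribution_roughly_stationary_after_burn_in(self):
        """Class-1 occupancy fluctuates around a stable level once burnt in."""
        config = toy_config(N=400, burn_in=150)
        rng = np.random.default_rng(11)
        pop = burn_in(init_population(config, rng), config, rng)
        windows = []
        for _ in range(2):
            fracs = []
            for _ in range(40):
                step(pop, config, rng, mutation=False)
                fracs.append((pop.ages[FEMALE] == 1).mean())
            windows.append(np.mean(fracs))
        # successive 40-period window means agree within binomial noise
        se = np.sqrt(0.25 / (400 * 40))
        assert abs(windows[0] - windows[1]) < 6 * se + 0.01


class TestRun:
    def test_identical_seeds_identical_results(self):
        config = toy_config(N=30, n_periods=60, burn_in=20, seed=12)
        a, b = run(config), run(config)
        assert np.array_equal(a.freq, b.freq)
        assert np.array_equal(
            np.nan_to_num(a.end_survivorship), np.nan_to_num(b.end_survivorship)
        )

    def test_single_period_run_equals_manual_step(self):
        config = toy_config(N=30, n_periods=1, burn_in=15, seed=21)
        result = run(config)
        rng = np.random.default_rng(21)
        pop = init_population(config, rng)
        burn_in(pop, config, rng)
        step(pop, config, rng)
        assert np.array_equal(result.final_freqs, pop.allele_frequencies())
        surv, fert = _end_state_curves(pop, config, config.locus_arrays())
        assert np.array_equal(
            np.nan_to_num(result.end_survivorship), np.nan_to_num(surv)
        )

    def test_matrix_shift_timing(self):
        yf = build_matrix("YF", young_min=2, young_max=4, n_classes=6)
        config = toy_config(n_periods=2000, shift=(1000, yf))
        assert matrix_in_force(config, 999) is config.matrix
        assert matrix_in_force(config, 1000) is yf
        assert matrix_in_force(config, 1500) is yf

    def test_shift_validation(self):
        yf = build_matrix("YF", young_min=2, young_max=4, n_classes=6)
        with pytest.raises(ValueError):
            toy_config(n_periods=100, shift=(100, yf))


class TestReplicates:
    def test_summary_mean_is_mean_of_replicates(self):
        config = toy_config(N=30, n_periods=40, burn_in=10)
        summary = run_replicates(config, 4, seed_base=100)
        finals = np.stack([r.final_freqs for r in summary.results])
        assert np.allclose(summary.mean, finals.mean(axis=0))
        assert summary.results[0].seed == 100
        assert summary.results[3].seed == 103

    def test_locus_fixed_in_every_replicate_has_zero_se(self):
        config = toy_config(
            N=20,
            n_periods=30,
            burn_in=10,
            loci=[LocusSpec(1, "mortality", "both", 6, e=0.0, mu=0.0, init_freq=1.0)],
        )
        summary = run_replicates(config, 3, seed_base=7)
        assert (summary.mean == 1.0).all()
        assert (summary.se == 0.0).all()

    def test_single_replicate_se_is_nan(self):
        config = toy_config(N=20, n_periods=20, burn_in=5)
        summary = run_replicates(config, 1)
        assert np.isnan(summary.se).all()


def test_run_to_absorption_neutral_locus():
    config = toy_config(
        N=20,
        burn_in=20,
        loci=[LocusSpec(1, "mortality", "both", 6, e=0.9, mu=0.0, init_freq=0.5)],
        matrix=build_matrix("YP", young_min=2, young_max=5, n_classes=6),
        seed=42,
    )
    fixed, periods = run_to_absorption(config, max_periods=50_000)
    assert fixed in (0.0, 1.0)
    assert periods < 50_000
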