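"""Simulation engine: the period loop, burn-in, full runs and replicates.

Each period (representing five years):

1. every individual draws survival from its effective survival probability
   (intrinsic table times expressed mortality load); survivors advance one
   age class, the final class always dies;
2. deaths are counted per sex and replaced by exactly that many newborns,
   so the census stays at N males and N females; each newborn's parents are
   drawn from the *surviving* pools through the mating-matrix birth loop,
   alleles are transmitted Mendelianly and new mutations introduced;
3. newborns enter age class 1 and neither die nor reproduce in their birth
   period.

A mutation-free burn-in first lets the age distribution reach an
approximate steady state; allele dynamics then start from the configured
initial frequencies (zero by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genetics import (
    FEMALE,
    MALE,
    MUTATION_MODELS,
    Individual,
    LocusArrays,
    LocusSpec,
    locus_arrays,
    mutate_gametes,
    transmit_gametes,
)
from .life_tables import LifeTables, load_multiplier
from .mating import MatingMatrix, draw_parent_pairs

__all__ = [
    "Population",
    "SimConfig",
    "SimResult",
    "ReplicateSummary",
    "init_population",
    "step",
    "burn_in",
    "run",
    "run_replicates",
    "run_to_absorption",
    "matrix_in_force",
]


@dataclass
class Population:
    """Array-packed population state: per-sex age classes and genotypes.

    ``ages[sex]`` is an int vector of length N (1-based age classes);
    ``geno[sex]`` is a ``(N, L)`` uint8 array of mutant-allele counts.
    """

    ages: list[np.ndarray]
    geno: list[np.ndarray]
    period: int = 0

    @property
    def n_per_sex(self) -> tuple[int, int]:
        return len(self.ages[MALE]), len(self.ages[FEMALE])

    def allele_frequencies(self) -> np.ndarray:
        """Mutant-allele frequency per locus and sex, shape ``(L, 2)``."""
        return np.stack(
            [self.geno[MALE].mean(axis=0) / 2.0, self.geno[FEMALE].mean(axis=0) / 2.0],
            axis=1,
        )

    def copy(self) -> "Population":
        return Population(
            [a.copy() for a in self.ages], [g.copy() for g in self.geno], self.period
        )

    def to_individuals(self, sex: int) -> list[Individual]:
        return [
            Individual(sex, int(a), g.copy())
            for a, g in zip(self.ages[sex], self.geno[sex])
        ]


@dataclass
class SimConfig:
    """Everything a single run needs.

    ``shift`` optionally replaces the mating matrix part-way through:
    ``(period, new_matrix)`` means periods ``0 .. period-1`` use ``matrix``
    and periods ``period`` onward use ``new_matrix``.
    """

    N: int
    loci: list[LocusSpec]
    tables: LifeTables
    matrix: MatingMatrix
    n_periods: int = 10000
    burn_in: int = 200
    seed: int = 0
    shift: tuple[int, MatingMatrix] | None = None
    mutation_model: str = "per_copy"
    max_attempts: int = 1_000_000
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2 per sex")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.mutation_model not in MUTATION_MODELS:
            raise ValueError(f"mutation_model must be one of {MUTATION_MODELS}")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        n = self.tables.n_classes
        if self.matrix.n_classes != n:
            raise ValueError(
                f"matrix is {self.matrix.n_classes}x{self.matrix.n_classes} "
                f"but tables have {n} age classes"
            )
        for l in self.loci:
            if l.onset_class > n:
                raise ValueError(
                    f"locus {l.id}: onset_class {l.onset_class} exceeds the "
                    f"{n} age classes"
                )
        if self.shift is not None:
            t, m = self.shift
            if not (0 <= t < self.n_periods):
                raise ValueError("shift period must lie in [0, n_periods)")
            if m.n_classes != n:
                raise ValueError("shift matrix must match the number of age classes")

    @property
    def n_classes(self) -> int:
        return self.tables.n_classes

    def locus_arrays(self) -> LocusArrays:
        return locus_arrays(self.loci)


@dataclass
class SimResult:
    """Output of one run.

    ``freq`` has shape ``(n_records, L, 2)``: mutant-allele frequency per
    recorded period (``periods`` gives the period index of each row; row 0
    is the post-burn-in initial state), locus and sex.  The end-state curves
    hold, per sex and age class, the mean effective survival and fertility
    of the individuals present at simulation end (NaN for empty classes).
    """

    periods: np.ndarray
    freq: np.ndarray
    end_survivorship: np.ndarray
    end_fertility: np.ndarray
    seed: int

    @property
    def final_freqs(self) -> np.ndarray:
        """Final mutant-allele frequencies, shape ``(L, 2)``."""
        return self.freq[-1]


@dataclass
class ReplicateSummary:
    """Replicate-averaged final frequencies: mean and standard error.

    ``mean``/``se`` have shape ``(L, 2)`` (locus x sex); the standard error
    is sd/sqrt(n_reps) with ddof=1 and is NaN for a single replicate.
    """

    results: list[SimResult]
    mean: np.ndarray
    se: np.ndarray

    @property
    def n_reps(self) -> int:
        return len(self.results)


def matrix_in_force(config: SimConfig, period: int) -> MatingMatrix:
    """The mating matrix the engine applies at a given (0-based) period."""
    if config.shift is not None and period >= config.shift[0]:
        return config.shift[1]
    return config.matrix


def init_population(config: SimConfig, rng: np.random.Generator) -> Population:
    """Uniform-random age classes, genotypes drawn at each locus's
    ``init_freq`` (all wild type by default)."""
    la = config.locus_arrays()
    ages, geno = [], []
    for _ in (MALE, FEMALE):
        ages.append(rng.integers(1, config.n_classes + 1, config.N).astype(np.int64))
        if la.n_loci and la.init_freq.any():
            g = (
                (rng.random((config.N, la.n_loci)) < la.init_freq).astype(np.uint8)
                + (rng.random((config.N, la.n_loci)) < la.init_freq).astype(np.uint8)
            )
        else:
            g = np.zeros((config.N, la.n_loci), dtype=np.uint8)
        geno.append(g)
    return Population(ages, geno, period=0)


def _step_arrays(
    pop: Population,
    config: SimConfig,
    la: LocusArrays,
    matrix: MatingMatrix,
    rng: np.random.Generator,
    mutation: bool,
) -> None:
    tables = config.tables
    surv_ages: list[np.ndarray] = []
    surv_geno: list[np.ndarray] = []
    deaths: list[int] = []
    for sex in (MALE, FEMALE):
        ages, geno = pop.ages[sex], pop.geno[sex]
        base = tables.survival[sex, ages - 1]
        mult = load_multiplier(ages, geno, sex, la, la.mortality)
        alive = rng.random(len(ages)) < base * mult
        surv_ages.append(ages[alive] + 1)
        surv_geno.append(geno[alive])
        deaths.append(int(len(ages) - alive.sum()))

    k_m, k_f = deaths
    k_tot = k_m + k_f
    if k_tot:
        fert = [
            tables.fertility[sex, surv_ages[sex] - 1]
            * load_multiplier(surv_ages[sex], surv_geno[sex], sex, la, la.fertility)
            for sex in (MALE, FEMALE)
        ]
        fathers, mothers = draw_parent_pairs(
            k_tot,
            surv_ages[MALE],
            surv_ages[FEMALE],
            fert[MALE],
            fert[FEMALE],
            matrix,
            rng,
            config.max_attempts,
        )
        paternal = transmit_gametes(surv_geno[MALE][fathers], rng)
        maternal = transmit_gametes(surv_geno[FEMALE][mothers], rng)
        if mutation:
            newborn = mutate_gametes(paternal, maternal, la, rng, config.mutation_model)
        else:
            newborn = (paternal + maternal).astype(np.uint8)
    else:
        newborn = np.zeros((0, la.n_loci), dtype=np.uint8)

    split = (slice(0, k_m), slice(k_m, k_tot))
    for sex, k in ((MALE, k_m), (FEMALE, k_f)):
        pop.ages[sex] = np.concatenate(
            [surv_ages[sex], np.ones(k, dtype=np.int64)]
        )
        pop.geno[sex] = np.concatenate([surv_geno[sex], newborn[split[sex]]], axis=0)
    pop.period += 1


def step(
    pop: Population,
    config: SimConfig,
    rng: np.random.Generator,
    mutation: bool = True,
    matrix: MatingMatrix | None = None,
) -> Population:
    """Advance the population by one period in place (and return it)."""
    la = config.locus_arrays()
    _step_arrays(pop, config, la, matrix or config.matrix, rng, mutation)
    return pop


def burn_in(
    pop: Population, config: SimConfig, rng: np.random.Generator
) -> Population:
    """Run ``config.burn_in`` periods with mutation disabled, bringing the
    age distribution to an approximate steady state."""
    la = config.locus_arrays()
    for _ in range(config.burn_in):
        _step_arrays(pop, config, la, config.matrix, rng, mutation=False)
    return pop


def _end_state_curves(
    pop: Population, config: SimConfig, la: LocusArrays
) -> tuple[np.ndarray, np.ndarray]:
    n = config.n_classes
    surv = np.full((2, n), np.nan)
    fert = np.full((2, n), np.nan)
    for sex in (MALE, FEMALE):
        ages, geno = pop.ages[sex], pop.geno[sex]
        s = config.tables.survival[sex, ages - 1] * load_multiplier(
            ages, geno, sex, la, la.mortality
        )
        f = config.tables.fertility[sex, ages - 1] * load_multiplier(
            ages, geno, sex, la, la.fertility
        )
        for c in range(1, n + 1):
            m = ages == c
            if m.any():
                surv[sex, c - 1] = s[m].mean()
                fert[sex, c - 1] = f[m].mean()
    return surv, fert


def run(config: SimConfig) -> SimResult:
    """Initialise, burn in, and run ``n_periods`` periods.

    All randomness flows through one generator seeded from ``config.seed``,
    so identical configurations give bit-identical results.
    """
    rng = np.random.default_rng(config.seed)
    la = config.locus_arrays()
    pop = init_population(config, rng)
    burn_in(pop, config, rng)

    rec_periods = [0]
    rec_freq = [pop.allele_frequencies()]
    for t in range(config.n_periods):
        _step_arrays(pop, config, la, matrix_in_force(config, t), rng, mutation=True)
        if (t + 1) % config.record_every == 0 or t == config.n_periods - 1:
            rec_periods.append(t + 1)
            rec_freq.append(pop.allele_frequencies())

    surv, fert = _end_state_curves(pop, config, la)
    return SimResult(
        periods=np.array(rec_periods),
        freq=np.array(rec_freq),
        end_survivorship=surv,
        end_fertility=fert,
        seed=config.seed,
    )


def run_replicates(
    config: SimConfig, n_reps: int, seed_base: int | None = None
) -> ReplicateSummary:
    """Independent replicates with seeds ``seed_base + r``; summarises the
    final-period frequencies with their mean and standard error."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if seed_base is None:
        seed_base = config.seed
    results = [replace(config, seed=seed_base + r) for r in range(n_reps)]
    results = [run(c) for c in results]
    finals = np.stack([r.final_freqs for r in results])  # (reps, L, 2)
    mean = finals.mean(axis=0)
    if n_reps > 1:
        se = finals.std(axis=0, ddof=1) / np.sqrt(n_reps)
    else:
        se = np.full_like(mean, np.nan)
    return ReplicateSummary(results=results, mean=mean, se=se)


def run_to_absorption(
    config: SimConfig, max_periods: int = 100_000
) -> tuple[float, int]:
    """Run until every locus is lost or fixed in the whole population.

    Returns ``(mean final frequency across loci, periods elapsed)``.  Used
    for drift checks on selection-free loci; absorption is only guaranteed
    when mutation cannot reintroduce variation (mu = 0).
    """
    rng = np.random.default_rng(config.seed)
    la = config.locus_arrays()
    pop = init_population(config, rng)
    burn_in(pop, config, rng)
    for t in range(max_periods):
        counts = pop.geno[MALE].sum(axis=0) + pop.geno[FEMALE].sum(axis=0)
        total = 4 * config.N
        if np.all((counts == 0) | (counts == total)):
            return float(np.mean(counts == total)), t
        _step_arrays(pop, config, la, matrix_in_force(config, t), rng, True)
    raise RuntimeError(f"not absorbed after {max_periods} periods")
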