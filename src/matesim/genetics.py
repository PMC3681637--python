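"""Diploid genetics: locus definitions, Mendelian transmission, mutation at birth.

Genotypes are stored as mutant-allele counts (0, 1 or 2) per locus.  Loci are
autosomal, biallelic and unlinked: each locus transmits independently, which
is equivalent to free recombination.  Mutation is unidirectional (wild type
to mutant); a mutant allele never reverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "SEX_NAMES",
    "EFFECTS",
    "SCOPES",
    "LocusSpec",
    "Individual",
    "locus_arrays",
    "transmit_gamete",
    "transmit_gametes",
    "mutate_newborn",
    "mutate_gametes",
]

#: Integer sex codes used throughout the package (array row indices).
MALE, FEMALE = 0, 1
SEX_NAMES = ("male", "female")

EFFECTS = ("mortality", "fertility")
SCOPES = ("both", "male_only", "female_only")

#: Supported mutation conventions.  ``per_copy`` applies the rate mu
#: independently to each of the two allele copies of every newborn;
#: ``per_diploid`` applies mu once per locus per newborn (at most one new
#: mutant copy per birth).
MUTATION_MODELS = ("per_copy", "per_diploid")


@dataclass
class LocusSpec:
    """One mutable locus.

    Parameters
    ----------
    id : int
        Small integer label, unique within a locus set.
    effect : {"mortality", "fertility"}
        Which vital rate the mutant allele degrades.
    scope : {"both", "male_only", "female_only"}
        Which sex expresses the mutant allele.
    onset_class : int
        Age class (1-based) at and beyond which the allele is expressed.
    e : float
        Selection strength: each expressed mutant allele multiplies the
        affected probability by ``1 - e`` (see ``h`` for heterozygotes).
    mu : float
        Mutation rate per allele copy per birth (wild type -> mutant).
    h : float
        Dominance coefficient.  A heterozygote's multiplier is ``1 - h*e``,
        a homozygote's is ``(1 - e)**2``; the default ``h=1`` is the
        codominant, per-copy multiplicative model.
    init_freq : float
        Initial mutant-allele frequency assigned at population
        initialisation (each allele copy is mutant independently with this
        probability).  The default 0 starts from a mutation-free population.
    """

    id: int
    effect: str
    scope: str
    onset_class: int
    e: float = 0.025
    mu: float = 0.005
    h: float = 1.0
    init_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"locus {self.id}: effect must be one of {EFFECTS}, got {self.effect!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"locus {self.id}: scope must be one of {SCOPES}, got {self.scope!r}")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError(f"locus {self.id}: e must lie in [0, 1], got {self.e}")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError(f"locus {self.id}: mu must lie in [0, 1), got {self.mu}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"locus {self.id}: h must lie in [0, 1], got {self.h}")
        if not 0.0 <= self.init_freq <= 1.0:
            raise ValueError(f"locus {self.id}: init_freq must lie in [0, 1], got {self.init_freq}")
        if int(self.onset_class) != self.onset_class or self.onset_class < 1:
            raise ValueError(f"locus {self.id}: onset_class must be a positive integer, got {self.onset_class}")

    def affects_sex(self, sex: int) -> bool:
        if self.scope == "both":
            return True
        return (self.scope == "male_only") == (sex == MALE)


@dataclass
class Individual:
    """A single simulated individual: sex, age class and genotype.

    The simulation engine works on packed arrays; this object is the
    record-level view used by the scalar API and by tests.
    """

    sex: int
    age_class: int
    genotype: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.uint8))

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.uint8)
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"sex must be {MALE} (male) or {FEMALE} (female)")
        if self.age_class < 1:
            raise ValueError("age_class must be >= 1")
        if self.genotype.ndim != 1 or (self.genotype > 2).any():
            raise ValueError("genotype must be a 1-D vector of allele counts in {0, 1, 2}")


class LocusArrays:
    """Column-wise view of a locus set, precomputed for the vectorised engine."""

    __slots__ = (
        "loci", "n_loci", "onset", "e", "mu", "het_factor", "hom_factor",
        "mortality", "fertility", "expressed_in", "init_freq",
    )

    def __init__(self, loci: list[LocusSpec]):
        self.loci = list(loci)
        self.n_loci = len(self.loci)
        self.onset = np.array([l.onset_class for l in loci], dtype=np.int64)
        self.e = np.array([l.e for l in loci], dtype=float)
        self.mu = np.array([l.mu for l in loci], dtype=float)
        self.init_freq = np.array([l.init_freq for l in loci], dtype=float)
        h = np.array([l.h for l in loci], dtype=float)
        self.het_factor = 1.0 - h * self.e
        self.hom_factor = (1.0 - self.e) ** 2
        self.mortality = np.array([l.effect == "mortality" for l in loci], dtype=bool)
        self.fertility = ~self.mortality
        self.expressed_in = np.array(
            [[l.affects_sex(MALE) for l in loci], [l.affects_sex(FEMALE) for l in loci]],
            dtype=bool,
        )


def locus_arrays(loci: list[LocusSpec]) -> LocusArrays:
    """Pack a list of :class:`LocusSpec` into arrays for vectorised use."""
    return LocusArrays(loci)


def transmit_gametes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mendelian transmission for a batch of parents.

    ``genotypes`` has shape ``(k, L)`` with allele counts in {0, 1, 2}.
    Returns a ``(k, L)`` uint8 array of transmitted alleles: a homozygous
    mutant locus always transmits the mutant, a heterozygous locus transmits
    it with probability one half, and loci segregate independently.
    """
    genotypes = np.asarray(genotypes, dtype=np.uint8)
    r = rng.random(genotypes.shape)
    return ((genotypes == 2) | ((genotypes == 1) & (r < 0.5))).astype(np.uint8)


def transmit_gamete(genotype: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Transmit one haploid gamete (0/1 per locus) from a single parent."""
    return transmit_gametes(np.atleast_2d(genotype), rng)[0]


def mutate_gametes(
    paternal: np.ndarray,
    maternal: np.ndarray,
    loci: LocusArrays,
    rng: np.random.Generator,
    model: str = "per_copy",
) -> np.ndarray:
    """Apply new mutations to a batch of gamete pairs; return newborn genotypes.

    Under ``per_copy`` each wild-type allele copy flips to mutant
    independently with its locus's rate mu; under ``per_diploid`` each
    newborn locus gains at most one new mutant copy with probability mu.
    Mutant alleles never revert, so the genotype count never decreases.
    """
    if model not in MUTATION_MODELS:
        raise ValueError(f"mutation model must be one of {MUTATION_MODELS}, got {model!r}")
    paternal = np.asarray(paternal, dtype=np.uint8)
    maternal = np.asarray(maternal, dtype=np.uint8)
    if paternal.shape != maternal.shape:
        raise ValueError("gamete arrays must have matching shapes")
    if paternal.shape[-1] != loci.n_loci:
        raise ValueError(
            f"gametes carry {paternal.shape[-1]} loci but {loci.n_loci} are defined"
        )
    if model == "per_copy":
        pat = paternal | (rng.random(paternal.shape) < loci.mu)
        mat = maternal | (rng.random(maternal.shape) < loci.mu)
        return (pat + mat).astype(np.uint8)
    # per_diploid: one Bernoulli(mu) event per newborn locus, applied to a
    # wild-type copy when one exists.
    counts = (paternal + maternal).astype(np.uint8)
    hit = (rng.random(counts.shape) < loci.mu) & (counts < 2)
    return (counts + hit).astype(np.uint8)


def mutate_newborn(
    paternal_gamete: np.ndarray,
    maternal_gamete: np.ndarray,
    loci: list[LocusSpec] | LocusArrays,
    rng: np.random.Generator,
    model: str = "per_copy",
) -> np.ndarray:
    """Combine two gametes into a newborn genotype, introducing new mutations."""
    la = loci if isinstance(loci, LocusArrays) else locus_arrays(loci)
    pat = np.atleast_2d(np.asarray(paternal_gamete, dtype=np.uint8))
    mat = np.atleast_2d(np.asarray(maternal_gamete, dtype=np.uint8))
    return mutate_gametes(pat, mat, la, rng, model=model)[0]
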