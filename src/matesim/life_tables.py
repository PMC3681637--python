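"""Intrinsic life tables and their modification by mutation load.

Age is discrete: classes 1..n (default 18), each representing a five-year
period.  ``survival[sex, x-1]`` is the probability that an individual of sex
``sex`` in age class ``x`` survives the period and advances to class ``x+1``;
``fertility[sex, x-1]`` is the probability that an individual of class ``x``,
once paired, contributes to a birth.  The last age class always has survival
zero (forced death).

Mutation load acts multiplicatively: an expressed mutant allele multiplies
the affected probability by ``1 - e`` (``1 - h*e`` for a lone heterozygous
copy).  A locus is expressed only at and beyond its age-of-onset class and
only in the sexes its scope names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import FEMALE, MALE, Individual, LocusArrays, LocusSpec, locus_arrays

__all__ = [
    "GompertzMakehamParams",
    "LifeTables",
    "gompertz_makeham_survival",
    "default_survival",
    "prolonged_fertility",
    "declining_fertility",
    "prolonged_tables",
    "mortality_study_tables",
    "load_multiplier",
    "effective_survival",
    "effective_fertility",
]

N_CLASSES_DEFAULT = 18


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Gompertz–Makeham hazard: lambda(x) = A + B * exp(C * x) per age class.

    A is the age-independent (extrinsic) hazard, B the baseline senescent
    hazard and C the exponential rate of its increase with age class.
    """

    A: float = 0.01
    B: float = 0.0001
    C: float = 0.5

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.B <= 0 or self.C <= 0:
            raise ValueError("B and C must be > 0")


def gompertz_makeham_survival(
    params: GompertzMakehamParams, n_classes: int = N_CLASSES_DEFAULT
) -> np.ndarray:
    """Per-class survival probabilities exp(-(A + B*e^(C*x))), x = 1..n-1.

    The final class receives survival 0: no individual outlives class ``n``.
    Survival is strictly decreasing in x for positive B and C.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    x = np.arange(1, n_classes + 1, dtype=float)
    s = np.exp(-(params.A + params.B * np.exp(params.C * x)))
    s = np.clip(s, 0.0, 1.0)
    s[-1] = 0.0
    return s


@dataclass
class LifeTables:
    """Per-sex intrinsic survival and fertility tables.

    Both arrays have shape ``(2, n_classes)`` with row 0 = male and row 1 =
    female; entries are probabilities.  Tables are sex-indexed even when the
    sexes are identical so that sex-specific scenarios need no code change.
    """

    survival: np.ndarray
    fertility: np.ndarray

    def __post_init__(self) -> None:
        self.survival = np.asarray(self.survival, dtype=float)
        self.fertility = np.asarray(self.fertility, dtype=float)
        for name, arr in (("survival", self.survival), ("fertility", self.fertility)):
            if arr.ndim != 2 or arr.shape[0] != 2:
                raise ValueError(f"{name} must have shape (2, n_classes)")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.survival.shape != self.fertility.shape:
            raise ValueError("survival and fertility must have the same shape")
        if (self.survival[:, -1] != 0).any():
            raise ValueError("survival in the last age class must be 0 (forced death)")

    @property
    def n_classes(self) -> int:
        return self.survival.shape[1]


def default_survival(n_classes: int = N_CLASSES_DEFAULT) -> np.ndarray:
    """Default intrinsic survival, identical for both sexes.

    Gompertz–Makeham with A=0.01, B=1e-4, C=0.5 per age class: survival
    stays above 0.9 through roughly class 10 and collapses before the final
    class — a schematic human-like survivorship curve.
    """
    s = gompertz_makeham_survival(GompertzMakehamParams(), n_classes)
    return np.vstack([s, s])


def prolonged_fertility(
    n_classes: int = N_CLASSES_DEFAULT,
    adult_min: int = 4,
    plateau: float = 0.9,
    last_fertile: int | None = None,
) -> np.ndarray:
    """Fertility vector: 0 before ``adult_min``, a plateau through
    ``last_fertile`` (default: the penultimate class), 0 afterwards."""
    if last_fertile is None:
        last_fertile = n_classes - 1
    f = np.zeros(n_classes)
    f[adult_min - 1 : last_fertile] = plateau
    return f


def declining_fertility(
    n_classes: int = N_CLASSES_DEFAULT,
    adult_min: int = 4,
    last_fertile: int = 9,
    plateau: float = 0.9,
) -> np.ndarray:
    """Fertility with a fixed mid-life cutoff: plateau over classes
    ``adult_min``..``last_fertile``, zero beyond (intrinsically menopausal)."""
    return prolonged_fertility(n_classes, adult_min, plateau, last_fertile)


def prolonged_tables(n_classes: int = N_CLASSES_DEFAULT) -> LifeTables:
    """Ancestral state for the fertility experiments: prolonged fertility in
    both sexes over the default survival curve."""
    f = prolonged_fertility(n_classes)
    return LifeTables(default_survival(n_classes), np.vstack([f, f]))


def mortality_study_tables(n_classes: int = N_CLASSES_DEFAULT) -> LifeTables:
    """Tables for the mortality-only experiments: prolonged male fertility
    but female fertility fixed to end at class 9 — the classic setting in
    which extended male mating is the only late-life source of selection."""
    fert = np.vstack(
        [prolonged_fertility(n_classes), declining_fertility(n_classes)]
    )
    return LifeTables(default_survival(n_classes), fert)


def load_multiplier(
    ages: np.ndarray,
    genotypes: np.ndarray,
    sex: int,
    loci: LocusArrays,
    effect_mask: np.ndarray,
) -> np.ndarray:
    """Multiplicative fitness modifier from expressed mutation load.

    For each individual, the product over expressed loci of the per-genotype
    factor (1 for wild type, ``1 - h*e`` for heterozygotes, ``(1-e)^2`` for
    homozygotes).  A locus is expressed iff the individual's age class has
    reached its onset and its scope includes ``sex``.  ``effect_mask``
    selects which effect type (mortality or fertility) enters.
    """
    sel = effect_mask & loci.expressed_in[sex]
    n = len(ages)
    if not sel.any() or n == 0:
        return np.ones(n)
    active = ages[:, None] >= loci.onset[None, sel]
    g = genotypes[:, sel]
    het = ((g == 1) & active).astype(float)
    hom = ((g == 2) & active).astype(float)
    log_het = np.log(np.maximum(loci.het_factor[sel], 1e-300))
    log_hom = np.log(np.maximum(loci.hom_factor[sel], 1e-300))
    mult = np.exp(het @ log_het + hom @ log_hom)
    # exact zeros for e = 1 (log floor keeps exp finite but tiny)
    return np.clip(mult, 0.0, 1.0)


def _scalar_effective(ind: Individual, base: float, loci, effect: str) -> float:
    la = loci if isinstance(loci, LocusArrays) else locus_arrays(list(loci))
    mask = la.mortality if effect == "mortality" else la.fertility
    mult = load_multiplier(
        np.array([ind.age_class]), np.atleast_2d(ind.genotype), ind.sex, la, mask
    )[0]
    return float(np.clip(base * mult, 0.0, 1.0))


def effective_survival(ind: Individual, tables: LifeTables, loci) -> float:
    """Survival probability of one individual: intrinsic survival for its
    sex and age class, reduced by its expressed mortality load."""
    base = tables.survival[ind.sex, ind.age_class - 1]
    return _scalar_effective(ind, base, loci, "mortality")


def effective_fertility(ind: Individual, tables: LifeTables, loci) -> float:
    """Fertility probability of one individual: intrinsic fertility reduced
    by its expressed fertility load (mortality loci never enter)."""
    base = tables.fertility[ind.sex, ind.age_class - 1]
    return _scalar_effective(ind, base, loci, "fertility")
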