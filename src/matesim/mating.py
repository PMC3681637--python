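"""Mating-preference matrices and pair formation.

The matrix M[i, j] gives the probability that a randomly drawn male of age
class i and female of age class j form a pair.  Three canonical matrices:

* ``AP`` (all pairs) — age-indifferent: any adult male with any adult female.
* ``YP`` (young pairs) — both sexes restricted to a young window.
* ``YF`` (young females) — adult males of any age, females young only.

A birth is simulated by rejection sampling: draw a candidate father and
mother uniformly from the surviving pools (with replacement), accept the
pair with probability M[i, j], then let a birth occur with probability equal
to the product of the two parents' effective fertilities.  Repeat until a
birth occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetics import FEMALE, MALE, Individual, LocusArrays, locus_arrays
from .life_tables import LifeTables, load_multiplier

__all__ = [
    "MatingMatrix",
    "build_matrix",
    "NoFertilePairsError",
    "draw_parent_pairs",
    "simulate_birth",
]

MATRIX_LABELS = ("AP", "YP", "YF", "custom")

#: Default young window (classes 4-7, i.e. ages 15-35) and adulthood
#: threshold (class 3: mating allowed after the second age class).
YOUNG_MIN_DEFAULT = 4
YOUNG_MAX_DEFAULT = 7
ADULT_MIN_DEFAULT = 3


class NoFertilePairsError(RuntimeError):
    """Raised when the birth loop cannot produce a birth.

    Signals a degenerate configuration — e.g. an empty parent pool, all-zero
    fertility, or a preference matrix with no admissible pair — rather than
    silently deadlocking.
    """


@dataclass
class MatingMatrix:
    """Pair-formation probabilities indexed by (male age class, female age class)."""

    M: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("mating matrix must be square")
        if ((self.M < 0) | (self.M > 1)).any():
            raise ValueError("mating matrix entries must lie in [0, 1]")
        if self.label not in MATRIX_LABELS:
            raise ValueError(f"label must be one of {MATRIX_LABELS}")

    @property
    def n_classes(self) -> int:
        return self.M.shape[0]


def build_matrix(
    label: str,
    young_min: int = YOUNG_MIN_DEFAULT,
    young_max: int = YOUNG_MAX_DEFAULT,
    adult_min: int = ADULT_MIN_DEFAULT,
    n_classes: int = 18,
) -> MatingMatrix:
    """Construct one of the canonical 0/1 preference matrices.

    AP: M[i,j] = 1 iff both i and j are at least ``adult_min``.
    YP: M[i,j] = 1 iff both i and j lie in [young_min, young_max].
    YF: M[i,j] = 1 iff i >= adult_min and j lies in [young_min, young_max].
    """
    if label not in ("AP", "YP", "YF"):
        raise ValueError(f"build_matrix handles AP/YP/YF, got {label!r}")
    if not (1 <= young_min <= young_max <= n_classes):
        raise ValueError("require 1 <= young_min <= young_max <= n_classes")
    if adult_min < 3:
        raise ValueError("adult_min must be >= 3 (no mating before the third class)")
    cls = np.arange(1, n_classes + 1)
    adult = cls >= adult_min
    young = (cls >= young_min) & (cls <= young_max)
    if label == "AP":
        male_ok, female_ok = adult, adult
    elif label == "YP":
        male_ok, female_ok = young, young
    else:  # YF
        male_ok, female_ok = adult, young
    M = np.outer(male_ok, female_ok).astype(float)
    return MatingMatrix(M, label=label)


def _acceptance_possible(
    M: np.ndarray, ages_m: np.ndarray, ages_f: np.ndarray,
    fert_m: np.ndarray, fert_f: np.ndarray,
) -> bool:
    """Whether any (male, female) draw has positive birth probability."""
    n = M.shape[0]
    best_m = np.zeros(n)
    best_f = np.zeros(n)
    np.maximum.at(best_m, ages_m - 1, fert_m)
    np.maximum.at(best_f, ages_f - 1, fert_f)
    return float((best_m[:, None] * M * best_f[None, :]).max()) > 0.0


def draw_parent_pairs(
    n_pairs: int,
    ages_m: np.ndarray,
    ages_f: np.ndarray,
    fert_m: np.ndarray,
    fert_f: np.ndarray,
    matrix: MatingMatrix,
    rng: np.random.Generator,
    max_attempts: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised birth loop: indices of ``n_pairs`` successful parent pairs.

    Candidate fathers and mothers are drawn uniformly with replacement, so a
    single individual may parent several newborns in one period.  Each
    candidate pair succeeds with probability M[i, j] * F_m * F_f, making the
    accepted-pair distribution proportional to pool counts x matrix x
    effective fertilities.
    """
    if len(ages_m) == 0 or len(ages_f) == 0:
        raise NoFertilePairsError("a parental pool is empty")
    fathers = np.empty(n_pairs, dtype=np.int64)
    mothers = np.empty(n_pairs, dtype=np.int64)
    got = 0
    attempts = 0
    checked = False
    M = matrix.M
    while got < n_pairs:
        if attempts >= max_attempts:
            raise NoFertilePairsError(
                f"no birth after {attempts} candidate pairs; "
                "matrix/fertility configuration may admit no fertile pair"
            )
        batch = int(min(max(4 * (n_pairs - got), 256), max_attempts - attempts))
        i = rng.integers(0, len(ages_m), batch)
        j = rng.integers(0, len(ages_f), batch)
        p = M[ages_m[i] - 1, ages_f[j] - 1] * fert_m[i] * fert_f[j]
        ok = np.nonzero(rng.random(batch) < p)[0]
        attempts += batch
        if ok.size == 0 and not checked:
            checked = True
            if not _acceptance_possible(M, ages_m, ages_f, fert_m, fert_f):
                raise NoFertilePairsError(
                    "no pair has positive birth probability under this "
                    "matrix and these fertilities"
                )
        take = ok[: n_pairs - got]
        fathers[got : got + take.size] = i[take]
        mothers[got : got + take.size] = j[take]
        got += take.size
    return fathers, mothers


def simulate_birth(
    males: list[Individual],
    females: list[Individual],
    matrix: MatingMatrix,
    tables: LifeTables,
    loci,
    rng: np.random.Generator,
    max_attempts: int = 1_000_000,
) -> tuple[Individual, Individual]:
    """Draw one successful (father, mother) pair from individual pools."""
    la = loci if isinstance(loci, LocusArrays) else locus_arrays(list(loci))
    ages_m = np.array([m.age_class for m in males], dtype=np.int64)
    ages_f = np.array([f.age_class for f in females], dtype=np.int64)
    geno_m = np.array([m.genotype for m in males], dtype=np.uint8).reshape(len(males), -1)
    geno_f = np.array([f.genotype for f in females], dtype=np.uint8).reshape(len(females), -1)
    fert_m = tables.fertility[MALE, ages_m - 1] * load_multiplier(
        ages_m, geno_m, MALE, la, la.fertility
    )
    fert_f = tables.fertility[FEMALE, ages_f - 1] * load_multiplier(
        ages_f, geno_f, FEMALE, la, la.fertility
    )
    fi, mi = draw_parent_pairs(
        1, ages_m, ages_f, fert_m, fert_f, matrix, rng, max_attempts
    )
    return males[int(fi[0])], females[int(mi[0])]
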