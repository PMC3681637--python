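"""Preference matrices and the pair-formation / birth loop."""

import numpy as np
import pytest

from matesim import (
    FEMALE,
    MALE,
    Individual,
    LocusSpec,
    NoFertilePairsError,
    build_matrix,
    simulate_birth,
)
from matesim.life_tables import load_multiplier
from matesim.genetics import locus_arrays
from matesim.mating import draw_parent_pairs

from conftest import enumerate_pair_distribution


class TestBuildMatrix:
    def test_ap_adults_only(self):
        M = build_matrix("AP", adult_min=3).M
        assert M[2 - 1, 10 - 1] == 0  # class-2 male excluded
        assert M[3 - 1, 3 - 1] == 1
        assert M[17 - 1, 17 - 1] == 1

    def test_yf_is_age_asymmetric(self):
        M = build_matrix("YF", young_min=4, young_max=7).M
        assert M[15 - 1, 5 - 1] == 1  # old male, young female
        assert M[5 - 1, 15 - 1] == 0  # young male, old female

    def test_yp_confined_to_young_window(self):
        M = build_matrix("YP", young_min=4, young_max=7).M
        i, j = np.nonzero(M)
        assert ((i + 1 >= 4) & (i + 1 <= 7)).all()
        assert ((j + 1 >= 4) & (j + 1 <= 7)).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(label="XX"),
            dict(label="YP", young_min=0),
            dict(label="YP", young_min=8, young_max=7),
            dict(label="AP", adult_min=2),
            dict(label="YF", young_max=19),
        ],
    )
    def test_invalid_bounds(self, kwargs):
        with pytest.raises(ValueError):
            build_matrix(**kwargs)


def test_matrix_blocks_underage_father(flat_tables, rng):
    """Two males (classes 2 and 5), one class-5 female, AP: the class-2
    male is always rejected, so the class-5 male fathers every birth."""
    males = [Individual(MALE, 2, np.zeros(1)), Individual(MALE, 5, np.zeros(1))]
    females = [Individual(FEMALE, 5, np.zeros(1))]
    loci = [LocusSpec(1, "mortality", "both", 6)]
    for _ in range(30):
        father, mother = simulate_birth(
            males, females, build_matrix("AP"), flat_tables, loci, rng
        )
        assert father.age_class == 5
        assert mother.age_class == 5


def test_all_infertile_females_raise(flat_tables, rng):
    import matesim.life_tables as lt

    tables = lt.LifeTables(flat_tables.survival, np.vstack(
        [np.ones(18), np.zeros(18)]
    ))
    males = [Individual(MALE, 5, np.zeros(1))]
    females = [Individual(FEMALE, 5, np.zeros(1))]
    loci = [LocusSpec(1, "mortality", "both", 6)]
    with pytest.raises(NoFertilePairsError):
        simulate_birth(males, females, build_matrix("AP"), tables, loci, rng,
                       max_attempts=10_000)


def test_empty_pool_raises(rng):
    with pytest.raises(NoFertilePairsError):
        draw_parent_pairs(
            1, np.array([], dtype=int), np.array([5]), np.array([]),
            np.array([1.0]), build_matrix("AP"), rng
        )


def test_accepted_pairs_match_enumeration(rng):
    """Accepted (father, mother) ages are distributed proportionally to
    pool counts x matrix x effective fertilities (exhaustive enumeration
    on a 4-male, 3-female pool)."""
    matrix = build_matrix("YF", young_min=4, young_max=7)
    ages_m = np.array([3, 5, 9, 9])
    ages_f = np.array([4, 6, 9])
    fert_m = np.array([0.9, 0.5, 0.7, 0.7])
    fert_f = np.array([0.8, 0.4, 0.9])
    expected = enumerate_pair_distribution(ages_m, ages_f, fert_m, fert_f, matrix)

    n = 40_000
    fa, mo = draw_parent_pairs(n, ages_m, ages_f, fert_m, fert_f, matrix, rng,
                               max_attempts=10_000_000)
    observed = np.zeros_like(expected)
    np.add.at(observed, (fa, mo), 1.0 / n)
    # total variation distance well inside Monte-Carlo noise at n = 4e4
    assert 0.5 * np.abs(observed - expected).sum() < 0.02
    # pairs the matrix forbids never occur
    assert observed[expected == 0].sum() == 0


def test_late_onset_female_locus_invisible_to_yf_birth_loop():
    """A female-limited fertility locus with onset above the young window
    leaves every admissible pair's birth probability unchanged under YF."""
    matrix = build_matrix("YF", young_min=4, young_max=7)
    loci = locus_arrays([LocusSpec(1, "fertility", "female_only", 8, e=0.9)])
    ages_f = np.arange(1, 19)
    mutant = np.full((18, 1), 2, dtype=np.uint8)
    wild = np.zeros((18, 1), dtype=np.uint8)
    base = 0.9 * np.ones(18)
    fert_mut = base * load_multiplier(ages_f, mutant, FEMALE, loci, loci.fertility)
    fert_wild = base * load_multiplier(ages_f, wild, FEMALE, loci, loci.fertility)
    admissible = matrix.M.any(axis=0)  # female classes any male may pair with
    assert np.array_equal(fert_mut[admissible], fert_wild[admissible])
    # the locus is expressed somewhere, just not where mating happens
    assert (fert_mut < fert_wild).any()


def test_ap_symmetric_penalty_for_either_sex_carrier(flat_tables):
    """Under AP with sex-symmetric tables, a male-limited and a
    female-limited fertility mutation at the same onset depress the total
    birth probability identically (exchangeability of the sexes)."""
    matrix = build_matrix("AP")
    ages = np.arange(1, 19)
    wild = np.zeros((18, 1), dtype=np.uint8)
    mutant = np.full((18, 1), 2, dtype=np.uint8)
    base = flat_tables.fertility[0]
    totals = []
    for scope, sex_mut in (("male_only", MALE), ("female_only", FEMALE)):
        la = locus_arrays([LocusSpec(1, "fertility", scope, 9, e=0.3)])
        fert = {
            MALE: base * load_multiplier(ages, mutant if sex_mut == MALE else wild, MALE, la, la.fertility),
            FEMALE: base * load_multiplier(ages, mutant if sex_mut == FEMALE else wild, FEMALE, la, la.fertility),
        }
        totals.append((fert[MALE][:, None] * matrix.M * fert[FEMALE][None, :]).sum())
    assert totals[0] == pytest.approx(totals[1])
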