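import numpy as np
import pytest

from matesim import (
    LifeTables,
    LocusSpec,
    build_matrix,
    default_survival,
    make_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_tables():
    return make_fixture("toy_tables")


@pytest.fixture
def toy_matrix():
    return make_fixture("toy_matrix")


@pytest.fixture
def flat_tables():
    """18-class tables with fertility 1 everywhere (and default survival)."""
    return LifeTables(default_survival(), np.ones((2, 18)))


@pytest.fixture
def one_mortality_locus():
    return [LocusSpec(1, "mortality", "both", 6, e=0.025, mu=0.005)]


def enumerate_pair_distribution(ages_m, ages_f, fert_m, fert_f, matrix):
    """Exact accepted-pair distribution over (father index, mother index).

    Candidates are drawn uniformly with replacement, so conditional on
    acceptance the pair probability is proportional to
    M[age_m, age_f] * fert_m * fert_f.
    """
    p = (
        matrix.M[np.asarray(ages_m)[:, None] - 1, np.asarray(ages_f)[None, :] - 1]
        * np.asarray(fert_m)[:, None]
        * np.asarray(fert_f)[None, :]
    )
    total = p.sum()
    if total == 0:
        raise ValueError("no pair has positive probability")
    return p / total
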