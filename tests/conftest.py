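import numpy as np
import pytest

from kincensus import Pedigree, make_species_params, simulate
from kincensus.demography import ALIVE


@pytest.fixture(scope="session")
def deer_params():
    return make_species_params("red_deer")


@pytest.fixture(scope="session")
def boar_params():
    return make_species_params("wild_boar")


@pytest.fixture(scope="session")
def deer_pedigree(deer_params):
    return simulate(deer_params, 200, seed=1)


@pytest.fixture(scope="session")
def boar_pedigree(boar_params):
    return simulate(boar_params, 200, seed=2)


def build_pedigree(rows, final_year, params=None):
    """Hand-build a pedigree from (id, sex, birth, death, mother, father) rows.

    death None means alive at final_year; parent 0 means unknown.
    """
    ids, sexes, births, deaths, mothers, fathers = zip(*rows)
    return Pedigree(
        ids=np.array(ids),
        female=np.array([s == "F" for s in sexes]),
        birth_year=np.array(births),
        death_year=np.array([ALIVE if d is None else d for d in deaths]),
        mother_id=np.array(mothers),
        father_id=np.array(fathers),
        final_year=final_year,
        params=params,
    )


@pytest.fixture
def toy_family(deer_params):
    """A mother of C and D, B father of C, E unrelated; all alive at year 10.

    A, B, E are mature red deer; C, D are juveniles (age 1).
    """
    rows = [
        (1, "F", 0, None, 0, 0),   # A, age 10
        (2, "M", 2, None, 0, 0),   # B, age 8
        (3, "F", 9, None, 1, 2),   # C, daughter of A and B
        (4, "M", 9, None, 1, 0),   # D, son of A, father unknown
        (5, "F", 9, None, 0, 0),   # E, unrelated juvenile
    ]
    return build_pedigree(rows, final_year=10, params=deer_params)
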