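"""Individual-based annual-cycle pedigree simulator with overlapping generations.

Simulates a closed, harvest-free population of a polygynous terrestrial mammal
on a yearly time step.  Every individual is tracked from birth to death with
its parent links, so the output is a complete multi-generation pedigree from
which kin-based census-size estimators can be evaluated against known truth.

The annual cycle is: mating and births; newborn mortality; yearling mortality;
density-dependent adult mortality (an annual Bernoulli rate on individuals
aged 2+, scaled by the pre-breeding population size relative to carrying
capacity); senescence; and finally a ceiling cull that removes any remaining
excess above carrying capacity, taken from newborns first (density-dependent
juvenile mortality), then yearlings, then adults.  For a low-fecundity
species the adult rate alone stabilizes the population somewhat below the
ceiling; for high-recruitment scenarios the ceiling binds and the newborn
cull absorbs the surplus, so adults never experience catastrophic cull years
and the realized long-run adult mortality stays near the preset's reference
value.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

_logger = logging.getLogger("kincensus")

__all__ = [
    "ALIVE",
    "UNKNOWN_PARENT",
    "SpeciesParams",
    "Pedigree",
    "TruthSizes",
    "SPECIES_PRESETS",
    "make_species_params",
    "init_population",
    "step_year",
    "simulate",
    "truth_sizes",
    "audit_pedigree",
    "realized_adult_mortality",
]

#: sentinel death_year for individuals alive at the pedigree's final year
ALIVE = -1
#: parent id code for founders, whose parents are outside the simulation
UNKNOWN_PARENT = 0


@dataclass(frozen=True)
class SpeciesParams:
    """Complete demographic parameterization of a simulated species.

    Parameters
    ----------
    name
        Label for the parameter set.
    max_lifespan
        Maximum age in years; individuals reaching it die of senescence.
    female_maturity, male_maturity
        Age (years) from which females/males can breed.  For polygynous
        species male "maturity" is social: the age from which males actually
        secure matings.
    fecundity_mean, fecundity_sd
        Mean and SD of the per-mother annual litter size.  Litter sizes are
        drawn from a Normal, rounded to the nearest integer and truncated
        below at zero.
    newborn_mortality, yearling_mortality
        Probability of dying during the first (age 0) and second (age 1)
        year of life.
    adult_mortality_ref
        Literature value for the mean annual mortality of adults (age >= 2).
        Used as the coefficient of the density-dependent adult mortality
        rate, min(1, adult_mortality_ref * N/K) with N the pre-breeding
        population size; the realized long-run adult rate (which also
        includes senescence and any cull spill-over) should stay within
        about 0.1 of this value.
    multi_mate_fraction
        Fraction of mature females mating with more than one male per year
        (0 for strictly monandrous species).
    partner_lambda
        Poisson mean of the partner-count distribution for multi-mating
        females.
    carrying_capacity
        Population ceiling K enforced by the regulation step.
    sex_ratio
        Probability that a newborn (or founder) is female.
    """

    name: str
    max_lifespan: int
    female_maturity: int
    male_maturity: int
    fecundity_mean: float
    fecundity_sd: float
    newborn_mortality: float
    yearling_mortality: float
    adult_mortality_ref: float
    multi_mate_fraction: float = 0.0
    partner_lambda: float = 2.0
    carrying_capacity: int = 500
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        problems = []
        for f in ("newborn_mortality", "yearling_mortality", "adult_mortality_ref",
                  "multi_mate_fraction", "sex_ratio"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{f}={v} not in [0, 1]")
        for f in ("female_maturity", "male_maturity"):
            v = getattr(self, f)
            if not 1 <= v <= self.max_lifespan:
                problems.append(f"{f}={v} not in [1, max_lifespan={self.max_lifespan}]")
        if self.fecundity_mean < 0:
            problems.append(f"fecundity_mean={self.fecundity_mean} < 0")
        if self.fecundity_sd < 0:
            problems.append(f"fecundity_sd={self.fecundity_sd} < 0")
        if self.carrying_capacity < 2:
            problems.append(f"carrying_capacity={self.carrying_capacity} < 2")
        if self.partner_lambda < 0:
            problems.append(f"partner_lambda={self.partner_lambda} < 0")
        if problems:
            raise ValueError("invalid SpeciesParams: " + "; ".join(problems))

    def replace(self, **changes) -> "SpeciesParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


SPECIES_PRESETS: dict[str, SpeciesParams] = {
    # Cervus elaphus: single calf per hind per year, late male social maturity.
    "red_deer": SpeciesParams(
        name="red_deer",
        max_lifespan=15,
        female_maturity=2,
        male_maturity=5,
        fecundity_mean=1.0,
        fecundity_sd=0.0,
        newborn_mortality=0.2,
        yearling_mortality=0.335,
        adult_mortality_ref=0.315,
        multi_mate_fraction=0.0,
        partner_lambda=2.0,
        carrying_capacity=500,
        sex_ratio=0.5,
    ),
    # Sus scrofa: large variable litters, early female maturity, 44% of sows
    # mate with more than one boar (Poisson-distributed partner count).
    "wild_boar": SpeciesParams(
        name="wild_boar",
        max_lifespan=12,
        female_maturity=1,
        male_maturity=3,
        fecundity_mean=4.9,
        fecundity_sd=2.1,
        newborn_mortality=0.539,
        yearling_mortality=0.585,
        adult_mortality_ref=0.360,
        multi_mate_fraction=0.44,
        partner_lambda=2.0,
        carrying_capacity=500,
        sex_ratio=0.5,
    ),
}


def make_species_params(name: str) -> SpeciesParams:
    """Return the demographic preset for a known species.

    Raises
    ------
    ValueError
        If `name` is not a known preset.
    """
    try:
        return SPECIES_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(SPECIES_PRESETS))
        raise ValueError(f"unknown species preset {name!r}; known presets: {known}") from None


class Pedigree:
    """A complete multi-generation pedigree: every individual ever alive.

    Stored as parallel numpy arrays sorted by id.  Ids are positive integers;
    parent id 0 means unknown (founders).  ``death_year == ALIVE`` marks
    individuals still alive at ``final_year``.
    """

    __slots__ = ("ids", "female", "birth_year", "death_year", "mother_id",
                 "father_id", "final_year", "params", "seed")

    def __init__(self, ids, female, birth_year, death_year, mother_id, father_id,
                 final_year: int, params: SpeciesParams | None = None,
                 seed: int | None = None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.female = np.asarray(female, dtype=bool)
        self.birth_year = np.asarray(birth_year, dtype=np.int64)
        self.death_year = np.asarray(death_year, dtype=np.int64)
        self.mother_id = np.asarray(mother_id, dtype=np.int64)
        self.father_id = np.asarray(father_id, dtype=np.int64)
        self.final_year = int(final_year)
        self.params = params
        self.seed = seed
        order = np.argsort(self.ids, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            for name in ("ids", "female", "birth_year", "death_year",
                         "mother_id", "father_id"):
                setattr(self, name, getattr(self, name)[order])

    def __len__(self) -> int:
        return len(self.ids)

    def alive_at(self, year: int | None = None) -> np.ndarray:
        """Boolean mask of individuals alive at `year` (default: final_year).

        An individual is alive at year t if it was born no later than t and
        either has no recorded death or died strictly after t.
        """
        if year is None:
            year = self.final_year
        born = self.birth_year <= year
        return born & ((self.death_year == ALIVE) | (self.death_year > year))

    def age_at(self, year: int | None = None) -> np.ndarray:
        if year is None:
            year = self.final_year
        return year - self.birth_year

    def mature_at(self, year: int | None = None) -> np.ndarray:
        """Mask of individuals alive and sexually mature at `year`."""
        if self.params is None:
            raise ValueError("pedigree has no SpeciesParams; maturity undefined")
        age = self.age_at(year)
        maturity = np.where(self.female, self.params.female_maturity,
                            self.params.male_maturity)
        return self.alive_at(year) & (age >= maturity)

    def index_of(self, ids) -> np.ndarray:
        """Row indices of the given ids (ids must exist in the pedigree)."""
        idx = np.searchsorted(self.ids, ids)
        return idx

    def to_frame(self):
        """Pedigree as a pandas DataFrame (PED-like column layout).

        ``death_year`` is a nullable integer column; missing means alive at
        the final year.
        """
        import pandas as pd

        death = pd.array(self.death_year, dtype="Int64")
        death[self.death_year == ALIVE] = pd.NA
        return pd.DataFrame({
            "id": self.ids,
            "sex": np.where(self.female, "F", "M"),
            "birth_year": self.birth_year,
            "death_year": death,
            "mother_id": self.mother_id,
            "father_id": self.father_id,
        })


@dataclass(frozen=True)
class TruthSizes:
    """True census sizes at the pedigree's final year.

    ``n_adult`` counts demographic adults (age >= 2, the class governed by
    the density-dependent adult mortality); ``n_breeding_females`` counts
    living females at or above the female maturity age.  The two use
    different criteria, so for an early-maturing species breeding females
    need not be a subset of adults.
    """

    n_total: int
    n_adult: int
    n_breeding_females: int

    def __post_init__(self):
        if self.n_adult > self.n_total or self.n_breeding_females > self.n_total:
            raise ValueError("truth sizes must satisfy "
                             "n_adult <= n_total and n_breeding_females <= n_total")

    def for_target(self, target: str) -> int:
        return {"total": self.n_total, "adult": self.n_adult,
                "breeding_females": self.n_breeding_females}[target]


# ---------------------------------------------------------------------------
# simulation internals

class _SimState:
    """Mutable live-cohort arrays plus an append-only record of the dead."""

    __slots__ = ("ids", "female", "birth", "mother", "father",
                 "dead", "next_id", "year")

    def __init__(self):
        self.dead: list[tuple] = []

    @classmethod
    def from_founders(cls, params: SpeciesParams, rng: np.random.Generator):
        st = cls()
        k = params.carrying_capacity
        st.ids = np.arange(1, k + 1, dtype=np.int64)
        st.female = rng.random(k) < params.sex_ratio
        ages = rng.integers(1, params.max_lifespan + 1, size=k)
        st.birth = -ages.astype(np.int64)  # age at year 0 equals -birth_year
        st.mother = np.full(k, UNKNOWN_PARENT, dtype=np.int64)
        st.father = np.full(k, UNKNOWN_PARENT, dtype=np.int64)
        st.next_id = k + 1
        st.year = 0
        return st

    @classmethod
    def from_pedigree(cls, ped: Pedigree):
        st = cls()
        alive = ped.alive_at(ped.final_year)
        st.ids = ped.ids[alive].copy()
        st.female = ped.female[alive].copy()
        st.birth = ped.birth_year[alive].copy()
        st.mother = ped.mother_id[alive].copy()
        st.father = ped.father_id[alive].copy()
        dead = ~alive
        if dead.any():
            st.dead.append((ped.ids[dead], ped.female[dead], ped.birth_year[dead],
                            ped.death_year[dead], ped.mother_id[dead],
                            ped.father_id[dead]))
        st.next_id = int(ped.ids.max()) + 1 if len(ped) else 1
        st.year = ped.final_year
        return st

    def bury(self, kill_mask: np.ndarray, year: int) -> None:
        """Move individuals under `kill_mask` to the dead record."""
        if not kill_mask.any():
            return
        death = np.full(int(kill_mask.sum()), year, dtype=np.int64)
        self.dead.append((self.ids[kill_mask], self.female[kill_mask],
                          self.birth[kill_mask], death,
                          self.mother[kill_mask], self.father[kill_mask]))
        keep = ~kill_mask
        self.ids = self.ids[keep]
        self.female = self.female[keep]
        self.birth = self.birth[keep]
        self.mother = self.mother[keep]
        self.father = self.father[keep]

    def to_pedigree(self, params: SpeciesParams, seed: int | None) -> Pedigree:
        alive_death = np.full(len(self.ids), ALIVE, dtype=np.int64)
        chunks = self.dead + [(self.ids, self.female, self.birth, alive_death,
                               self.mother, self.father)]
        cols = [np.concatenate([c[i] for c in chunks]) for i in range(6)]
        return Pedigree(*cols, final_year=self.year, params=params, seed=seed)


def _step(st: _SimState, params: SpeciesParams, rng: np.random.Generator) -> None:
    """Advance the live population one year through the full annual cycle."""
    t = st.year + 1
    n_start = len(st.ids)  # pre-breeding size: the density index for adults
    age = t - st.birth

    # --- mating & births -------------------------------------------------
    mature_f = st.female & (age >= params.female_maturity)
    mature_m = (~st.female) & (age >= params.male_maturity)
    male_ids = st.ids[mature_m]
    n_births = 0
    if mature_f.any() and len(male_ids) > 0:
        mother_ids = st.ids[mature_f]
        n_mf = len(mother_ids)
        litters = np.rint(rng.normal(params.fecundity_mean, params.fecundity_sd,
                                     n_mf))
        litters = np.maximum(litters, 0).astype(np.int64)
        # one uniform partner per female; multi-mating females overwrite below
        single_sire = rng.choice(male_ids, size=n_mf)
        new_mother = np.repeat(mother_ids, litters)
        new_father = np.repeat(single_sire, litters)
        if params.multi_mate_fraction > 0:
            multi = rng.random(n_mf) < params.multi_mate_fraction
            starts = np.cumsum(litters) - litters
            for i in np.flatnonzero(multi):
                # a "multi-male" female has at least 2 partners (capped by
                # the number of mature males); each offspring's sire is
                # uniform over her partner set
                k = max(int(rng.poisson(params.partner_lambda)), 2)
                k = min(k, len(male_ids))
                partners = rng.choice(male_ids, size=k, replace=False)
                li = litters[i]
                if li > 0:
                    sires = partners[rng.integers(0, k, size=li)]
                    new_father[starts[i]:starts[i] + li] = sires
        n_births = int(litters.sum())
        if n_births:
            new_ids = np.arange(st.next_id, st.next_id + n_births, dtype=np.int64)
            st.next_id += n_births
            st.ids = np.concatenate([st.ids, new_ids])
            st.female = np.concatenate([st.female,
                                        rng.random(n_births) < params.sex_ratio])
            st.birth = np.concatenate([st.birth,
                                       np.full(n_births, t, dtype=np.int64)])
            st.mother = np.concatenate([st.mother, new_mother])
            st.father = np.concatenate([st.father, new_father])
            age = t - st.birth

    # --- newborn & yearling mortality ------------------------------------
    n_now = len(st.ids)
    u = rng.random(n_now)
    kill = ((age == 0) & (u < params.newborn_mortality)) \
        | ((age == 1) & (u < params.yearling_mortality))

    # --- density-dependent adult mortality --------------------------------
    m_adult = min(1.0, params.adult_mortality_ref * n_start
                  / params.carrying_capacity)
    if m_adult > 0:
        kill |= (age >= 2) & (rng.random(n_now) < m_adult)

    # --- senescence -------------------------------------------------------
    kill |= age >= params.max_lifespan

    # --- ceiling cull (density-dependent juvenile mortality) --------------
    # remaining excess above K is removed from newborns first, spilling to
    # yearlings and only then adults, so recruitment rather than the adult
    # stock absorbs high-fecundity surpluses
    excess = int((~kill).sum()) - params.carrying_capacity
    if excess > 0:
        for pool_mask in (age == 0, age == 1, age >= 2):
            pool = np.flatnonzero(pool_mask & ~kill)
            if len(pool) == 0:
                continue
            take = min(excess, len(pool))
            culled = rng.choice(pool, size=take, replace=False)
            kill[culled] = True
            excess -= take
            if excess == 0:
                break

    st.bury(kill, t)
    st.year = t
    # survivors age implicitly: age is always (year - birth_year)


def init_population(params: SpeciesParams, seed: int) -> Pedigree:
    """Found a population of `carrying_capacity` unrelated individuals.

    Ages are uniform on {1, ..., max_lifespan}; sexes are independent
    Bernoulli(sex_ratio); no parent links.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    st = _SimState.from_founders(params, rng)
    return st.to_pedigree(params, seed)


def step_year(pedigree: Pedigree, params: SpeciesParams | None = None,
              rng: np.random.Generator | None = None) -> Pedigree:
    """Run one annual cycle and return the extended pedigree.

    The cycle is: mating & births (each mature female that finds at least one
    mature male produces a Normal-draw litter, rounded and truncated at 0),
    newborn mortality, yearling mortality, density-dependent adult mortality
    (rate adult_mortality_ref * N/K on age >= 2), senescence at max_lifespan,
    then a ceiling cull removing any remaining excess above carrying
    capacity from newborns first, then yearlings, then adults.
    """
    params = params or pedigree.params
    if params is None:
        raise ValueError("no SpeciesParams available")
    if rng is None:
        rng = np.random.default_rng()
    st = _SimState.from_pedigree(pedigree)
    _step(st, params, rng)
    return st.to_pedigree(params, pedigree.seed)


def simulate(params: SpeciesParams, n_years: int, seed: int) -> Pedigree:
    """Simulate `n_years` annual cycles from a fresh founder population.

    Returns the full pedigree (every individual ever alive) with
    ``final_year = n_years``.  Bit-reproducible for fixed arguments: the root
    seed is expanded into one child stream for initialization and one per
    year.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_years + 1)
    rng = np.random.default_rng(streams[0])
    st = _SimState.from_founders(params, rng)
    for t in range(1, n_years + 1):
        _step(st, params, np.random.default_rng(streams[t]))
        if t % 20 == 0:
            _logger.info("%s year %d: %d alive", params.name, t, len(st.ids))
    return st.to_pedigree(params, seed)


def truth_sizes(pedigree: Pedigree) -> TruthSizes:
    """True total, adult, and breeding-female counts at the final year.

    Adults are the demographic adult class (age >= 2); breeding females are
    females at or above the female maturity age.
    """
    alive = pedigree.alive_at()
    if not alive.any():
        return TruthSizes(0, 0, 0)
    mature = pedigree.mature_at()
    adult = alive & (pedigree.age_at() >= 2)
    return TruthSizes(
        n_total=int(alive.sum()),
        n_adult=int(adult.sum()),
        n_breeding_females=int((mature & pedigree.female).sum()),
    )


def audit_pedigree(pedigree: Pedigree) -> None:
    """Validate structural invariants; raise AssertionError on violation.

    Checks: unique ids; parent ids resolve; mothers are female and fathers
    male; each parent was sexually mature at the offspring's birth year;
    no lifespan exceeds the species maximum; the living set at the final
    year does not exceed carrying capacity.
    """
    p = pedigree.params
    ids = pedigree.ids
    assert len(np.unique(ids)) == len(ids), "duplicate ids"
    for parent_col, is_female, mat_age in (
            (pedigree.mother_id, True, p.female_maturity if p else None),
            (pedigree.father_id, False, p.male_maturity if p else None)):
        has = parent_col != UNKNOWN_PARENT
        if not has.any():
            continue
        pos = np.searchsorted(ids, parent_col[has])
        assert pos.max(initial=0) < len(ids) and \
            np.array_equal(ids[pos], parent_col[has]), "unresolved parent id"
        assert np.all(pedigree.female[pos] == is_female), "parent sex mismatch"
        if mat_age is not None:
            parent_age_at_birth = pedigree.birth_year[has] - pedigree.birth_year[pos]
            assert np.all(parent_age_at_birth >= mat_age), \
                "parent below maturity age at offspring birth"
    died = pedigree.death_year != ALIVE
    if p is not None:
        spans = np.where(died, pedigree.death_year, pedigree.final_year) \
            - pedigree.birth_year
        # founders drawn at the maximum initial age live through one final
        # cycle before the senescence step removes them
        founder = (pedigree.mother_id == UNKNOWN_PARENT) \
            & (pedigree.father_id == UNKNOWN_PARENT)
        bound = np.where(founder, p.max_lifespan + 1, p.max_lifespan)
        assert np.all(spans <= bound), "lifespan exceeds maximum"
        assert int(pedigree.alive_at().sum()) <= p.carrying_capacity, \
            "living set exceeds carrying capacity"


def realized_adult_mortality(pedigree: Pedigree, last_n_years: int = 100) -> float:
    """Mean realized annual mortality of adults over the final years.

    For each year t, the rate is the fraction of individuals that were alive
    and aged >= 2 entering year t and died during it (from the
    density-dependent rate, senescence, or cull spill-over).
    """
    rates = []
    start = max(1, pedigree.final_year - last_n_years + 1)
    for t in range(start, pedigree.final_year + 1):
        adults = pedigree.alive_at(t - 1) & (pedigree.age_at(t - 1) >= 2)
        n = int(adults.sum())
        if n:
            died = int((adults & (pedigree.death_year == t)).sum())
            rates.append(died / n)
    return float(np.mean(rates)) if rates else float("nan")
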