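"""Random sampling of the standing population and parent-offspring-pair tallies.

A "sample" mimics one season's hunting bag drawn uniformly at random from the
population alive at the pedigree's final year — all coexisting cohorts, not a
single birth cohort.  Parent-offspring pairs (POPs) are then read directly
off the pedigree (perfect kin assignment): a pair is every ordered
(parent, offspring) link with both members sampled.  Because generations
overlap, pairs are tagged adult-adult or adult-juvenile by the offspring's
maturity at the sampled year; detection itself never depends on the tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import Pedigree, UNKNOWN_PARENT

__all__ = ["SampleSet", "POPSet", "KinCounts", "draw_sample", "find_pops",
           "kin_counts"]


@dataclass(frozen=True)
class SampleSet:
    """Ids drawn uniformly without replacement from the living population."""

    ids: np.ndarray
    fraction: float
    year: int
    seed: int

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class POPSet:
    """Directed parent-offspring pairs with both members in the sample.

    ``parent_sex`` entries are "mother"/"father"; ``pair_class`` entries are
    "adult-juvenile" or "adult-adult" (offspring mature at the sampled year).
    """

    parent_id: np.ndarray
    offspring_id: np.ndarray
    parent_sex: np.ndarray
    pair_class: np.ndarray

    def __len__(self) -> int:
        return len(self.parent_id)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "parent_id": self.parent_id,
            "offspring_id": self.offspring_id,
            "parent_sex": self.parent_sex,
            "pair_class": self.pair_class,
        })


@dataclass(frozen=True)
class KinCounts:
    """The sample tallies consumed by the POP-based estimators.

    Two juvenile/adult partitions coexist: ``n_juv``/``n_adult`` split by
    sex-specific sexual maturity (the breeding classes CKMR uses), while
    ``n_juv_age``/``n_adult_age`` split at age 2 (the demographic classes
    g-CMR uses).  Pair counts tally each parent-offspring pair once:
    n = n_juv + n_adult; h_total = h_mother + h_father; k_md
    (mother-daughter pairs, daughter of any age) is a subset of h_mother.
    """

    n: int
    n_juv: int
    n_adult: int
    n_adult_f: int
    n_adult_m: int
    n_juv_age: int
    n_adult_age: int
    n_f: int
    h_total: int
    h_mother: int
    h_father: int
    k_md: int


def draw_sample(pedigree: Pedigree, fraction: float, seed: int) -> SampleSet:
    """Sample a fraction of the final-year standing population.

    Size is round(fraction * n_alive), clamped to at least 2 (an estimator
    needs at least one pair).  Uniform without replacement; seeded.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    alive_ids = pedigree.ids[pedigree.alive_at()]
    if len(alive_ids) < 2:
        raise ValueError("fewer than 2 individuals alive at the final year")
    size = int(np.rint(fraction * len(alive_ids)))
    size = min(max(size, 2), len(alive_ids))
    rng = np.random.default_rng(seed)
    picked = rng.choice(alive_ids, size=size, replace=False)
    return SampleSet(ids=np.sort(picked), fraction=fraction,
                     year=pedigree.final_year, seed=seed)


def find_pops(sample: SampleSet, pedigree: Pedigree) -> POPSet:
    """Every (parent, offspring) pair with both members sampled.

    Detection is exact (perfect pedigree knowledge, no false pairs) and
    independent of age classes; pairs are tagged by parent sex and by
    whether the offspring is itself mature at the sampled year.
    """
    sampled_pos = pedigree.index_of(sample.ids)
    in_sample = np.zeros(len(pedigree), dtype=bool)
    in_sample[sampled_pos] = True

    mature = pedigree.mature_at(sample.year)
    parents, offspring, sexes, classes = [], [], [], []
    for parent_col, sex_tag in ((pedigree.mother_id, "mother"),
                                (pedigree.father_id, "father")):
        pid = parent_col[sampled_pos]
        known = pid != UNKNOWN_PARENT
        cand = sampled_pos[known]
        ppos = pedigree.index_of(pid[known])
        hit = in_sample[ppos]
        parents.append(pedigree.ids[ppos[hit]])
        offspring.append(pedigree.ids[cand[hit]])
        sexes.append(np.full(int(hit.sum()), sex_tag, dtype=object))
        classes.append(np.where(mature[cand[hit]], "adult-adult",
                                "adult-juvenile").astype(object))
    return POPSet(parent_id=np.concatenate(parents),
                  offspring_id=np.concatenate(offspring),
                  parent_sex=np.concatenate(sexes),
                  pair_class=np.concatenate(classes))


def kin_counts(sample: SampleSet, pops: POPSet, pedigree: Pedigree) -> KinCounts:
    """Tally the sample composition and POP counts the estimators consume.

    Maturity is judged at the sampled year with sex-specific maturity ages.
    """
    pos = pedigree.index_of(sample.ids)
    female = pedigree.female[pos]
    mature = pedigree.mature_at(sample.year)[pos]
    adult_age = pedigree.age_at(sample.year)[pos] >= 2
    n = len(sample.ids)
    n_adult = int(mature.sum())
    n_adult_f = int((mature & female).sum())
    n_adult_age = int(adult_age.sum())

    is_mother = pops.parent_sex == "mother"
    h_mother = int(is_mother.sum())
    h_father = len(pops) - h_mother
    if h_mother:
        dpos = pedigree.index_of(pops.offspring_id[is_mother])
        k_md = int(pedigree.female[dpos].sum())
    else:
        k_md = 0
    return KinCounts(
        n=n,
        n_juv=n - n_adult,
        n_adult=n_adult,
        n_adult_f=n_adult_f,
        n_adult_m=n_adult - n_adult_f,
        n_juv_age=n - n_adult_age,
        n_adult_age=n_adult_age,
        n_f=int(female.sum()),
        h_total=len(pops),
        h_mother=h_mother,
        h_father=h_father,
        k_md=k_md,
    )
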