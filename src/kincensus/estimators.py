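"""Four parent-offspring-pair census-size estimators.

All four treat kinship as recapture: an individual is "recaptured" when the
sample contains a first-order relative.  Because the simulated species have
overlapping generations, a sampled animal can be a parent and an offspring at
once, so kin comparisons are made over *ordered* pairs of sampled
individuals — each parent-offspring pair contributes one comparison per
direction.  The Lincoln-Petersen-type formulas below are written with the
resulting factors of two already cancelled against the ``KinCounts`` pair
tallies (which count each pair once).

* CKMR (naive close-kin mark-recapture) — Lincoln-Petersen on the immature
  vs sexually mature partition with all POPs (adult-adult included) as
  recaptures; targets the adult population.
* g-CMR — Lincoln-Petersen on demographic age classes (juveniles = age < 2)
  inflated by the sampled adult fraction; targets the total population.
* Moment — method-of-moments on the mother-daughter pair frequency among
  sampled females; targets the breeding-female population.
* CRE (Creel-Rosenblatt) — breeders observed in the sample plus unsampled
  parents whose presence the reconstructed pedigree reveals; targets the
  adult population.

Degenerate samples (zero pair counts) yield ``defined=False`` records rather
than exceptions so that batch experiments can tally failure rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import Pedigree, UNKNOWN_PARENT
from .sampling import KinCounts, SampleSet, find_pops, kin_counts

__all__ = ["Estimate", "estimate_ckmr", "estimate_gcmr", "estimate_moment",
           "estimate_cre", "estimate_all", "TARGET_BY_METHOD"]

#: census size each method estimates
TARGET_BY_METHOD = {
    "CKMR": "adult",
    "gCMR": "total",
    "Moment": "breeding_females",
    "CRE": "adult",
}


@dataclass(frozen=True)
class Estimate:
    method: str
    n_hat: float
    target: str
    defined: bool

    @classmethod
    def undefined(cls, method: str) -> "Estimate":
        return cls(method=method, n_hat=float("nan"),
                   target=TARGET_BY_METHOD[method], defined=False)


def estimate_ckmr(counts: KinCounts) -> Estimate:
    """Naive close-kin mark-recapture estimate of adult population size.

    Lincoln-Petersen with the immature animals as the marking sample (each
    offspring marks its two parents) and the sexually mature animals as the
    recapture sample; over ordered comparisons this reduces to
    N_adult = n_juv * n_adult / h_total.  h_total includes adult-adult POPs,
    the overlapping-generations adaptation: a mature animal still marks its
    own (also mature) parents.
    """
    if counts.h_total == 0 or counts.n_juv == 0 or counts.n_adult == 0:
        return Estimate.undefined("CKMR")
    n_hat = counts.n_juv * counts.n_adult / counts.h_total
    return Estimate("CKMR", n_hat, "adult", True)


def estimate_gcmr(counts: KinCounts) -> Estimate:
    """Genetic-CMR estimate of total population size.

    The same ordered-comparison Lincoln-Petersen as CKMR but on demographic
    age classes (juveniles = age < 2, adults = age >= 2), then inflated to
    the whole population by the sampled adult fraction n / n_adult_age
    (valid under uniform sampling); the adult factors cancel:
    N_total = n_juv_age * n / h_total.
    """
    if counts.h_total == 0 or counts.n_juv_age == 0 or counts.n_adult_age == 0:
        return Estimate.undefined("gCMR")
    n_hat = counts.n_juv_age * counts.n / counts.h_total
    return Estimate("gCMR", n_hat, "total", True)


def estimate_moment(counts: KinCounts) -> Estimate:
    """Method-of-moments estimate of the breeding-female population size.

    Based on the frequency of mother-daughter pairs among the
    n_f (n_f - 1) ordered pairs of sampled females:
    N_F = n_f * (n_f - 1) / (4 * k_md).
    """
    if counts.k_md == 0 or counts.n_f < 2:
        return Estimate.undefined("Moment")
    n_hat = counts.n_f * (counts.n_f - 1) / (4.0 * counts.k_md)
    return Estimate("Moment", n_hat, "breeding_females", True)


def estimate_cre(sample: SampleSet, pedigree: Pedigree) -> Estimate:
    """Creel-Rosenblatt estimate of adult population size.

    Counts the breeders evident in the sample — every sampled sexually
    mature individual — plus the distinct unsampled parents whose presence
    pedigree reconstruction reveals: a parent of a sampled offspring is
    inferable when its mate (the other parent) is sampled, or when at least
    two of its offspring are sampled (a sibling group implies a shared
    unsampled parent).
    """
    pos = pedigree.index_of(sample.ids)
    in_sample = np.zeros(len(pedigree), dtype=bool)
    in_sample[pos] = True
    n_breeders_sampled = int(pedigree.mature_at(sample.year)[pos].sum())

    mother = pedigree.mother_id[pos]
    father = pedigree.father_id[pos]
    m_known = mother != UNKNOWN_PARENT
    f_known = father != UNKNOWN_PARENT
    m_sampled = np.zeros(len(pos), dtype=bool)
    f_sampled = np.zeros(len(pos), dtype=bool)
    m_sampled[m_known] = in_sample[pedigree.index_of(mother[m_known])]
    f_sampled[f_known] = in_sample[pedigree.index_of(father[f_known])]

    inferred: set[int] = set()
    for parent, known, own, mate in ((mother, m_known, m_sampled, f_sampled),
                                     (father, f_known, f_sampled, m_sampled)):
        unsampled = known & ~own
        # through a sampled mate and the shared sampled offspring
        inferred.update(parent[unsampled & mate].tolist())
        # through a sampled sibling group (>= 2 offspring in the sample)
        ids, counts_ = np.unique(parent[unsampled], return_counts=True)
        inferred.update(ids[counts_ >= 2].tolist())

    n_hat = n_breeders_sampled + len(inferred)
    if n_hat == 0:
        return Estimate.undefined("CRE")
    return Estimate("CRE", float(n_hat), "adult", True)


def estimate_all(sample: SampleSet, pedigree: Pedigree,
                 counts: KinCounts | None = None) -> list[Estimate]:
    """Run all four estimators on one sample.

    Always returns four records (CKMR, gCMR, Moment, CRE), with
    ``defined=False`` where the sample is degenerate for a method.
    """
    if counts is None:
        pops = find_pops(sample, pedigree)
        counts = kin_counts(sample, pops, pedigree)
    return [
        estimate_ckmr(counts),
        estimate_gcmr(counts),
        estimate_moment(counts),
        estimate_cre(sample, pedigree),
    ]
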