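import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kincensus import (KinCounts, SampleSet, draw_sample, estimate_all,
                       estimate_ckmr, estimate_cre, estimate_gcmr,
                       estimate_moment, find_pops, kin_counts)
from conftest import build_pedigree


def mk_counts(**kw):
    base = dict(n=0, n_juv=0, n_adult=0, n_adult_f=0, n_adult_m=0,
                n_juv_age=0, n_adult_age=0, n_f=0, h_total=0, h_mother=0,
                h_father=0, k_md=0)
    base.update(kw)
    return KinCounts(**base)


class TestFormulas:
    def test_ckmr_arithmetic(self):
        est = estimate_ckmr(mk_counts(n=50, n_juv=20, n_adult=30, h_total=40))
        assert est.defined and est.target == "adult"
        assert est.n_hat == pytest.approx(20 * 30 / 40)

    def test_gcmr_arithmetic(self):
        est = estimate_gcmr(mk_counts(n=100, n_juv_age=30, n_adult_age=70,
                                      h_total=20))
        assert est.defined and est.target == "total"
        assert est.n_hat == pytest.approx(30 * 100 / 20)

    def test_moment_arithmetic(self):
        est = estimate_moment(mk_counts(n_f=11, k_md=10))
        assert est.defined and est.target == "breeding_females"
        assert est.n_hat == pytest.approx(11 * 10 / 40)

    @pytest.mark.parametrize("fn, counts", [
        (estimate_ckmr, mk_counts(n_juv=5, n_adult=5, h_total=0)),
        (estimate_ckmr, mk_counts(n_juv=0, n_adult=5, h_total=3)),
        (estimate_gcmr, mk_counts(n=10, n_juv_age=5, n_adult_age=5, h_total=0)),
        (estimate_moment, mk_counts(n_f=11, k_md=0)),
        (estimate_moment, mk_counts(n_f=1, k_md=2)),
    ])
    def test_degenerate_counts_are_flagged_not_raised(self, fn, counts):
        est = fn(counts)
        assert not est.defined and np.isnan(est.n_hat)

    @pytest.mark.parametrize("c", [2, 5])
    def test_homogeneity_in_sample_scale(self, c):
        # scaling every count and every pair tally by c scales the estimates
        # by c (the Lincoln-Petersen degree-one homogeneity)
        base = mk_counts(n=60, n_juv=25, n_adult=35, n_juv_age=30,
                         n_adult_age=30, n_f=31, h_total=12, k_md=4)
        scaled = mk_counts(n=60 * c, n_juv=25 * c, n_adult=35 * c,
                           n_juv_age=30 * c, n_adult_age=30 * c, n_f=31 * c,
                           h_total=12 * c, k_md=4 * c)
        for fn, tol in ((estimate_ckmr, 0), (estimate_gcmr, 0),
                        (estimate_moment, 0.05)):
            ratio = fn(scaled).n_hat / fn(base).n_hat
            assert ratio == pytest.approx(c, rel=tol or 1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(n_juv=st.integers(0, 400), n_adult=st.integers(0, 400),
           n_f=st.integers(0, 400), h=st.integers(0, 200), k=st.integers(0, 100))
    def test_estimates_are_finite_nonnegative_or_flagged(self, n_juv, n_adult,
                                                         n_f, h, k):
        c = mk_counts(n=n_juv + n_adult, n_juv=n_juv, n_adult=n_adult,
                      n_juv_age=n_juv, n_adult_age=n_adult, n_f=n_f,
                      h_total=h, h_mother=min(h, k), k_md=min(h, k))
        for fn in (estimate_ckmr, estimate_gcmr, estimate_moment):
            est = fn(c)
            if est.defined:
                assert np.isfinite(est.n_hat) and est.n_hat >= 0
            else:
                assert np.isnan(est.n_hat)

    def test_monotone_decreasing_in_pair_counts(self):
        ck = [estimate_ckmr(mk_counts(n_juv=20, n_adult=30, h_total=h)).n_hat
              for h in (10, 20, 40)]
        assert ck[0] > ck[1] > ck[2]
        mo = [estimate_moment(mk_counts(n_f=30, k_md=k)).n_hat for k in (2, 5, 9)]
        assert mo[0] > mo[1] > mo[2]


def one_parent_population(n_adults, n_juveniles, seed, deer_params):
    """Idealized two-generation stand: every juvenile has exactly one living
    parent among the adults; the other parent is unknown (dead before the
    census).  This is the assumption-satisfying limit of the ordered-pair
    Lincoln-Petersen forms: each offspring marks one living breeder.
    """
    rng = np.random.default_rng(seed)
    rows = []
    half = n_adults // 2
    for i in range(1, n_adults + 1):
        rows.append((i, "F" if i <= half else "M", 0, None, 0, 0))
    for j in range(n_adults + 1, n_adults + n_juveniles + 1):
        p = int(rng.integers(1, n_adults + 1))
        mother, father = (p, 0) if p <= half else (0, p)
        rows.append((j, "F" if rng.random() < 0.5 else "M", 9, None,
                     mother, father))
    return build_pedigree(rows, final_year=10, params=deer_params)


class TestGenerativeOracles:
    """Mean recovery of the target size on idealized populations.

    Tolerances are three standard errors of the replicate mean plus a 1%
    allowance for the O(1/E[pairs]) Lincoln-Petersen finite-sample bias.
    """

    def run_reps(self, ped, q, n_reps, pick):
        vals = []
        for r in range(n_reps):
            s = draw_sample(ped, q, seed=r)
            c = kin_counts(s, find_pops(s, ped), ped)
            est = pick(s, c)
            if est.defined:
                vals.append(est.n_hat)
        vals = np.array(vals)
        return vals.mean(), 3 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_ckmr_recovers_adult_count(self, deer_params):
        ped = one_parent_population(100, 300, seed=0, deer_params=deer_params)
        mean, band = self.run_reps(ped, 0.7, 400,
                                   lambda s, c: estimate_ckmr(c))
        assert abs(mean - 100) < band + 1.0

    def test_gcmr_recovers_total_count(self, deer_params):
        ped = one_parent_population(100, 300, seed=1, deer_params=deer_params)
        mean, band = self.run_reps(ped, 0.7, 400,
                                   lambda s, c: estimate_gcmr(c))
        assert abs(mean - 400) < band + 4.0

    def test_moment_recovers_breeding_female_count(self, deer_params):
        # 100 mothers, each with exactly one living daughter
        rows = [(i, "F", 0, None, 0, 0) for i in range(1, 101)]
        rows += [(100 + i, "F", 9, None, i, 0) for i in range(1, 101)]
        # add males so the sample is not all-female
        rows += [(300 + i, "M", 9, None, 0, 0) for i in range(1, 101)]
        ped = build_pedigree(rows, final_year=10, params=deer_params)
        mean, band = self.run_reps(ped, 0.7, 400,
                                   lambda s, c: estimate_moment(c))
        assert abs(mean - 100) < band + 2.0


class TestCRE:
    def test_toy_inference_through_sampled_mate(self, toy_family):
        # sample the mother A, her daughter C, and the unrelated juvenile E:
        # B (C's father) is unsampled but inferable through mate + offspring
        s = SampleSet(ids=np.array([1, 3, 5]), fraction=0.6, year=10, seed=0)
        est = estimate_cre(s, toy_family)
        assert est.defined
        assert est.n_hat == 2  # A sampled breeder + B inferred

    def test_sibling_group_reveals_unsampled_parent(self, toy_family):
        # C and D share mother A; sampling only the offspring still counts A
        s = SampleSet(ids=np.array([3, 4]), fraction=0.4, year=10, seed=0)
        est = estimate_cre(s, toy_family)
        assert est.defined and est.n_hat == 1

    def test_sample_without_breeders_or_kin_is_undefined(self, toy_family):
        s = SampleSet(ids=np.array([5]), fraction=0.2, year=10, seed=0)
        est = estimate_cre(s, toy_family)
        assert not est.defined

    def test_census_limit_counts_adults_exactly(self, deer_params):
        ped = one_parent_population(80, 160, seed=2, deer_params=deer_params)
        s = draw_sample(ped, 1.0, seed=0)
        est = estimate_cre(s, ped)
        assert est.n_hat == 80


class TestEstimateAll:
    def test_returns_four_records_matching_individual_calls(self, deer_pedigree):
        s = draw_sample(deer_pedigree, 0.3, seed=5)
        c = kin_counts(s, find_pops(s, deer_pedigree), deer_pedigree)
        batch = {e.method: e for e in estimate_all(s, deer_pedigree)}
        assert set(batch) == {"CKMR", "gCMR", "Moment", "CRE"}
        assert batch["CKMR"] == estimate_ckmr(c)
        assert batch["gCMR"] == estimate_gcmr(c)
        assert batch["Moment"] == estimate_moment(c)
        assert batch["CRE"] == estimate_cre(s, deer_pedigree)

    def test_degenerate_sample_yields_flagged_records(self, toy_family):
        s = SampleSet(ids=np.array([2, 5]), fraction=0.4, year=10, seed=0)
        ests = estimate_all(s, toy_family)
        assert len(ests) == 4
        assert not any(e.defined for e in ests if e.method != "CRE")
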