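"""Information criterion, candidate enumeration, grid search, allocators."""

import itertools
import math

import numpy as np
import pytest

from twophase_audit import (Design, GridSchedule, SeedStream, Stratum,
                            StratumTable, Theta, adaptive_grid_search,
                            allocate_bcc_star, allocate_cc_star, allocate_srs,
                            draw_wave, enumerate_candidates,
                            fisher_information, run_multiwave, var_beta,
                            var_beta_schur)
from twophase_audit.design import (InformationModel, WavePlan,
                                   cc_star_expected, srs_expected)
from twophase_audit.likelihood import Cohort
from twophase_audit.simulate import SimScenario, generate_cohort, scenario_theta

from conftest import perturbed_thetas

VCCC4 = StratumTable.from_mapping(
    {(0, 0, 0): 504, (0, 1, 0): 1350, (1, 0, 0): 42, (1, 1, 0): 116})
VCCC8 = StratumTable.from_mapping(
    {(0, 0, 0): 171, (0, 1, 0): 701, (1, 0, 0): 34, (1, 1, 0): 93,
     (0, 0, 1): 333, (0, 1, 1): 649, (1, 0, 1): 8, (1, 1, 1): 23})


class TestFisherInformation:
    def test_affine_in_each_pi(self, base_theta, base_spec, toy_strata):
        base_pi = np.array([0.3, 0.4, 0.5, 0.6])
        for s in range(4):
            mats = []
            for val in (0.0, 0.5, 1.0):
                pi = base_pi.copy()
                pi[s] = val
                mats.append(fisher_information(base_theta, base_spec, pi,
                                               toy_strata))
            midpoint = 0.5 * (mats[0] + mats[2])
            np.testing.assert_allclose(mats[1], midpoint, atol=1e-10)

    def test_symmetric_psd(self, base_theta, base_spec, toy_strata):
        for k, th in enumerate(perturbed_thetas(base_theta, base_spec, 10,
                                                seed=3)):
            pi = np.linspace(0.1, 0.9, 4) if k % 2 else np.full(4, 0.5)
            I = fisher_information(th, base_spec, pi, toy_strata)
            np.testing.assert_allclose(I, I.T, atol=1e-12)
            assert np.linalg.eigvalsh(I).min() >= -1e-8

    def test_full_validation_equals_complete_data_information(
            self, base_theta, base_spec, toy_strata):
        # at pi = 1 the unvalidated term vanishes: only E[S_v S_v'] remains
        from twophase_audit.cells import cell_grid
        grid = cell_grid(base_spec)
        flat = base_theta.flatten(base_spec)
        mass = grid.masses(flat, toy_strata.z_dist)
        S = grid.scores_validated(flat)
        complete = (mass[:, None, None] * S[:, :, None] * S[:, None, :]).sum(0)
        I = fisher_information(base_theta, base_spec, np.ones(4), toy_strata)
        np.testing.assert_allclose(I, complete, atol=1e-12)

    def test_matches_monte_carlo_score_outer_products(self, base_spec):
        # simulate subjects, draw V ~ Bernoulli(pi_stratum), average the
        # outer products of the realized per-subject scores
        from twophase_audit.cells import cell_grid
        scenario = SimScenario(N=200_000)
        th = scenario_theta(scenario)
        cohort = generate_cohort(scenario, SeedStream(5).child("cohort", 0))
        strata = cohort.stratum_table()
        pi = np.array([0.05, 0.3, 0.2, 0.5])
        rng = np.random.default_rng(77)
        sid = cohort.record_stratum_ids()
        v = rng.random(len(cohort)) < pi[sid]
        grid = cell_grid(base_spec)
        flat = th.flatten(base_spec)
        cell = grid.cell_index(cohort.y_star, cohort.x_star, cohort.y,
                               cohort.x, cohort.z)
        S = np.where(v[:, None], grid.scores_validated(flat)[cell],
                     grid.scores_unvalidated(flat)[sid])
        outer = S[:, :, None] * S[:, None, :]
        emp = outer.mean(axis=0)
        se = outer.std(axis=0, ddof=1) / math.sqrt(len(cohort))
        I = fisher_information(th, base_spec, pi, strata)
        assert np.all(np.abs(emp - I) < 3.5 * se + 1e-10)


class TestVarBeta:
    def test_schur_equals_full_inverse(self, base_theta, base_spec,
                                       toy_strata):
        rng = np.random.default_rng(9)
        for th in perturbed_thetas(base_theta, base_spec, 50, seed=10):
            alloc = rng.multivariate_hypergeometric(toy_strata.counts, 40)
            d = Design(toy_strata, alloc)
            a = var_beta(th, base_spec, d)
            b = var_beta_schur(th, base_spec, d)
            assert a == pytest.approx(b, rel=1e-10)

    def test_monotone_under_added_validation(self, base_theta, base_spec,
                                             toy_strata):
        # exhaustive: adding one validated subject anywhere never hurts
        designs = enumerate_candidates(toy_strata, 40, m=5, step=1)
        im = InformationModel(base_theta, base_spec, toy_strata)
        base_vars = im.var_beta_many(designs)
        for s in range(4):
            bumped = designs.copy()
            bumped[:, s] += 1
            ok = bumped[:, s] <= toy_strata.counts[s]
            vars_b = im.var_beta_many(bumped[ok])
            assert np.all(vars_b <= base_vars[ok] + 1e-12)

    def test_full_validation_is_best(self, base_theta, base_spec, toy_strata):
        im = InformationModel(base_theta, base_spec, toy_strata)
        full = im.var_beta_many(toy_strata.counts[None, :])[0]
        candidates = enumerate_candidates(toy_strata, 40, m=5, step=1)
        assert full <= im.var_beta_many(candidates).min() + 1e-14

    def test_singular_information_gives_inf_sentinel(self, base_theta,
                                                     base_spec, toy_strata):
        # with no validation at all the information has rank at most the
        # number of strata (4 < 10 parameters): the criterion returns the
        # +inf sentinel so such designs order last rather than raising
        d = Design(toy_strata, np.zeros(4, dtype=int))
        assert var_beta(base_theta, base_spec, d) == math.inf


class TestEnumerateCandidates:
    def test_two_strata_compositions(self):
        st = StratumTable.from_mapping({(0, 0, 0): 10, (0, 1, 0): 10,
                                        (1, 0, 0): 0, (1, 1, 0): 0})
        cands = enumerate_candidates(st, 4, m=1, step=1)
        got = {tuple(row[st.counts > 0]) for row in cands}
        assert got == {(1, 3), (2, 2), (3, 1)}

    def test_three_strata_count_matches_brute_force(self):
        st = StratumTable.from_mapping({(0, 0, 0): 100, (0, 1, 0): 100,
                                        (1, 0, 0): 100, (1, 1, 0): 0})
        cands = enumerate_candidates(st, 6, m=1, step=1)
        brute = [c for c in itertools.product(range(1, 7), repeat=3)
                 if sum(c) == 6 and max(c) <= min(6 - 3 + 1, 100)]
        assert cands.shape[0] == len(brute) == 10

    def test_budget_at_minimum_forces_single_candidate(self, toy_strata):
        cands = enumerate_candidates(toy_strata, 20, m=5, step=1)
        assert cands.shape[0] == 1
        np.testing.assert_array_equal(cands[0], [5, 5, 5, 5])

    def test_candidates_satisfy_constraint_and_bounds(self, toy_strata):
        for step in (1, 3, 7):
            cands = enumerate_candidates(toy_strata, 40, m=5, step=step)
            assert np.all(cands.sum(axis=1) == 40)
            assert np.all(cands >= 5)
            assert np.all(cands <= toy_strata.counts)


class TestAdaptiveGridSearch:
    def test_equals_exhaustive_minimum_on_toy(self, base_theta, base_spec,
                                              toy_strata):
        brute_cands = enumerate_candidates(toy_strata, 40, m=5, step=1)
        for th in perturbed_thetas(base_theta, base_spec, 20, seed=13):
            im = InformationModel(th, base_spec, toy_strata)
            variances = im.var_beta_many(brute_cands)
            if not np.isfinite(variances.min()):
                continue
            best = brute_cands[int(np.argmin(variances))]
            d, trace = adaptive_grid_search(th, base_spec, toy_strata, 40,
                                            GridSchedule((15, 5, 1), m=5))
            assert im.var_beta_many(d.alloc[None, :])[0] == \
                pytest.approx(variances.min(), rel=1e-12)
            np.testing.assert_array_equal(d.alloc, best)

    def test_full_budget_returns_full_validation(self, base_theta, base_spec,
                                                 toy_strata):
        d, _ = adaptive_grid_search(base_theta, base_spec, toy_strata,
                                    toy_strata.N, GridSchedule((15, 5, 1), m=5))
        np.testing.assert_array_equal(d.alloc, toy_strata.counts)

    def test_trace_variance_non_increasing(self, base_theta, base_spec):
        scenario = SimScenario()
        cohort = generate_cohort(scenario, SeedStream(2).child("cohort", 0))
        strata = cohort.stratum_table()
        d, trace = adaptive_grid_search(base_theta, base_spec, strata, 400,
                                        GridSchedule((15, 5, 1), m=10))
        assert np.all(np.diff(trace.best_var) <= 1e-15)
        assert d.n == 400
        assert np.all(d.alloc >= 10)

    def test_optmle_beats_classical_designs_on_criterion(
            self, base_theta, base_spec):
        scenario = SimScenario()
        cohort = generate_cohort(scenario, SeedStream(4).child("cohort", 0))
        strata = cohort.stratum_table()
        opt, _ = adaptive_grid_search(base_theta, base_spec, strata, 400,
                                      GridSchedule((15, 5, 1), m=10))
        v_opt = var_beta(base_theta, base_spec, opt)
        for comparator in (allocate_bcc_star(strata, 400),
                           allocate_cc_star(strata, 400),
                           allocate_srs(strata, 400)):
            assert v_opt <= var_beta(base_theta, base_spec, comparator) + 1e-15

    def test_search_respects_floor(self, base_theta, base_spec):
        scenario = SimScenario()
        cohort = generate_cohort(scenario, SeedStream(6).child("cohort", 0))
        strata = cohort.stratum_table()
        floor = np.array([50, 50, 50, 50])
        d, _ = adaptive_grid_search(base_theta, base_spec, strata, 400,
                                    GridSchedule((25, 5, 1), m=10),
                                    floor=floor)
        assert np.all(d.alloc >= floor)
        assert d.n == 400


class TestAllocators:
    def test_bcc_star_vccc_eight_strata(self):
        d = allocate_bcc_star(VCCC8, 200)
        assert sorted(d.alloc.tolist()) == [8, 23, 28, 28, 28, 28, 28, 29]
        assert d[Stratum(1, 0, 1)] == 8  # smallest stratum taken in full
        assert d[Stratum(1, 1, 1)] == 23

    def test_bcc_star_vccc_four_strata(self):
        d = allocate_bcc_star(VCCC4, 200)
        assert sorted(d.alloc.tolist()) == [42, 52, 53, 53]
        assert d[Stratum(1, 0)] == 42  # (Y*=1, X*=0) taken in full

    def test_bcc_star_equal_strata(self):
        st = StratumTable.from_mapping({(0, 0, 0): 500, (0, 1, 0): 500,
                                        (1, 0, 0): 500, (1, 1, 0): 500})
        np.testing.assert_array_equal(allocate_bcc_star(st, 200).alloc,
                                      [50, 50, 50, 50])

    def test_srs_expected_matches_stratum_shares(self):
        np.testing.assert_allclose(srs_expected(VCCC4, 200),
                                   [50.1, 134.2, 4.2, 11.5], atol=0.05)
        st = StratumTable.from_mapping({(0, 0, 0): 300, (0, 1, 0): 300,
                                        (1, 0, 0): 300, (1, 1, 0): 300})
        np.testing.assert_allclose(srs_expected(st, 100), 25.0)
        np.testing.assert_array_equal(allocate_srs(st, st.N).alloc, st.counts)

    def test_cc_star_expected_matches_margin_shares(self):
        np.testing.assert_allclose(cc_star_expected(VCCC4, 200),
                                   [27.2, 72.8, 26.6, 73.4], atol=0.05)

    def test_cc_star_equal_halves_and_cap(self):
        margins = VCCC4.counts.reshape(2, 2).sum(axis=1)
        d = allocate_cc_star(VCCC4, 200)
        assert d.alloc[:2].sum() == 100 and d.alloc[2:].sum() == 100
        small = StratumTable.from_mapping({(0, 0, 0): 1000, (0, 1, 0): 1000,
                                           (1, 0, 0): 20, (1, 1, 0): 10})
        d2 = allocate_cc_star(small, 200)
        assert d2.alloc[2:].sum() == 30 and d2.alloc[:2].sum() == 170

    def test_cc_star_odd_budget_extra_to_ystar0(self):
        d = allocate_cc_star(VCCC4, 201)
        assert d.alloc[:2].sum() == 101 and d.alloc[2:].sum() == 100

    def test_infeasible_budget_raises(self):
        from twophase_audit.design import InfeasibleDesignError
        with pytest.raises(InfeasibleDesignError):
            allocate_srs(VCCC4, VCCC4.N + 1)


class TestDrawWave:
    def test_counts_match_design_and_reproducible(self):
        scenario = SimScenario(N=2000, n=200)
        cohort = generate_cohort(scenario, SeedStream(8).child("cohort", 0))
        strata = cohort.stratum_table()
        d = allocate_bcc_star(strata, 200)
        none = np.zeros(len(cohort), dtype=bool)
        a = draw_wave(cohort, d, none, SeedStream(8).child("strat", 0))
        b = draw_wave(cohort, d, none, SeedStream(8).child("strat", 0))
        assert np.array_equal(a, b)
        sid = cohort.record_stratum_ids()
        realized = np.bincount(sid[a], minlength=4)
        np.testing.assert_array_equal(realized, d.alloc)

    def test_full_table_validates_everyone(self):
        scenario = SimScenario(N=500, n=100)
        cohort = generate_cohort(scenario, SeedStream(9).child("cohort", 0))
        strata = cohort.stratum_table()
        v = draw_wave(cohort, strata.counts, np.zeros(len(cohort), dtype=bool),
                      SeedStream(9).child("strat", 0))
        assert v.all()

    def test_shortfall_names_stratum(self):
        from twophase_audit.design import InfeasibleDesignError
        scenario = SimScenario(N=500, n=100)
        cohort = generate_cohort(scenario, SeedStream(10).child("cohort", 0))
        too_many = cohort.stratum_table().counts + 1
        with pytest.raises(InfeasibleDesignError, match="stratum"):
            draw_wave(cohort, too_many, np.zeros(len(cohort), dtype=bool),
                      SeedStream(10).child("strat", 0))


class TestMultiwave:
    def test_single_wave_plan_equals_allocator(self):
        scenario = SimScenario(N=4000, n=200)
        cohort = generate_cohort(scenario, SeedStream(11).child("cohort", 0))
        res = run_multiwave(cohort, scenario.model_spec(), WavePlan((200,)),
                            rng=SeedStream(11).child("mw2", 0),
                            compute_se=False)
        expected = allocate_bcc_star(cohort.stratum_table(), 200)
        np.testing.assert_array_equal(res.designs[0].alloc, expected.alloc)
        assert res.cohort.n_validated == 200

    def test_two_waves_respect_cumulative_budget_and_floor(self):
        scenario = SimScenario()
        cohort = generate_cohort(scenario, SeedStream(12).child("cohort", 0))
        res = run_multiwave(cohort, scenario.model_spec(),
                            WavePlan((200, 200)),
                            schedule=GridSchedule((25, 5, 1), m=10),
                            rng=SeedStream(12).child("mw2", 0),
                            compute_se=False)
        assert res.cohort.n_validated == 400
        wave1 = res.designs[0].alloc
        final = res.designs[-1].alloc
        assert np.all(final >= wave1)
        assert final.sum() == 400
        assert res.fit.converged
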