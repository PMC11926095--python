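"""Unit and property tests for the mixed-membership block model core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogsoc import (
    MMSBMParams,
    MixedMembershipSBM,
    align_labels,
    e_step,
    fit_em,
    init_params,
    log_likelihood,
    m_step,
    predict,
    score_probability,
)
from cogsoc.mmsbm import DegenerateParameterError, DegenerateRowWarning
from cogsoc.ratings import RatingsTable

from _oracles import bf_e_step, bf_log_likelihood, bf_m_step, bf_score_probability
from conftest import random_links, random_params, table_from_links


class TestInitParams:
    def test_rows_are_simplex_points(self):
        params = init_params(7, 4, 3, 2, seed=0)
        assert np.allclose(params.theta.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(params.eta.sum(axis=1), 1, atol=1e-12)
        assert np.allclose(params.p.sum(axis=2), 1, atol=1e-12)

    def test_strictly_positive(self):
        params = init_params(50, 20, 5, 5, seed=3)
        assert (params.theta > 0).all()
        assert (params.eta > 0).all()
        assert (params.p > 0).all()

    def test_single_group_forced_to_one(self):
        params = init_params(4, 3, 1, 1, seed=1)
        assert np.allclose(params.theta, 1.0)
        assert np.allclose(params.eta, 1.0)

    def test_deterministic_given_seed(self):
        a = init_params(5, 5, 2, 3, seed=9)
        b = init_params(5, 5, 2, 3, seed=9)
        assert np.array_equal(a.theta, b.theta)
        assert np.array_equal(a.p, b.p)

    @pytest.mark.parametrize("dims", [(0, 1, 1, 1), (1, 1, 0, 1), (1, -2, 1, 1)])
    def test_rejects_nonpositive_dimensions(self, dims):
        with pytest.raises(ValueError):
            init_params(*dims, seed=0)


class TestScoreProbability:
    def test_single_group_collapses_to_p(self, rng):
        params = random_params(2, 2, 1, 1, rng)
        for s in range(1, 6):
            assert score_probability(params, 0, 0, s) == pytest.approx(
                params.p[0, 0, s - 1], abs=1e-15
            )

    def test_one_hot_collapse(self, rng):
        params = random_params(3, 3, 2, 2, rng)
        params.theta[0] = [1.0, 0.0]
        params.eta[1] = [0.0, 1.0]
        assert score_probability(params, 0, 1, 4) == pytest.approx(
            params.p[0, 1, 3], abs=1e-15
        )

    def test_matches_four_term_enumeration(self, rng):
        params = random_params(1, 1, 2, 2, rng)
        params.theta[0] = [0.3, 0.7]
        params.eta[0] = [0.6, 0.4]
        for s in range(1, 6):
            assert score_probability(params, 0, 0, s) == pytest.approx(
                bf_score_probability(params.theta[0], params.eta[0], params.p, s),
                abs=1e-14,
            )

    def test_distribution_normalized(self, rng):
        params = random_params(4, 4, 3, 2, rng)
        dist = score_probability(params, 2, 3)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestLogLikelihood:
    def test_empty_table_gives_zero(self):
        table = RatingsTable.from_links([], users=["u0"], tasks=["t0"])
        params = init_params(1, 1, 2, 2, seed=0)
        assert log_likelihood(params, table) == 0.0

    def test_single_one_hot_link(self, rng):
        params = random_params(1, 1, 2, 2, rng)
        params.theta[0] = [0.0, 1.0]
        params.eta[0] = [1.0, 0.0]
        table = table_from_links([(0, 0, 3)], 1, 1)
        assert log_likelihood(params, table) == pytest.approx(
            np.log(params.p[1, 0, 2]), abs=1e-12
        )

    def test_matches_bruteforce_on_small_instance(self, rng):
        links = random_links(3, 2, rng)[:5]
        params = random_params(3, 2, 2, 2, rng)
        table = table_from_links(links, 3, 2)
        expected = bf_log_likelihood(params.theta, params.eta, params.p, links)
        assert log_likelihood(params, table) == pytest.approx(expected, abs=1e-12)


class TestEStep:
    def test_single_cell_gives_unit_mass(self, rng):
        params = random_params(2, 2, 1, 1, rng)
        table = table_from_links([(0, 0, 1), (1, 1, 5)], 2, 2)
        omega = e_step(params, table)
        assert np.allclose(omega, 1.0)

    def test_constant_p_factorizes_into_memberships(self, rng):
        params = random_params(3, 3, 2, 3, rng)
        params.p[:] = params.p[0, 0]          # identical law for every (k, l)
        table = table_from_links([(0, 1, 2), (2, 0, 4)], 3, 3)
        omega = e_step(params, table)
        for i, (u, t, _) in enumerate([(0, 1, 2), (2, 0, 4)]):
            expected = np.outer(params.theta[u], params.eta[t])
            assert np.allclose(omega[i], expected, atol=1e-12)

    def test_matches_bruteforce_normalization(self, rng):
        links = random_links(4, 3, rng)
        params = random_params(4, 3, 2, 2, rng)
        table = table_from_links(links, 4, 3)
        omega = e_step(params, table)
        for slab, expected in zip(omega, bf_e_step(params.theta, params.eta,
                                                   params.p, links)):
            assert np.abs(slab - expected).max() < 1e-12

    def test_zero_probability_link_raises(self):
        params = init_params(1, 1, 2, 2, seed=0)
        params.p[:, :, 0] = 0.0               # score 1 impossible everywhere
        table = table_from_links([(0, 0, 1)], 1, 1)
        with pytest.raises(DegenerateParameterError):
            e_step(params, table)


class TestMStep:
    def test_point_mass_omega_concentrates_memberships(self):
        links = [(0, 0, 2), (0, 1, 3), (1, 0, 4), (1, 1, 1)]
        table = table_from_links(links, 2, 2)
        omega = np.zeros((4, 2, 2))
        omega[:, 1, 0] = 1.0                  # all mass on (k=1, l=0)
        with pytest.warns(DegenerateRowWarning):   # other (k,l) cells empty
            params = m_step(omega, table, 2, 2)
        assert np.allclose(params.theta[:, 1], 1.0)
        assert np.allclose(params.eta[:, 0], 1.0)

    def test_uniform_omega_gives_uniform_memberships(self):
        links = [(0, 0, 1), (1, 0, 5)]
        table = table_from_links(links, 2, 1)
        omega = np.full((2, 2, 2), 0.25)
        params = m_step(omega, table, 2, 1)
        assert np.allclose(params.theta, 0.5)

    def test_matches_bruteforce_update_sums(self, rng):
        links = [(0, 0, 1), (0, 1, 3), (1, 0, 2), (1, 1, 5), (2, 0, 4), (2, 1, 4)]
        table = table_from_links(links, 3, 2)
        omega = rng.dirichlet(np.ones(4), size=6).reshape(6, 2, 2)
        params = m_step(omega, table, 3, 2)
        theta, eta, p = bf_m_step(list(omega), links, 3, 2, 2, 2)
        assert np.abs(params.theta - theta).max() < 1e-12
        assert np.abs(params.eta - eta).max() < 1e-12
        assert np.abs(params.p - p).max() < 1e-12

    def test_zero_degree_user_flagged_uniform(self):
        links = [(0, 0, 2)]
        table = table_from_links(links, 2, 1)    # user u1 has no links
        omega = np.full((1, 2, 2), 0.25)
        with pytest.warns(DegenerateRowWarning):
            params = m_step(omega, table, 2, 1)
        assert np.allclose(params.theta[1], 0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_outputs_always_normalized(self, seed):
        rng = np.random.default_rng(seed)
        U, T = int(rng.integers(2, 5)), int(rng.integers(2, 4))
        links = random_links(U, T, rng)
        table = table_from_links(links, U, T)
        omega = rng.dirichlet(np.ones(6), size=len(links)).reshape(len(links), 2, 3)
        params = m_step(omega, table, U, T)
        params.validate(atol=1e-12)


class TestFitEM:
    def test_trace_monotone_on_random_instances(self, rng):
        for i in range(10):
            U, T = int(rng.integers(3, 8)), int(rng.integers(2, 5))
            links = random_links(U, T, rng)
            table = table_from_links(links, U, T)
            res = fit_em(table, 2, 2, seed=i, max_iter=60, n_restarts=1)
            assert np.all(np.diff(res.loglik_trace) >= -1e-9)

    def test_constant_scores_collapse_p_to_point_mass(self, rng):
        links = [(u, t, 4) for u in range(6) for t in range(4)]
        table = table_from_links(links, 6, 4)
        res = fit_em(table, 2, 3, seed=0, max_iter=200, n_restarts=2)
        assert np.allclose(res.params.p[:, :, 3], 1.0, atol=1e-9)

    def test_best_restart_selected(self, planted_ratings):
        res = fit_em(planted_ratings, 3, 3, seed=0, max_iter=80, n_restarts=3,
                     tol=1e-5)
        assert res.loglik == pytest.approx(res.restart_logliks.max())

    def test_rejects_bad_arguments(self, planted_ratings):
        with pytest.raises(ValueError):
            fit_em(planted_ratings, 3, 3, max_iter=0)
        with pytest.raises(ValueError):
            fit_em(planted_ratings, 3, 3, tol=0.0)


class TestAlignLabels:
    def test_inverse_permutation_recovers_reference(self, rng):
        ref = random_params(6, 4, 3, 3, rng)
        cand = MMSBMParams(
            theta=ref.theta[:, [1, 0, 2]],
            eta=ref.eta[:, [2, 1, 0]],
            p=ref.p[np.ix_([1, 0, 2], [2, 1, 0])],
        )
        aligned = align_labels(ref, cand)
        assert np.allclose(aligned.p, ref.p, atol=1e-15)
        assert np.allclose(aligned.theta, ref.theta, atol=1e-15)

    def test_identity_when_already_aligned(self, rng):
        ref = random_params(4, 4, 2, 2, rng)
        aligned = align_labels(ref, ref.copy())
        assert np.allclose(aligned.p, ref.p)

    def test_matches_exhaustive_permutation_search(self, rng):
        import itertools

        ref = random_params(5, 5, 3, 3, rng)
        cand = random_params(5, 5, 3, 3, rng)
        best_cost = min(
            np.abs(ref.p - cand.p[np.ix_(kp, lp)]).sum()
            for kp in itertools.permutations(range(3))
            for lp in itertools.permutations(range(3))
        )
        aligned = align_labels(ref, cand)
        assert np.abs(ref.p - aligned.p).sum() == pytest.approx(best_cost, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            align_labels(random_params(2, 2, 2, 2, rng), random_params(2, 2, 3, 2, rng))


class TestPredict:
    def test_point_mass_tensor_predicts_that_score(self, rng):
        params = random_params(3, 3, 2, 2, rng)
        params.p[:] = 0.0
        params.p[:, :, 3] = 1.0
        proba, modal = predict(params, [0, 1, 2], [0, 1, 2])
        assert (modal == 4).all()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_modal_matches_enumeration(self, rng):
        params = random_params(4, 4, 3, 2, rng)
        _, modal = predict(params, [1], [2])
        dist = [bf_score_probability(params.theta[1], params.eta[2], params.p, s)
                for s in range(1, 6)]
        assert modal[0] == int(np.argmax(dist)) + 1

    def test_ties_break_toward_lower_score(self):
        p = np.zeros((1, 1, 5))
        p[0, 0, 1] = 0.5
        p[0, 0, 3] = 0.5                      # scores 2 and 4 tie exactly
        params = MMSBMParams(np.ones((1, 1)), np.ones((1, 1)), p)
        _, modal = predict(params, [0], [0])
        assert modal[0] == 2


class TestEstimator:
    def test_fit_sets_sklearn_style_attributes(self, planted_ratings):
        model = MixedMembershipSBM(3, 3, n_restarts=1, max_iter=40, tol=1e-4,
                                   random_state=0).fit(planted_ratings)
        assert model.theta_.shape == (planted_ratings.n_users, 3)
        assert model.p_.shape == (3, 3, 5)
        assert np.all(np.diff(model.loglik_trace_) >= -1e-9)

    def test_get_set_params_roundtrip(self):
        model = MixedMembershipSBM(4, 2, n_restarts=7)
        params = model.get_params()
        assert params["n_user_groups"] == 4 and params["n_restarts"] == 7
        model.set_params(n_task_groups=5)
        assert model.n_task_groups == 5

    def test_predict_on_id_pairs(self, planted_ratings):
        model = MixedMembershipSBM(2, 2, n_restarts=1, max_iter=30, tol=1e-4,
                                   random_state=1).fit(planted_ratings)
        frame = planted_ratings.to_frame().head(10)
        preds = model.predict(frame)
        assert preds.shape == (10,)
        assert set(preds) <= {1, 2, 3, 4, 5}

    def test_unknown_id_rejected(self, planted_ratings):
        model = MixedMembershipSBM(2, 2, n_restarts=1, max_iter=20, tol=1e-3,
                                   random_state=1).fit(planted_ratings)
        import pandas as pd

        with pytest.raises(KeyError):
            model.predict(pd.DataFrame({"user_id": ["nope"], "task_id": ["t00"]}))
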