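"""Unit tests for the z-score event-based mixture model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import zsustain as zs
from zsustain.model import (
    _DataCache,
    is_valid_order,
    random_sequence,
    stage_expectations,
)


# ---------------------------------------------------------------------------
# expected_value
# ---------------------------------------------------------------------------


class TestExpectedValue:
    def test_stage_zero_is_zero_everywhere(self, spec17, rng):
        order = random_sequence(spec17, rng)
        S = stage_expectations(order, spec17)
        assert np.all(S[0] == 0.0)

    def test_waypoint_positions_are_exact(self, spec17, rng):
        order = random_sequence(spec17, rng)
        W = spec17.n_waypoints
        for i, e in enumerate(order):
            b, j = divmod(int(e), W)
            val = zs.expected_value(order, i + 1, b, spec17)
            assert val == pytest.approx(spec17.waypoints[j], abs=1e-12)

    def test_toy_midpoint_interpolation(self):
        # E=4; biomarker "b" has waypoints {1,2} at positions 2 and 4, so the
        # z_max anchor collides with the last waypoint and is dropped:
        # stage 1 interpolates (0,0)-(2,1) -> 0.5
        spec = zs.ZScoreEventModelSpec(
            biomarkers=("a", "b"), waypoints=(1.0, 2.0), z_max=3.0
        )
        seq = zs.EventSequence((("a", 1.0), ("b", 1.0), ("a", 2.0), ("b", 2.0)))
        assert zs.expected_value(seq, 1, "b", spec) == pytest.approx(0.5)
        assert zs.expected_value(seq, 4, "b", spec) == pytest.approx(2.0)
        # biomarker "a" ends at position 3 < E, so it rises to z_max at E
        assert zs.expected_value(seq, 4, "a", spec) == pytest.approx(3.0)

    def test_monotone_and_bounded(self, spec17):
        rng = np.random.default_rng(7)
        for _ in range(20):
            S = stage_expectations(random_sequence(spec17, rng), spec17)
            assert np.all(np.diff(S, axis=0) >= -1e-12)
            assert S.min() >= 0.0 and S.max() <= spec17.z_max + 1e-12

    def test_invalid_sequence_rejected(self, toy_spec3):
        with pytest.raises(ValueError):
            zs.expected_value(np.array([0, 0, 1]), 1, "a", toy_spec3)
        with pytest.raises(ValueError):
            zs.expected_value(np.array([0, 1, 2]), 99, "a", toy_spec3)


# ---------------------------------------------------------------------------
# subject_loglik / mixture_loglik
# ---------------------------------------------------------------------------


class TestLoglik:
    def test_single_event_closed_form(self):
        # one biomarker, one waypoint z=1, sigma=1, datum 0:
        # log( (phi(0)+phi(-1))/2 ) with phi the standard normal pdf
        spec = zs.ZScoreEventModelSpec(biomarkers=("b",), waypoints=(1.0,), z_max=1.0)
        seq = zs.EventSequence((("b", 1.0),))
        expected = math.log(
            0.5
            * (1.0 + math.exp(-0.5))
            / math.sqrt(2 * math.pi)
        )
        assert zs.subject_loglik(np.array([0.0]), seq, spec) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_naive_stage_sum(self):
        spec = zs.ZScoreEventModelSpec(
            biomarkers=("a", "b", "c"), waypoints=(1.0, 2.0), z_max=4.0, sigma=1.3
        )
        rng = np.random.default_rng(3)
        order = random_sequence(spec, rng)
        S = stage_expectations(order, spec)
        X = rng.normal(0, 2, (20, 3))
        sig = spec.sigma_array
        for row in X:
            naive = 0.0
            terms = []
            for k in range(spec.n_events + 1):
                logp = sum(
                    -0.5 * math.log(2 * math.pi)
                    - math.log(sig[b])
                    - 0.5 * ((row[b] - S[k, b]) / sig[b]) ** 2
                    for b in range(3)
                )
                terms.append(logp)
            m = max(terms)
            naive = m + math.log(sum(math.exp(t - m) for t in terms)) - math.log(
                spec.n_events + 1
            )
            assert zs.subject_loglik(row, order, spec) == pytest.approx(naive, abs=1e-10)

    def test_relabeling_symmetry(self, rng):
        spec = zs.ZScoreEventModelSpec(
            biomarkers=("a", "b", "c"), waypoints=(1.0, 2.0), z_max=4.0
        )
        order = random_sequence(spec, rng)
        X = rng.normal(0, 1, (15, 3))
        # swap biomarkers a <-> c in both the data and the sequence
        perm = [2, 1, 0]
        W = spec.n_waypoints
        b_of, j_of = order // W, order % W
        order_sw = np.array([perm[b] * W + j for b, j in zip(b_of, j_of)])
        lls = zs.subject_loglik(X, order, spec)
        lls_sw = zs.subject_loglik(X[:, perm], order_sw, spec)
        np.testing.assert_allclose(lls, lls_sw, atol=1e-12)

    def test_nonfinite_input_rejected(self, toy_spec3):
        with pytest.raises(ValueError):
            zs.subject_loglik(np.array([np.nan, 0.0, 0.0]), np.array([0, 1, 2]), toy_spec3)

    def test_mixture_k1_equals_subject_sum(self, toy_spec3, rng):
        X = rng.normal(0, 1, (30, 3))
        order = np.array([0, 1, 2])
        model = zs.SubtypeModel(
            spec=toy_spec3, orders=[order], fractions=np.array([1.0]), log_likelihood=0.0
        )
        total = zs.mixture_loglik(X, model)
        assert total == pytest.approx(float(zs.subject_loglik(X, order, toy_spec3).sum()))

    def test_mixture_duplicate_sequence_collapses(self, toy_spec3, rng):
        X = rng.normal(0, 1, (30, 3))
        order = np.array([1, 0, 2])
        m1 = zs.SubtypeModel(
            spec=toy_spec3, orders=[order], fractions=np.array([1.0]), log_likelihood=0.0
        )
        m2 = zs.SubtypeModel(
            spec=toy_spec3,
            orders=[order, order.copy()],
            fractions=np.array([0.5, 0.5]),
            log_likelihood=0.0,
        )
        assert zs.mixture_loglik(X, m2) == pytest.approx(zs.mixture_loglik(X, m1))

    def test_mixture_matches_hand_expansion(self, toy_spec3):
        X = np.array([[0.2, 1.1, -0.3], [1.5, 0.1, 0.9]])
        o1, o2 = np.array([0, 1, 2]), np.array([2, 1, 0])
        f = np.array([0.3, 0.7])
        model = zs.SubtypeModel(
            spec=toy_spec3, orders=[o1, o2], fractions=f, log_likelihood=0.0
        )
        by_hand = sum(
            math.log(
                f[0] * math.exp(zs.subject_loglik(row, o1, toy_spec3))
                + f[1] * math.exp(zs.subject_loglik(row, o2, toy_spec3))
            )
            for row in X
        )
        assert zs.mixture_loglik(X, model) == pytest.approx(by_hand, abs=1e-10)


# ---------------------------------------------------------------------------
# sequence sampling and validity
# ---------------------------------------------------------------------------


@given(st.integers(0, 10_000))
def test_random_sequences_are_valid(seed):
    spec = zs.event_spec_for()
    order = random_sequence(spec, np.random.default_rng(seed))
    assert is_valid_order(order, spec)


def test_event_sequence_round_trip(spec17):
    t1, _ = zs.default_trajectories()
    order = t1.to_order(spec17)
    assert zs.EventSequence.from_order(order, spec17) == t1


def test_event_sequence_rejects_disorder(toy_spec3):
    spec = zs.ZScoreEventModelSpec(biomarkers=("a", "b"), waypoints=(1.0, 2.0), z_max=3.0)
    with pytest.raises(ValueError):
        zs.EventSequence((("a", 2.0), ("a", 1.0), ("b", 1.0), ("b", 2.0))).validate(spec)
    with pytest.raises(ValueError):
        zs.EventSequence((("a", 1.0), ("a", 1.0), ("b", 1.0), ("b", 2.0))).validate(spec)


# ---------------------------------------------------------------------------
# EM, MCMC, fit, assign
# ---------------------------------------------------------------------------


def _planted_toy(rng, n=300, noise=0.0):
    spec = zs.ZScoreEventModelSpec(
        biomarkers=("a", "b", "c"), waypoints=(1.0, 2.0), z_max=3.0
    )
    truth = zs.EventSequence(
        (("b", 1.0), ("a", 1.0), ("b", 2.0), ("c", 1.0), ("a", 2.0), ("c", 2.0))
    )
    order = truth.to_order(spec)
    S = stage_expectations(order, spec)
    stages = rng.integers(0, spec.n_events + 1, n)
    X = S[stages] + rng.normal(0, noise, (n, 3)) if noise else S[stages]
    return spec, order, stages, X


class TestInference:
    def test_em_k1_recovers_noise_free_sequence(self, rng):
        spec, order, _, X = _planted_toy(rng)
        model = zs.optimize_sequences_em(X, 1, spec, n_starts=3, seed=1)
        assert np.array_equal(model.orders[0], order)
        assert model.fractions == pytest.approx([1.0])

    def test_em_fractions_sum_to_one(self, rng):
        spec, _, _, X = _planted_toy(rng, noise=0.8)
        model = zs.optimize_sequences_em(X, 2, spec, n_starts=2, seed=2)
        assert model.fractions.sum() == pytest.approx(1.0)

    def test_em_rejects_k_larger_than_n(self, toy_spec3, rng):
        X = rng.normal(0, 1, (3, 3))
        with pytest.raises(ValueError):
            zs.optimize_sequences_em(X, 5, toy_spec3, n_starts=1, seed=0)

    def test_em_separates_two_planted_subtypes(self):
        # two well-separated 8-event sequences; direct (non-hierarchical) EM
        from scipy.stats import kendalltau

        rng = np.random.default_rng(5)
        spec = zs.ZScoreEventModelSpec(
            biomarkers=tuple("abcdefgh"), waypoints=(1.0,), z_max=3.0
        )
        o1 = np.arange(8)
        o2 = np.arange(8)[::-1].copy()
        S1, S2 = stage_expectations(o1, spec), stage_expectations(o2, spec)
        n = 400
        lab = (rng.random(n) < 0.4).astype(int)
        stages = rng.integers(0, 9, n)
        X = np.where(lab[:, None] == 0, S1[stages], S2[stages]) + rng.normal(
            0, 1.0, (n, 8)
        )
        model = zs.optimize_sequences_em(X, 2, spec, n_starts=5, seed=6)
        taus = []
        for planted in (o1, o2):
            taus.append(
                max(
                    kendalltau(
                        np.argsort(planted), np.argsort(model.orders[c])
                    )[0]
                    for c in range(2)
                )
            )
        assert min(taus) >= 0.8

    def test_mcmc_archive_all_valid_and_deterministic(self, rng):
        spec, order, _, X = _planted_toy(rng, noise=1.0)
        init = zs.optimize_sequences_em(X, 1, spec, n_starts=1, seed=3)
        m_a = zs.mcmc_sequences(X, init, spec, n_iter=400, seed=9)
        m_b = zs.mcmc_sequences(X, init, spec, n_iter=400, seed=9)
        np.testing.assert_array_equal(m_a.mcmc_orders, m_b.mcmc_orders)
        np.testing.assert_array_equal(m_a.mcmc_loglik, m_b.mcmc_loglik)
        for t in range(0, 400, 37):
            assert is_valid_order(m_a.mcmc_orders[t, 0].astype(np.int64), spec)

    def test_mcmc_rejects_zero_iterations(self, toy_spec3, rng):
        X = rng.normal(0, 1, (20, 3))
        model = zs.optimize_sequences_em(X, 1, toy_spec3, n_starts=1, seed=0)
        with pytest.raises(ValueError):
            zs.mcmc_sequences(X, model, toy_spec3, n_iter=0, seed=0)

    def test_fit_k1_single_sequence_full_fraction(self, rng):
        spec, order, _, X = _planted_toy(rng, noise=0.5)
        model = zs.fit(X, 1, spec, zs.FitSettings(n_starts=2, n_mcmc=300), seed=4)
        assert model.n_subtypes == 1
        assert model.fractions == pytest.approx([1.0])

    def test_fit_loglik_non_decreasing_in_k(self, rng):
        spec, _, _, X = _planted_toy(rng, noise=1.0)
        settings = zs.FitSettings(n_starts=2, n_mcmc=200, split_restarts=3)
        levels = zs.fit(X, 2, spec, settings, seed=8, return_levels=True)
        assert levels[2].log_likelihood >= levels[1].log_likelihood - 1e-6

    def test_assign_exact_profiles(self, rng):
        spec, order, _, _ = _planted_toy(rng)
        S = stage_expectations(order, spec)
        o2 = random_sequence(spec, np.random.default_rng(11))
        model = zs.SubtypeModel(
            spec=spec,
            orders=[order, o2],
            fractions=np.array([0.5, 0.5]),
            log_likelihood=1.0,
        )
        k = 4
        X = np.vstack([S[k], np.zeros(3)])
        asg = zs.assign(X, model)
        assert asg.labels[0] == 0
        assert asg.stages[0] == k
        # an all-zero z-row sits at stage 0 under every subtype
        assert asg.stages[1] == 0
        np.testing.assert_allclose(asg.stage_posterior.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(asg.proba.sum(axis=1), 1.0, atol=1e-12)

    def test_assign_requires_fitted_model(self, toy_spec3):
        model = zs.SubtypeModel(
            spec=toy_spec3, orders=[np.array([0, 1, 2])], fractions=np.array([1.0])
        )
        with pytest.raises(ValueError):
            zs.assign(np.zeros((2, 3)), model)

    def test_model_json_round_trip(self, rng):
        spec, order, _, X = _planted_toy(rng, noise=0.7)
        model = zs.optimize_sequences_em(X, 1, spec, n_starts=1, seed=12)
        clone = zs.SubtypeModel.from_dict(model.to_dict())
        assert np.array_equal(clone.orders[0], model.orders[0])
        assert clone.fractions == pytest.approx(model.fractions)
        assert clone.log_likelihood == pytest.approx(model.log_likelihood)
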