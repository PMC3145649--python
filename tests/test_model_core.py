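import numpy as np
import pytest
from scipy.stats import norm

from nbel.model_core import (
    Hyperparams,
    MixtureState,
    ScoreMatrix,
    classify,
    mixture_density,
    normalize_columns,
    posterior_interaction_prob,
)


def make_state(pi, tau, mu0loc, delta, nu=0.5):
    st = MixtureState(pi=np.asarray(pi), tau=np.asarray(tau),
                      mu0loc=np.asarray(mu0loc), delta=np.asarray(delta), nu=nu)
    st.validate()
    return st


class TestScoreMatrix:
    def test_rejects_nonfinite_scores(self):
        with pytest.raises(ValueError, match="non-finite"):
            ScoreMatrix(["a", "b"], np.array([[1.0, 2.0], [np.nan, 0.0]]))

    def test_rejects_id_length_mismatch(self):
        with pytest.raises(ValueError):
            ScoreMatrix(["a"], np.ones((2, 2)))


class TestNormalize:
    def test_small_column_standardised_with_sample_variance(self):
        # sample sd of (1,2,3) is exactly 1, so the column maps to (-1,0,1)
        sm = ScoreMatrix(["a", "b", "c"], np.array([[1.0], [2.0], [3.0]]))
        out = normalize_columns(sm)
        np.testing.assert_allclose(out.scores[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)
        assert out.normalized and not sm.normalized

    def test_columns_have_zero_mean_unit_variance(self, rng):
        sm = ScoreMatrix(list(range(50)), rng.normal(3.0, 2.5, size=(50, 3)))
        out = normalize_columns(sm)
        np.testing.assert_allclose(out.scores.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.scores.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_already_standardised_column_unchanged(self, rng):
        x = rng.normal(size=(40, 1))
        x = (x - x.mean()) / x.std(ddof=1)
        out = normalize_columns(ScoreMatrix(list(range(40)), x))
        np.testing.assert_allclose(out.scores, x, atol=1e-8)

    def test_constant_column_errors_naming_column(self):
        sm = ScoreMatrix(["a", "b", "c"], np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        with pytest.raises(ValueError, match="column 1"):
            normalize_columns(sm)

    def test_double_normalization_rejected(self, rng):
        sm = normalize_columns(ScoreMatrix(list(range(10)), rng.normal(size=(10, 2))))
        with pytest.raises(ValueError, match="already"):
            normalize_columns(sm)

    def test_log_transform_requires_positive(self):
        sm = ScoreMatrix(["a", "b"], np.array([[1.0], [-2.0]]))
        with pytest.raises(ValueError, match="positive"):
            normalize_columns(sm, log_transform=True)


class TestMixtureDensity:
    def test_single_standard_normal_component(self):
        st = make_state([1.0], [1.0], [[0.0]], [[0.0]])
        assert mixture_density(0.0, 0, 0, st) == pytest.approx(0.3989422804, abs=1e-6)

    def test_zero_offsets_collapse_statuses(self, rng):
        st = make_state([0.3, 0.7], [1.0, 2.5], [[-1.0], [0.5]], [[0.0], [0.0]])
        for y in rng.normal(size=10):
            assert mixture_density(y, 0, 0, st) == pytest.approx(mixture_density(y, 0, 1, st))

    def test_matches_bruteforce_component_sum(self, rng):
        H, p = 5, 3
        st = make_state(np.full(H, 0.2), rng.gamma(2, 1, H) + 0.1,
                        rng.normal(size=(H, p)), rng.gamma(1, 1, (H, p)))
        for y in rng.normal(scale=2, size=6):
            for j in range(p):
                for status in (0, 1):
                    loc = st.mu0loc[:, j] + status * st.delta[:, j]
                    brute = float(np.sum(st.pi * norm.pdf(y, loc, 1 / np.sqrt(st.tau))))
                    assert mixture_density(y, j, status, st) == pytest.approx(brute, rel=1e-10)

    def test_invalid_status_rejected(self):
        st = make_state([1.0], [1.0], [[0.0]], [[0.0]])
        with pytest.raises(ValueError, match="status"):
            mixture_density(0.0, 0, 2, st)

    def test_density_integrates_to_one(self):
        st = make_state([0.6, 0.4], [1.0, 4.0], [[-2.0], [1.0]], [[1.5], [0.5]])
        grid = np.linspace(-12, 12, 4001)
        for status in (0, 1):
            vals = [mixture_density(y, 0, status, st) for y in grid]
            assert np.trapezoid(vals, grid) == pytest.approx(1.0, abs=1e-3)

    def test_stochastic_ordering_of_cdfs(self):
        # nonnegative offsets push interacting mass upward at every threshold
        st = make_state([0.5, 0.5], [1.0, 2.0], [[-1.0], [0.8]], [[2.0], [0.4]])
        grid = np.linspace(-8, 8, 161)
        dense = np.linspace(-15, 8, 3001)
        for t in grid:
            mask = dense <= t
            f0 = np.trapezoid([mixture_density(y, 0, 0, st) for y in dense[mask]], dense[mask])
            f1 = np.trapezoid([mixture_density(y, 0, 1, st) for y in dense[mask]], dense[mask])
            assert f1 <= f0 + 1e-6


class TestPosteriorInteractionProb:
    def test_symmetric_likelihoods_give_half(self):
        st = make_state([0.4, 0.6], [1.0, 3.0], [[-0.5, 0.2], [0.7, -0.1]],
                        np.zeros((2, 2)))
        assert posterior_interaction_prob(np.array([0.3, -0.8]), st, 0.5) == pytest.approx(0.5)

    def test_equidistant_point_gives_half(self):
        st = make_state([1.0], [1.0], [[0.0]], [[1.0]])
        assert posterior_interaction_prob(np.array([0.5]), st, 0.5) == pytest.approx(0.5)

    def test_unit_shift_matches_logistic_of_half(self):
        st = make_state([1.0], [1.0], [[0.0]], [[1.0]])
        expect = 1.0 / (1.0 + np.exp(-0.5))
        assert posterior_interaction_prob(np.array([1.0]), st, 0.5) == pytest.approx(expect, abs=1e-12)

    def test_monotone_in_prior_probability(self, rng):
        st = make_state([0.5, 0.5], [1.0, 2.0], rng.normal(size=(2, 3)),
                        rng.gamma(1, 1, (2, 3)))
        row = rng.normal(size=3)
        probs = [posterior_interaction_prob(row, st, nu) for nu in np.linspace(0.01, 0.99, 25)]
        assert np.all(np.diff(probs) >= -1e-12)

    def test_log_space_matches_direct_products(self, rng):
        st = make_state([0.3, 0.7], [1.0, 2.0], rng.normal(size=(2, 4)),
                        rng.gamma(1, 1, (2, 4)))
        for _ in range(5):
            row = rng.normal(size=4)
            nu = rng.uniform(0.1, 0.9)
            f1 = np.prod([mixture_density(row[j], j, 1, st) for j in range(4)])
            f0 = np.prod([mixture_density(row[j], j, 0, st) for j in range(4)])
            direct = nu * f1 / (nu * f1 + (1 - nu) * f0)
            assert posterior_interaction_prob(row, st, nu) == pytest.approx(direct, abs=1e-10)

    def test_invariant_to_component_relabelling(self, rng):
        # permuting components (jointly over pi, tau, locations, offsets)
        # leaves the posterior probability unchanged
        H, p = 4, 2
        st = make_state(np.array([0.1, 0.2, 0.3, 0.4]), rng.gamma(2, 1, H) + 0.2,
                        rng.normal(size=(H, p)), rng.gamma(1, 1, (H, p)))
        perm = np.array([2, 0, 3, 1])
        st2 = make_state(st.pi[perm], st.tau[perm], st.mu0loc[perm], st.delta[perm])
        row = rng.normal(size=p)
        assert posterior_interaction_prob(row, st, 0.5) == pytest.approx(
            posterior_interaction_prob(row, st2, 0.5), abs=1e-12
        )

    def test_rejects_degenerate_prior(self):
        st = make_state([1.0], [1.0], [[0.0]], [[1.0]])
        for nu in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                posterior_interaction_prob(np.array([0.0]), st, nu)


class TestClassify:
    def test_strict_threshold_with_tie_to_zero(self):
        np.testing.assert_array_equal(
            classify(np.array([0.9, 0.1, 0.5]), 0.5), [1, 0, 0]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(classify(np.ones(4), 0.5), np.ones(4, dtype=int))

    def test_matches_elementwise_comparison(self, rng):
        probs = rng.random(200)
        t = 0.37
        np.testing.assert_array_equal(classify(probs, t), (probs > t).astype(int))

    def test_threshold_bounds(self):
        for t in (0.0, 1.0, 1.3):
            with pytest.raises(ValueError):
                classify(np.array([0.5]), t)


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(H=1), dict(alpha=0.0), dict(kappa=-1.0), dict(a_tau=0.0),
         dict(nu_fixed=1.5), dict(n_iter=100, n_burn=100)],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)
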