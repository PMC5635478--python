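"""Dependency-representation model tests.

The likelihood oracle here is coded independently of the package: it
accumulates posterior-weighted counts with plain Python loops and
dictionaries, derives the Laplace-smoothed conditionals from first
principles, and sums the six chain-rule factorizations term by term.
"""

import numpy as np
import pytest

from adrmil.dem import (
    DemData,
    DemParams,
    RoleTriple,
    dem_fit,
    dem_instance_likelihood,
    dem_m_step,
    dem_pair_conditional,
    dem_posterior_matrix,
    dem_triple_conditional,
    resolve_alpha,
    resolve_beta,
    resolve_gamma,
)
from adrmil.iem import IemParams, PosteriorTable, iem_posterior
from adrmil.features import TermVector


# --------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------
def brute_force_likelihood(triples, weights, posteriors, query, c, lam, gamma, beta, alpha, W):
    """Evaluate the interpolated six-factorization likelihood for one
    query triple by explicit enumeration over the training triples."""

    def n_w(i, w):
        # weight of token w in instance i (roles may repeat a token)
        return sum(wt for tok, wt in zip(triples[i], weights[i]) if tok == w)

    def contains(i, *gs):
        return all(g in triples[i] for g in gs)

    def uni(w, cls):
        num = lam + sum(n_w(i, w) * posteriors[i][cls] for i in range(len(triples)))
        den = lam * W + sum(
            sum(weights[i]) * posteriors[i][cls] for i in range(len(triples))
        )
        return num / den

    def praw(w, g, cls):
        num = lam + sum(
            n_w(i, w) * posteriors[i][cls] for i in range(len(triples)) if contains(i, g)
        )
        den = lam * W + sum(
            sum(weights[i]) * posteriors[i][cls]
            for i in range(len(triples))
            if contains(i, g)
        )
        return num / den

    def traw(w, g1, g2, cls):
        num = lam + sum(
            n_w(i, w) * posteriors[i][cls]
            for i in range(len(triples))
            if contains(i, g1, g2)
        )
        den = lam * W + sum(
            sum(weights[i]) * posteriors[i][cls]
            for i in range(len(triples))
            if contains(i, g1, g2)
        )
        return num / den

    b1, b2 = beta
    a1, a2, a3, a4 = alpha

    def p2(w, g, cls):
        return b1 * uni(w, cls) + b2 * praw(w, g, cls)

    def p3(w, g1, g2, cls):
        return (
            a1 * uni(w, cls) + a2 * praw(w, g1, cls) + a3 * praw(w, g2, cls)
            + a4 * traw(w, g1, g2, cls)
        )

    q, r, s = query
    return (
        gamma[0] * uni(q, c) * p2(r, q, c) * p3(s, q, r, c)
        + gamma[1] * uni(q, c) * p2(s, q, c) * p3(r, q, s, c)
        + gamma[2] * uni(r, c) * p2(q, r, c) * p3(s, q, r, c)
        + gamma[3] * uni(r, c) * p2(s, r, c) * p3(q, r, s, c)
        + gamma[4] * uni(s, c) * p2(q, s, c) * p3(r, q, s, c)
        + gamma[5] * uni(s, c) * p2(r, s, c) * p3(q, r, s, c)
    )


def random_problem(rng, W=3, n=6):
    triples = [tuple(int(t) for t in rng.integers(0, W, size=3)) for _ in range(n)]
    weights = [tuple(float(w) for w in rng.uniform(0.2, 1.5, size=3)) for _ in range(n)]
    posteriors = rng.dirichlet([1, 1], size=n)
    lam = float(rng.uniform(0.2, 2.0))
    gamma = rng.dirichlet(np.ones(6))
    beta = rng.dirichlet(np.ones(2))
    alpha = rng.dirichlet(np.ones(4))
    return triples, weights, posteriors, lam, gamma, beta, alpha


def fitted_params(triples, weights, posteriors, lam, gamma, beta, alpha, W):
    data = DemData.from_triples(
        [RoleTriple(*t, *w) for t, w in zip(triples, weights)], W
    )
    return data, dem_m_step(data, posteriors, lam, gamma, beta, alpha)


class TestLikelihoodOracle:
    def test_matches_brute_force_on_random_tables(self):
        """>= 1000 random (instance, class) cases against the
        independent enumeration oracle, |diff| < 1e-12."""
        rng = np.random.default_rng(42)
        cases = 0
        while cases < 1000:
            triples, weights, posteriors, lam, gamma, beta, alpha = random_problem(rng)
            W = 3
            data, params = fitted_params(
                triples, weights, posteriors, lam, gamma, beta, alpha, W
            )
            for t, w in zip(triples, weights):
                for c in (0, 1):
                    got = dem_instance_likelihood(RoleTriple(*t, *w), c, params)
                    want = brute_force_likelihood(
                        triples, weights, posteriors, t, c, lam, gamma, beta, alpha, W
                    )
                    assert got == pytest.approx(want, abs=1e-12)
                    cases += 1

    def test_vectorized_estep_equals_scalar_path(self):
        rng = np.random.default_rng(7)
        triples, weights, posteriors, lam, gamma, beta, alpha = random_problem(rng, W=4, n=12)
        data, params = fitted_params(triples, weights, posteriors, lam, gamma, beta, alpha, 4)
        vec = dem_posterior_matrix(data, params)
        for i, (t, w) in enumerate(zip(triples, weights)):
            scalar = params.posterior(RoleTriple(*t, *w))
            assert vec[i] == pytest.approx(scalar, abs=1e-12)
        assert vec.sum(axis=1) == pytest.approx(np.ones(len(triples)), abs=1e-9)


class TestConditionals:
    def _params(self, beta=None, alpha=None):
        rng = np.random.default_rng(3)
        triples, weights, posteriors, lam, gamma, _, _ = random_problem(rng, W=3, n=5)
        beta = (1.0, 0.0) if beta is None else beta
        alpha = (1.0, 0.0, 0.0, 0.0) if alpha is None else alpha
        data, params = fitted_params(triples, weights, posteriors, lam, gamma, beta, alpha, 3)
        return params

    def test_degenerate_beta_returns_unigram(self):
        params = self._params(beta=(1.0, 0.0))
        for w in range(3):
            assert dem_pair_conditional(w, 1, 0, params) == pytest.approx(
                params.unigram(w, 0)
            )

    def test_beta_zero_one_returns_raw_pairwise(self):
        params = self._params(beta=(0.0, 1.0))
        assert dem_pair_conditional(2, 1, 0, params) == pytest.approx(
            params.pair_raw(2, 1, 0)
        )

    def test_mixed_beta_is_the_weighted_sum(self):
        params = self._params(beta=(0.7, 0.3))
        got = dem_pair_conditional(2, 0, 1, params)
        want = 0.7 * params.unigram(2, 1) + 0.3 * params.pair_raw(2, 0, 1)
        assert got == pytest.approx(want, abs=1e-15)

    def test_degenerate_alpha_returns_unigram(self):
        params = self._params(alpha=(1.0, 0.0, 0.0, 0.0))
        assert dem_triple_conditional(1, 0, 2, 0, params) == pytest.approx(
            params.unigram(1, 0)
        )

    def test_alpha_half_half_hand_value(self):
        params = self._params(alpha=(0.5, 0.0, 0.0, 0.5))
        got = dem_triple_conditional(2, 0, 1, 1, params)
        want = 0.5 * params.unigram(2, 1) + 0.5 * params.triple_raw(2, 0, 1, 1)
        assert got == pytest.approx(want, abs=1e-15)

    def test_unseen_context_backs_off_to_uniform_table(self):
        params = self._params(beta=(0.0, 1.0))
        # a token index never seen as a context in this vocabulary slot
        assert params.pair_raw(0, -1, 0) == pytest.approx(1.0 / 3.0)


class TestWeightResolution:
    def test_printed_four_entry_beta_keeps_first_two(self):
        beta = resolve_beta((0.97, 0.02, 0.01, 0.0))
        assert beta == pytest.approx([0.97 / 0.99, 0.02 / 0.99])

    def test_printed_two_entry_alpha_maps_to_ends(self):
        assert resolve_alpha((0.10, 0.90)) == pytest.approx([0.10, 0.0, 0.0, 0.90])

    def test_mixture_weights_sum_to_one(self):
        for w in (resolve_gamma(None), resolve_beta(None), resolve_alpha(None)):
            assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestMStep:
    def test_hand_counted_tables_on_three_labeled_triples(self):
        # triples (0,1,2)->c0, (0,1,2)->c0, (3,1,2)->c1; unit weights, lam=1, W=4
        triples = [(0, 1, 2), (0, 1, 2), (3, 1, 2)]
        P = np.array([[1, 0], [1, 0], [0, 1]], float)
        data = DemData.from_triples([RoleTriple(*t) for t in triples], 4)
        params = dem_m_step(data, P, lam=1.0)
        # unigram: class 0 has counts {0:2, 1:2, 2:2}, total 6
        assert params.unigram(0, 0) == pytest.approx((1 + 2) / (4 + 6))
        assert params.unigram(3, 0) == pytest.approx(1 / (4 + 6))
        # pairwise p(0 | context 1, c0): both c0 instances contain 1;
        # count of token 0 in them = 2; total weight = 6
        assert params.pair_raw(0, 1, 0) == pytest.approx((1 + 2) / (4 + 6))
        # triple p(3 | {1,2}, c1): one c1 instance; count 1, total 3
        assert params.triple_raw(3, 1, 2, 1) == pytest.approx((1 + 1) / (4 + 3))
        # class prior: (1+2)/(2+3)
        assert params.class_prior[0] == pytest.approx(3 / 5)

    def test_never_cooccurring_context_is_uniform(self):
        data = DemData.from_triples([RoleTriple(0, 1, 2)], 4)
        params = dem_m_step(data, np.array([[1.0, 0.0]]), lam=1.0)
        # tokens 0 and 3 never co-occur -> raw table is the lam-only limit
        assert params.triple_raw(2, 0, 3, 0) == pytest.approx(1.0 / 4.0)

    def test_one_sided_posteriors_leave_other_class_pure_smoothing(self):
        data = DemData.from_triples([RoleTriple(0, 1, 2), RoleTriple(0, 1, 3)], 4)
        params = dem_m_step(data, np.array([[1.0, 0.0], [1.0, 0.0]]), lam=1.0)
        for w in range(4):
            assert params.unigram(w, 1) == pytest.approx(1.0 / 4.0)
            assert params.pair_raw(w, 0, 1) == pytest.approx(1.0 / 4.0)


class TestIndependenceLimit:
    def test_marginal_tables_collapse_to_naive_bayes(self):
        """With pairwise/triple tables equal to the unigram marginals the
        six factorizations all reduce to the naive-Bayes product, for
        any mixture weights."""
        rng = np.random.default_rng(11)
        W = 6
        triples = [RoleTriple(*(int(x) for x in rng.integers(0, W, size=3))) for _ in range(30)]
        data = DemData.from_triples(triples, W)
        uni = rng.dirichlet(np.ones(W), size=2).T
        prior = rng.dirichlet([1, 1])
        for gamma in (None, tuple(rng.dirichlet(np.ones(6)))):
            params = DemParams.from_marginals(uni, prior, data, lam=1.0, gamma=gamma)
            iem = IemParams(prior, uni, 1.0)
            for t in triples:
                dem_post = params.posterior(t)
                iem_post = iem_posterior(
                    TermVector(np.array([t.q, t.r, t.s]), np.ones(3)), iem
                )
                assert dem_post == pytest.approx(iem_post, abs=1e-9)

    def test_single_factorization_gamma(self):
        rng = np.random.default_rng(12)
        triples, weights, posteriors, lam, _, beta, alpha = random_problem(rng)
        gamma = (1.0, 0, 0, 0, 0, 0)
        data, params = fitted_params(triples, weights, posteriors, lam, gamma, beta, alpha, 3)
        t = RoleTriple(*triples[0], *weights[0])
        got = dem_instance_likelihood(t, 0, params)
        want = (
            params.unigram(t.q, 0)
            * params.pair_cond(t.r, t.q, 0)
            * params.triple_cond(t.s, t.q, t.r, 0)
        )
        assert got == pytest.approx(want, abs=1e-15)


class TestFit:
    def test_max_iter_zero_returns_initial_parameters(self):
        data = DemData.from_triples([RoleTriple(0, 1, 2)], 3)
        table = PosteriorTable(np.array([[1.0, 0.0]]), np.ones(1, bool))
        params, post, trace = dem_fit(data, table, max_iter=0)
        want = dem_m_step(data, table)
        assert params.U == pytest.approx(want.U)
        assert trace == []

    def test_rejects_non_triple_instances(self):
        from adrmil.mil import _role_triples

        bad = TermVector(np.array([0, 1]), np.ones(2), tuple_id="t9")
        with pytest.raises(ValueError, match="t9"):
            _role_triples([bad])

    def test_posterior_rows_normalized_each_estep(self):
        rng = np.random.default_rng(13)
        triples = [RoleTriple(*(int(x) for x in rng.integers(0, 5, size=3))) for _ in range(40)]
        data = DemData.from_triples(triples, 5)
        u = rng.uniform(size=40)
        table = PosteriorTable(np.column_stack([u, 1 - u]), np.zeros(40, bool))
        _, post, _ = dem_fit(data, table, max_iter=5, tol=0.0)
        assert post.probs.sum(axis=1) == pytest.approx(np.ones(40), abs=1e-9)
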