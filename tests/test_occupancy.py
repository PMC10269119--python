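"""Multispecies occupancy model: state distribution, likelihood, fitting
and derived occupancy quantities."""

import itertools

import numpy as np
import pytest

from camshield.occupancy import (
    DetectionParams,
    MSOMFit,
    MSOMSpec,
    NaturalParams,
    compare_models,
    conditional_occupancy,
    cooccurrence_probability,
    enumerate_states,
    fit_msom,
    marginal_occupancy,
    site_likelihood,
    state_probabilities,
    total_loglik,
)
from camshield.simulate import simulate_histories


def _dist_oracle(f1, f2=None):
    """Independent enumeration of the multinomial-logit state distribution."""
    S = len(f1)
    pairs = list(itertools.combinations(range(S), 2))
    weights = []
    for i in range(2**S):
        z = [(i >> s) & 1 for s in range(S)]
        lw = sum(f1[s] * z[s] for s in range(S))
        if f2 is not None:
            lw += sum(f2[q] * z[j] * z[k] for q, (j, k) in enumerate(pairs))
        weights.append(np.exp(lw))
    w = np.array(weights)
    return w / w.sum()


def _fit_at(theta, guild_names, order=2):
    """Wrap a parameter vector in an MSOMFit (no data; point values only)."""
    spec = MSOMSpec(tuple(guild_names), order)
    S, P = spec.S, len(spec.pairs)
    theta = np.asarray(theta, float)
    f2 = theta[S : S + P] if P else None
    from scipy.special import expit

    return MSOMFit(
        spec=spec,
        params=NaturalParams(theta[:S], f2),
        detection=DetectionParams(expit(theta[S + P :])),
        theta=theta,
        loglik=0.0,
        aic=2 * theta.size,
        n_params=theta.size,
        vcov=None,
        converged=True,
        grad_norm=0.0,
        n_sites=0,
        site_y=np.zeros((0, S), int),
        site_k=np.zeros((0, S), int),
    )


class TestStates:
    def test_canonical_order(self):
        assert enumerate_states(1).tolist() == [[0], [1]]
        assert enumerate_states(2).tolist() == [[0, 0], [1, 0], [0, 1], [1, 1]]

    def test_exhaustive_and_stable(self):
        s = enumerate_states(3)
        assert len({tuple(r) for r in s.tolist()}) == 8
        np.testing.assert_array_equal(s, enumerate_states(3))

    @pytest.mark.parametrize("S", [0, 5])
    def test_out_of_range(self, S):
        with pytest.raises(ValueError):
            enumerate_states(S)


class TestStateProbabilities:
    def test_uniform_at_zero(self):
        dist = state_probabilities(NaturalParams([0.0, 0.0], [0.0]))
        np.testing.assert_allclose(dist, 0.25)

    def test_independence_without_interaction(self):
        dist = state_probabilities(NaturalParams([0.7, -1.1], [0.0]))
        states = enumerate_states(2)
        p1 = dist[states[:, 0] == 1].sum()
        p2 = dist[states[:, 1] == 1].sum()
        assert dist[3] == pytest.approx(p1 * p2, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        dist = state_probabilities(NaturalParams([0.5, -0.3], [1.0]))
        np.testing.assert_allclose(dist, _dist_oracle([0.5, -0.3], [1.0]), atol=1e-14)
        # weights (1, e^0.5, e^-0.3, e^1.2) normalised
        assert dist[3] == pytest.approx(0.4948267, abs=1e-6)

    def test_sums_to_one_for_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            f1 = rng.uniform(-5, 5, 3)
            f2 = rng.uniform(-5, 5, 3)
            assert state_probabilities(NaturalParams(f1, f2)).sum() == pytest.approx(
                1.0, abs=1e-12
            )

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            state_probabilities(NaturalParams([np.inf, 0.0]))


class TestSiteLikelihood:
    def test_single_species_closed_forms(self):
        dist = state_probabilities(NaturalParams([0.0]))  # psi = 0.5
        assert site_likelihood([0], [0.5], dist, [1]) == pytest.approx(0.75)
        # occasion-wise history (1, 0): 0.5 * 0.5 * 0.5
        assert site_likelihood([np.array([1.0, 0.0])], [0.5], dist, [2]) == pytest.approx(0.125)

    def test_detection_without_effort_raises(self):
        dist = state_probabilities(NaturalParams([0.0]))
        with pytest.raises(ValueError):
            site_likelihood([2], [0.5], dist, [0])

    def test_matches_brute_force_enumeration(self):
        f1, f2 = [0.4, -0.2], [0.7]
        p = [0.3, 0.6]
        dist = state_probabilities(NaturalParams(f1, f2))
        oracle_dist = _dist_oracle(f1, f2)
        K = 2
        for hist in itertools.product([0, 1], repeat=2 * K):
            h = np.array(hist, float).reshape(2, K)
            got = site_likelihood(list(h), p, dist, [K, K])
            want = 0.0
            for i, z in enumerate(itertools.product([0, 1], repeat=2)):
                term = oracle_dist[sum(zz << s for s, zz in enumerate(z))]
                for s in range(2):
                    for k in range(K):
                        if z[s]:
                            term *= p[s] if h[s, k] else 1 - p[s]
                        elif h[s, k]:
                            term *= 0.0
                want += term
            assert got == pytest.approx(want, abs=1e-12)


@pytest.fixture(scope="module")
def sim_fit():
    f = NaturalParams([0.3, -0.4], [0.8])
    hists = simulate_histories(f, [0.4, 0.5], 300, 20, ("prey", "human"), seed=42)
    fit = fit_msom(hists, MSOMSpec(("prey", "human"), 2), seed=0)
    return f, hists, fit


class TestFit:
    def test_convergence_and_aic_identity(self, sim_fit):
        _, _, fit = sim_fit
        assert fit.converged
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)

    def test_mle_beats_truth(self, sim_fit):
        f, hists, fit = sim_fit
        truth_theta = np.r_[f.first_order, f.second_order,
                            np.log(0.4 / 0.6), np.log(0.5 / 0.5)]
        assert fit.loglik >= total_loglik(fit, theta=truth_theta)

    def test_no_interaction_model_has_four_parameters(self, sim_fit):
        _, hists, _ = sim_fit
        fit1 = fit_msom(hists, MSOMSpec(("prey", "human"), 1), seed=0)
        assert fit1.n_params == 4
        assert fit1.params.second_order is None

    def test_duplicated_data_doubles_loglik(self, sim_fit):
        _, hists, fit = sim_fit
        doubled = {}
        for g, h in hists.items():
            doubled[g] = type(h)(
                guild=g,
                stations=h.stations + [s + "_b" for s in h.stations],
                matrix=np.vstack([h.matrix, h.matrix]),
            )
        fit2 = fit_msom(doubled, fit.spec, seed=0)
        assert fit2.loglik == pytest.approx(2 * fit.loglik, rel=1e-5)
        np.testing.assert_allclose(fit2.theta, fit.theta, atol=5e-3)

    def test_zero_detection_guild_warns(self):
        f = NaturalParams([0.3, -0.4], [0.0])
        hists = simulate_histories(f, [0.4, 0.5], 50, 5, ("prey", "human"), seed=1)
        hists["human"].matrix[:] = 0.0
        with pytest.warns(UserWarning, match="zero detections"):
            fit_msom(hists, MSOMSpec(("prey", "human"), 2), seed=0)

    def test_mismatched_site_dimension_raises(self, sim_fit):
        _, hists, _ = sim_fit
        short = dict(hists)
        h = hists["human"]
        short["human"] = type(h)(guild="human", stations=h.stations[:-1], matrix=h.matrix[:-1])
        with pytest.raises(ValueError, match="site dimension"):
            fit_msom(short, MSOMSpec(("prey", "human"), 2), seed=0)


class TestCompareModels:
    def test_aic_arithmetic_and_tiebreak(self, monkeypatch):
        base = _fit_at(np.zeros(5), ("a", "b"), order=2)
        small = _fit_at(np.zeros(4), ("a", "b"), order=1)
        # equal loglik, k = 4 vs 5 -> smaller model first, delta = 2
        for f, k in ((base, 5), (small, 4)):
            f.loglik = -100.0
            f.n_params = k
            f.aic = 2 * k + 200.0
        table = compare_models([base, small])
        assert table[0]["model"] == 1 and table[0]["best"]
        assert table[1]["delta_aic"] == pytest.approx(2.0)

    def test_single_fit(self):
        f = _fit_at(np.zeros(4), ("a", "b"), order=1)
        table = compare_models([f])
        assert len(table) == 1 and table[0]["delta_aic"] == 0.0

    def test_mismatched_data_raises(self):
        a = _fit_at(np.zeros(4), ("a", "b"), order=1)
        b = _fit_at(np.zeros(4), ("a", "b"), order=1)
        b.site_y = np.ones((3, 2), int)
        b.site_k = np.ones((3, 2), int)
        with pytest.raises(ValueError, match="identical data"):
            compare_models([a, b])


class TestDerivedQuantities:
    # f1=0.5, f2=-0.3, f12=1.0: the enumeration oracle gives
    # P(1,1)=0.494827, P(1,0)=0.245724, P(0,1)=0.110411
    THETA = [0.5, -0.3, 1.0, 0.0, 0.0]

    def test_marginal_symmetric_case(self):
        fit = _fit_at([0.0, 0.0, 0.0, 0.0, 0.0], ("a", "b"))
        assert marginal_occupancy(fit, "a").value == pytest.approx(0.5)
        assert cooccurrence_probability(fit, "a", "b").value == pytest.approx(0.25)

    def test_oracle_values(self):
        fit = _fit_at(self.THETA, ("a", "b"))
        assert marginal_occupancy(fit, "a").value == pytest.approx(0.7405503, abs=1e-6)
        assert cooccurrence_probability(fit, "a", "b").value == pytest.approx(0.4948267, abs=1e-6)
        assert conditional_occupancy(fit, "a", "b", True).value == pytest.approx(0.8175745, abs=1e-6)

    def test_marginal_monotone_in_first_order(self):
        vals = [
            marginal_occupancy(_fit_at([f, -0.3, 1.0, 0, 0], ("a", "b")), "a").value
            for f in np.linspace(-2, 2, 9)
        ]
        assert all(np.diff(vals) > 0)

    def test_conditional_equals_marginal_without_interaction(self):
        fit = _fit_at([0.5, -0.3, 0.0, 0.0, 0.0], ("a", "b"))
        assert conditional_occupancy(fit, "a", "b", True).value == pytest.approx(
            marginal_occupancy(fit, "a").value, abs=1e-12
        )

    @pytest.mark.parametrize("f12", [-2.0, -0.5, 0.5, 2.0])
    def test_conditional_gap_sign_follows_interaction(self, f12):
        fit = _fit_at([0.5, -0.3, f12, 0, 0], ("a", "b"))
        gap = (
            conditional_occupancy(fit, "a", "b", True).value
            - conditional_occupancy(fit, "a", "b", False).value
        )
        assert np.sign(gap) == np.sign(f12)

    def test_certain_cooccurrence_limit(self):
        fit = _fit_at([0.5, -0.3, 20.0, 0, 0], ("a", "b"))
        assert cooccurrence_probability(fit, "a", "b").value == pytest.approx(
            marginal_occupancy(fit, "a").value, abs=1e-6
        )

    def test_same_guild_raises(self):
        fit = _fit_at(self.THETA, ("a", "b"))
        with pytest.raises(ValueError):
            conditional_occupancy(fit, "a", "a", True)

    def test_impossible_conditioning_event_raises(self):
        # P(z_b = 1) is numerically negligible at f_b = -60
        fit = _fit_at([0.5, -60.0, 0.0, 0.0, 0.0], ("a", "b"))
        with pytest.raises(ValueError, match="zero probability"):
            conditional_occupancy(fit, "a", "b", True)

    def test_delta_method_ci_brackets_estimate(self):
        f = NaturalParams([0.3, -0.4], [0.8])
        hists = simulate_histories(f, [0.4, 0.5], 200, 15, ("prey", "human"), seed=5)
        fit = fit_msom(hists, MSOMSpec(("prey", "human"), 2), seed=0)
        est = marginal_occupancy(fit, "prey")
        assert 0.0 <= est.ci_low <= est.value <= est.ci_high <= 1.0
        assert est.se > 0

    def test_parametric_bootstrap_ci(self):
        f = NaturalParams([0.3, -0.4], [0.8])
        hists = simulate_histories(f, [0.4, 0.5], 120, 10, ("prey", "human"), seed=6)
        fit = fit_msom(hists, MSOMSpec(("prey", "human"), 2), seed=0)
        a = marginal_occupancy(fit, "prey", ci="parametric", B=50, seed=9)
        b = marginal_occupancy(fit, "prey", ci="parametric", B=50, seed=9)
        assert a == b  # seeded determinism
        assert a.ci_low <= a.value <= a.ci_high
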