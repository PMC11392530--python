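"""HMM correctness: discretization, kernel, emissions, forward-backward,
and both fitting strategies on small instances."""

import itertools

import numpy as np
import pytest
from scipy.integrate import quad

import epismc as e
from epismc.observations import ObsBlock, PairObservationSequence
from epismc.smc import (EmissionBlock, FreeParameters, SMCModel,
                        baum_welch_fit, constant_model, discretize_time,
                        emission_matrix, forward_backward, likelihood_fit,
                        transition_matrix)

DEM = e.Demography((0.0,), (10_000.0,))


def random_obs(rng, L=60, p_seg=0.3):
    sym = rng.random(L) < p_seg
    pos = np.flatnonzero(sym)
    block = ObsBlock("m1", 2, pos, np.ones(len(pos), dtype=np.int64),
                     dominant=True)
    return PairObservationSequence(L, [block])


def snp_model(n_states=3, mu=2e-5, r=5e-5, window=1, dem=DEM):
    disc = discretize_time(n_states, dem)
    return SMCModel(disc, dem, r, [EmissionBlock("m1", "symmetric", (mu,),
                                                 nbs=4)], window_size=window)


class TestDiscretization:
    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            discretize_time(1, DEM)

    @pytest.mark.parametrize("K", [2, 8, 40])
    def test_equal_prior_masses(self, K):
        disc = discretize_time(K, DEM)
        masses = DEM.interval_masses(np.asarray(disc.boundaries))
        np.testing.assert_allclose(masses, 1.0 / K, rtol=1e-9)

    def test_equal_masses_under_bottleneck(self):
        dem = e.Demography((0.0, 1000.0, 5000.0), (10_000.0, 1_000.0, 10_000.0))
        disc = discretize_time(10, dem)
        masses = dem.interval_masses(np.asarray(disc.boundaries))
        np.testing.assert_allclose(masses, 0.1, rtol=1e-9)

    def test_representative_times_inside_intervals(self):
        disc = discretize_time(12, DEM)
        b = np.asarray(disc.boundaries)
        r = np.asarray(disc.rep_times)
        assert np.all(r > b[:-1]) and np.all(r < b[1:])

    def test_deterministic(self):
        a = discretize_time(7, DEM)
        b = discretize_time(7, DEM)
        assert a.boundaries == b.boundaries and a.rep_times == b.rep_times


class TestTransitionMatrix:
    def test_rows_sum_to_one(self):
        disc = discretize_time(10, DEM)
        A = transition_matrix(disc, DEM, 1e-7)
        np.testing.assert_allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_at_zero_recombination(self):
        disc = discretize_time(6, DEM)
        np.testing.assert_array_equal(transition_matrix(disc, DEM, 0.0),
                                      np.eye(6))

    def test_off_diagonal_grows_with_rho(self):
        disc = discretize_time(6, DEM)
        off = []
        for r in (1e-9, 1e-8, 1e-7):
            A = transition_matrix(disc, DEM, r)
            off.append(A.sum() - np.trace(A))
        assert off[0] < off[1] < off[2]

    def test_small_rho_matches_quadrature_oracle(self):
        """Independent double integral of the single-recombination density."""
        disc = discretize_time(5, DEM)
        r = 1e-9
        A = transition_matrix(disc, DEM, r)
        N = 10_000.0
        edges = np.asarray(disc.boundaries)
        reps = np.asarray(disc.rep_times)
        i = 2
        s = reps[i]
        p_rec = 1 - np.exp(-2 * r * s)

        def dens_below(t, u):
            # coalesce with the other branch at t in (u, s)
            return (1 / s) * (1 / (2 * N)) * np.exp(-2 * (t - u) / (2 * N))

        def dens_above(t, u):
            return ((1 / s) * np.exp(-2 * (s - u) / (2 * N))
                    * (1 / (2 * N)) * np.exp(-(t - s) / (2 * N)))

        for j in [0, 4]:
            a, b = edges[j], min(edges[j + 1], 1e7)
            if j < i:
                q, _ = quad(lambda u: quad(lambda t: dens_below(t, u),
                                           max(a, u), min(b, s))[0]
                            if u < b else 0.0, 0, s, limit=200)
            else:
                q, _ = quad(lambda u: quad(lambda t: dens_above(t, u),
                                           max(a, s), b)[0], 0, s, limit=200)
            assert A[i, j] == pytest.approx(p_rec * q, rel=0.01)


class TestEmissionMatrix:
    def test_rows_sum_to_one_per_block(self):
        disc = discretize_time(5, DEM)
        blocks = [EmissionBlock("m1", "symmetric", (1e-8,), nbs=4),
                  EmissionBlock("meth", "asymmetric", (3.5e-4, 1.5e-3))]
        E = emission_matrix(disc, blocks)
        np.testing.assert_allclose(E[:, :2].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(E[:, 2:].sum(axis=1), 1.0, atol=1e-12)

    def test_values_equal_direct_evaluation(self):
        disc = discretize_time(5, DEM)
        E = emission_matrix(disc, [EmissionBlock("m", "symmetric", (1e-4,),
                                                 nbs=2)])
        t = np.asarray(disc.rep_times)
        np.testing.assert_allclose(E[:, 0], 0.5 + 0.5 * np.exp(-4e-4 * t),
                                   rtol=1e-12)

    def test_seg_probability_increases_with_state_depth(self):
        disc = discretize_time(8, DEM)
        E = emission_matrix(disc, [EmissionBlock("m", "symmetric", (1e-4,),
                                                 nbs=2)])
        assert np.all(np.diff(E[:, 1]) > 0)

    def test_marker_without_rates_rejected(self):
        disc = discretize_time(3, DEM)
        with pytest.raises(ValueError):
            emission_matrix(disc, [EmissionBlock("m", "symmetric", (), nbs=2)])


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        """Log-likelihood equals brute-force summation over all 3^8 paths."""
        model = snp_model(n_states=3)
        obs = random_obs(rng, L=8)
        fb = forward_backward(obs, model)
        A, E, pi = model.window_transition(), model.emissions(), model.prior()
        sym = np.zeros(8, dtype=int)
        sym[obs.blocks[0].event_positions] = 1
        total = 0.0
        for path in itertools.product(range(3), repeat=8):
            p = pi[path[0]] * E[path[0], sym[0]]
            for k in range(1, 8):
                p *= A[path[k - 1], path[k]] * E[path[k], sym[k]]
            total += p
        assert fb.loglik == pytest.approx(np.log(total), abs=1e-10)

    def test_posterior_rows_sum_to_one(self, rng):
        model = snp_model(n_states=5, window=10)
        fb = forward_backward(random_obs(rng, L=500), model)
        np.testing.assert_allclose(fb.posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_uniform_emissions_give_prior_posteriors(self):
        # with r=0 the chain never moves: posteriors equal the prior when the
        # observations carry no information
        model = snp_model(n_states=4, mu=0.0, r=0.0)
        block = ObsBlock("m1", 2, np.empty(0, dtype=np.int64),
                         np.empty(0, dtype=np.int64), dominant=True)
        obs = PairObservationSequence(50, [block])
        fb = forward_backward(obs, model)
        np.testing.assert_allclose(fb.posteriors,
                                   np.tile(model.prior(), (50, 1)), atol=1e-10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            PairObservationSequence(0, [])

    def test_symbol_outside_alphabet_rejected(self):
        with pytest.raises(ValueError):
            ObsBlock("m1", 2, np.array([1]), np.array([5]), dominant=True)

    def test_windowed_equals_per_site_for_weak_transitions(self, rng):
        # windows approximate per-site likelihood well when r is tiny
        obs = random_obs(rng, L=400, p_seg=0.2)
        m1 = snp_model(n_states=4, r=1e-12, window=1)
        m2 = snp_model(n_states=4, r=1e-12, window=50)
        ll1 = forward_backward(obs, m1).loglik
        ll2 = forward_backward(obs, m2).loglik
        assert ll1 == pytest.approx(ll2, rel=1e-6)


class TestBaumWelch:
    def test_all_fixed_returns_input(self, rng):
        model = snp_model(n_states=3)
        obs = [random_obs(rng) for _ in range(2)]
        fit = baum_welch_fit(obs, model, FreeParameters(demography=False))
        assert fit.n_iterations == 1 and fit.converged
        assert fit.demography == model.demography

    def test_likelihood_monotone_over_random_fixtures(self, rng):
        """EM property: the trajectory never decreases (20 random fixtures)."""
        for k in range(20):
            model = snp_model(n_states=3, mu=rng.uniform(1e-6, 1e-4),
                              r=rng.uniform(1e-6, 1e-4))
            obs = [random_obs(rng, L=80, p_seg=rng.uniform(0.1, 0.6))]
            fit = baum_welch_fit(obs, model,
                                 FreeParameters(demography=True,
                                                demography_groups=[[0], [1, 2]]),
                                 max_iter=6, mstep_maxiter=60)
            t = np.asarray(fit.loglik_trajectory)
            assert np.all(np.diff(t) >= -1e-6 * np.abs(t[:-1]) - 1e-9)

    def test_composite_likelihood_invariant_to_pair_order(self, rng):
        model = snp_model(n_states=3)
        obs = [random_obs(rng) for _ in range(4)]
        f1 = baum_welch_fit(obs, model, FreeParameters(demography=False))
        f2 = baum_welch_fit(obs[::-1], model, FreeParameters(demography=False))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-9)

    def test_recovers_constant_size(self, constant_data):
        data = constant_data
        obs = [data.encode_pair(i, j) for i in range(6)
               for j in range(i + 1, 6)]
        blocks = [EmissionBlock("m1", "symmetric", (1e-8,), nbs=4),
                  EmissionBlock("m2", "symmetric", (1e-4,), nbs=2)]
        model = constant_model(5000.0, 1e-8, blocks, n_states=12,
                               window_size=100)
        fit = baum_welch_fit(obs, model,
                             FreeParameters(demography=True,
                                            demography_groups=[[0, 1, 2, 3],
                                                               [4, 5, 6, 7],
                                                               [8, 9, 10, 11]]),
                             max_iter=10)
        sizes = np.asarray(fit.demography.sizes)
        # interior of the time range: recover truth within a factor 2 at this
        # reduced scale
        assert np.all(sizes[4:] > 5_000) and np.all(sizes[4:] < 20_000)


class TestLikelihoodFit:
    def test_one_dimensional_rate_recovery(self, rng):
        """Free mutation rate only: optimum recovered from model-generated data."""
        true_mu = 5e-5
        model = snp_model(n_states=4, mu=true_mu, r=1e-7, window=1)
        A, E, pi = model.window_transition(), model.emissions(), model.prior()
        L = 60_000
        cumA = A.cumsum(axis=1)
        state = int(rng.choice(4, p=pi))
        seg = np.empty(L, dtype=bool)
        u = rng.random(L)
        v = rng.random(L)
        for s in range(L):
            state = int(np.searchsorted(cumA[state], u[s]))
            seg[s] = v[s] < E[state, 1]
        pos = np.flatnonzero(seg)
        obs = PairObservationSequence(
            L, [ObsBlock("m1", 2, pos, np.ones(len(pos), dtype=np.int64),
                         dominant=True)])
        start = snp_model(n_states=4, mu=2e-5, r=1e-7, window=1)
        start.blocks[0].free = True
        fit = likelihood_fit([obs], start,
                             FreeParameters(demography=False, rates=("m1",)))
        assert fit.rates["m1"][0] == pytest.approx(true_mu, rel=0.3)

    def test_returns_at_least_initial_likelihood(self, rng):
        model = snp_model(n_states=3)
        obs = [random_obs(rng)]
        fit = likelihood_fit(obs, model, FreeParameters(demography=True),
                             maxiter=5)
        assert fit.loglik_trajectory[-1] >= fit.loglik_trajectory[0] - 1e-9

    def test_no_free_parameters_rejected(self, rng):
        with pytest.raises(ValueError):
            likelihood_fit([random_obs(rng)], snp_model(),
                           FreeParameters(demography=False))
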