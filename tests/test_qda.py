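import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qdaseg import qda as q
from qdaseg.cluster import kmeans

BOUNDS = q.Bounds(0.0, 255.0)


def _mixture(seed, n=500, means=(20.0, 80.0, 140.0, 220.0), sd=8.0):
    rng = np.random.default_rng(seed)
    return np.concatenate([rng.normal(m, sd, n) for m in means])


class TestQuantumAlgebra:
    def test_quantize_boundaries_and_midpoint(self):
        assert q.quantize(BOUNDS.hi, BOUNDS).q == pytest.approx(1.0)
        assert q.quantize(BOUNDS.lo, BOUNDS).q == pytest.approx(-1.0)
        assert q.quantize((BOUNDS.hi + BOUNDS.lo) / 2, BOUNDS).q == pytest.approx(0.0)

    def test_dequantize_boundaries(self):
        qb1 = q.quantize(BOUNDS.hi, BOUNDS)
        qbm1 = q.quantize(BOUNDS.lo, BOUNDS)
        assert q.dequantize(qb1, BOUNDS) == pytest.approx(BOUNDS.hi)
        assert q.dequantize(qbm1, BOUNDS) == pytest.approx(BOUNDS.lo)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(x=st.floats(0.0, 255.0, allow_nan=False))
    def test_round_trip_identity(self, x):
        assert q.dequantize(q.quantize(x, BOUNDS), BOUNDS) == pytest.approx(
            x, abs=1e-12
        )

    def test_rotation_identity_at_zero(self):
        qb = q.quantize(100.0, BOUNDS)
        r = q.rotate(qb, 0.0)
        assert (r.q, r.alpha, r.beta) == (qb.q, qb.alpha, qb.beta)

    def test_quarter_turn(self):
        qb = q.QubitValue(q=-1.0, alpha=1.0, beta=0.0)
        r = q.rotate(qb, math.pi / 2)
        assert r.alpha == pytest.approx(0.0, abs=1e-12)
        assert r.beta == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        x=st.floats(0.0, 255.0, allow_nan=False),
        t1=st.floats(-1.0, 1.0),
        t2=st.floats(-1.0, 1.0),
    )
    def test_rotation_group_action(self, x, t1, t2):
        qb = q.quantize(x, BOUNDS)
        a = q.rotate(q.rotate(qb, t1), t2)
        b = q.rotate(qb, t1 + t2)
        assert a.alpha == pytest.approx(b.alpha, abs=1e-12)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.alpha**2 + a.beta**2 == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_norm_invariant(self):
        qb = q.quantize(42.0, BOUNDS)
        for theta in np.linspace(-1.5, 1.5, 17):
            qb2 = q.rotate(qb, theta)
            assert qb2.alpha**2 + qb2.beta**2 == pytest.approx(1.0, abs=1e-12)


class TestFitness:
    def test_mape_zero_when_equal(self):
        assert q.mape([1, 2, 3], [1, 2, 3]) == 0.0

    def test_mape_example(self):
        assert q.mape([2, 2], [1, 2]) == pytest.approx(25.0)

    def test_mape_excludes_zero_class(self):
        assert q.mape([0, 2], [5, 2]) == 0.0

    def test_unsupervised_zero_at_centroids(self):
        pix = np.array([10.0, 50.0, 200.0])
        assert q.fitness(np.array([10.0, 50.0, 200.0]), pix, BOUNDS) == 0.0

    def test_supervised_zero_when_labels_match(self):
        pix = np.array([10.0, 10.0, 200.0])
        truth = np.array([1, 1, 2])
        assert q.fitness(np.array([10.0, 200.0]), pix, BOUNDS, truth) == 0.0

    def test_empty_pixels_rejected(self):
        with pytest.raises(ValueError):
            q.fitness(np.array([1.0]), np.array([]), BOUNDS)


class TestSwarm:
    def _swarm(self, spread=0.0, n=3, seed=0):
        cfg = q.QDAConfig(n_agents=n, seed=seed, init_spread=spread)
        pix = _mixture(seed, n=100)
        st_ = q.init_swarm(cfg, BOUNDS, np.array([20.0, 80.0, 140.0, 220.0]), pix)
        return cfg, pix, st_

    def test_zero_spread_clones_seed(self):
        _, _, st_ = self._swarm(spread=0.0)
        assert np.allclose(st_.positions, st_.positions[0])
        assert np.array_equal(st_.food_pos, st_.positions[0])

    def test_seed_determinism(self):
        _, _, a = self._swarm(spread=0.2, seed=3)
        _, _, b = self._swarm(spread=0.2, seed=3)
        assert np.array_equal(a.positions, b.positions)

    def test_food_is_best(self):
        _, _, st_ = self._swarm(spread=0.3)
        assert np.isfinite(st_.fitness).all()
        assert st_.food_fit <= st_.fitness.min() + 1e-15

    def test_out_of_bounds_seed_rejected(self):
        cfg = q.QDAConfig(n_agents=2, seed=0)
        with pytest.raises(ValueError, match="bounds"):
            q.init_swarm(cfg, BOUNDS, np.array([-5.0, 50.0]), np.array([1.0]))

    def test_identical_positions_are_neighbors(self):
        _, _, st_ = self._swarm(spread=0.0)
        assert 1 in q.neighbor_set(st_, 0, T=10)

    def test_zero_radius_distinct_positions(self):
        _, _, st_ = self._swarm(spread=0.3)
        assert q.neighbor_set(st_, 0, radius=0.0).size == 0

    def test_neighbor_oracle_scan(self):
        rng = np.random.default_rng(1)
        _, _, st_ = self._swarm(spread=0.3, n=8, seed=2)
        r = 30.0
        for i in range(st_.n_agents):
            nb = set(q.neighbor_set(st_, i, radius=r).tolist())
            brute = {
                j
                for j in range(st_.n_agents)
                if j != i
                and np.linalg.norm(st_.positions[i] - st_.positions[j]) <= r
            }
            assert nb == brute


class TestOperators:
    def _state(self, positions, steps, pix):
        fits = np.array([q.fitness(p, pix, BOUNDS) for p in positions])
        best, worst = int(np.argmin(fits)), int(np.argmax(fits))
        return q.SwarmState(
            positions=positions,
            steps=steps,
            fitness=fits,
            food_pos=positions[best].copy(),
            food_fit=float(fits[best]),
            enemy_pos=positions[worst].copy(),
            enemy_fit=float(fits[worst]),
            bounds=BOUNDS,
            rng=np.random.default_rng(0),
        )

    def test_symmetric_neighbors_null_separation_cohesion(self):
        pix = np.array([10.0, 50.0])
        pos = np.array([[50.0], [40.0], [60.0]])
        st_ = self._state(pos, np.zeros_like(pos), pix)
        S, A, C, F, E = q.swarm_operators(st_, 0, neighbors=np.array([1, 2]))
        assert np.allclose(S, 0) and np.allclose(C, 0)

    def test_food_at_self_gives_zero_attraction(self):
        pix = np.array([10.0, 50.0])
        pos = np.array([[50.0], [40.0]])
        st_ = self._state(pos, np.zeros_like(pos), pix)
        st_.food_pos = pos[0].copy()
        S, A, C, F, E = q.swarm_operators(st_, 0, neighbors=np.array([1]))
        assert np.allclose(F, 0)

    def test_hand_case_matches_printed_equations(self):
        pix = np.array([0.0, 10.0, 20.0, 30.0, 100.0])
        b = q.Bounds(0.0, 100.0)
        pos = np.array([[10.0, 50.0], [12.0, 52.0], [14.0, 48.0]])
        steps = np.array([[1.0, 1.0], [0.5, 0.5], [0.0, 2.0]])
        fits = np.array([q.fitness(p, pix, b) for p in pos])
        best, worst = int(np.argmin(fits)), int(np.argmax(fits))
        st_ = q.SwarmState(
            positions=pos.copy(), steps=steps.copy(), fitness=fits,
            food_pos=pos[best].copy(), food_fit=float(fits[best]),
            enemy_pos=pos[worst].copy(), enemy_fit=float(fits[worst]),
            bounds=b, rng=np.random.default_rng(0),
        )
        w = q.DAWeights(s=0.1, a=0.2, c=0.3, f=0.4, e=0.05, xi=0.5)
        expected = []
        for i in range(3):
            nb = [j for j in range(3) if j != i]
            Xi = pos[i]
            S = -sum(Xi - pos[j] for j in nb)
            A = sum(steps[j] for j in nb) / 2
            C = sum(pos[j] for j in nb) / 2 - Xi
            F = pos[best] - Xi
            E = pos[worst] + Xi
            dX = w.s * S + w.a * A + w.c * C + w.f * F + w.e * E + w.xi * steps[i]
            expected.append(np.clip(Xi + dX, 0, 100))
        cfg = q.QDAConfig(n_agents=3, seed=0, theta=1e-9)
        st2 = q.da_step(st_, w, pix, cfg, T=100)
        assert np.allclose(st2.positions, np.array(expected), atol=1e-6)

    def test_printed_cohesion_sign_flips(self):
        pix = np.array([10.0, 50.0])
        pos = np.array([[40.0], [60.0], [80.0]])
        st_ = self._state(pos, np.zeros_like(pos), pix)
        _, _, C_fixed, _, _ = q.swarm_operators(st_, 0, neighbors=np.array([1, 2]))
        _, _, C_printed, _, _ = q.swarm_operators(
            st_, 0, neighbors=np.array([1, 2]), printed_cohesion_sign=True
        )
        assert np.allclose(C_printed, -C_fixed)


class TestDaStep:
    def test_null_update_with_zero_weights(self):
        cfg = q.QDAConfig(n_agents=3, seed=0, init_spread=0.05)
        pix = _mixture(0, n=50)
        st_ = q.init_swarm(cfg, BOUNDS, np.array([20.0, 80.0, 140.0, 220.0]), pix)
        before = st_.positions.copy()
        q.da_step(st_, q.DAWeights(0, 0, 0, 0, 0, 0), pix, cfg, T=100)
        assert np.array_equal(st_.positions, before)

    def test_elitist_food_never_worsens(self):
        cfg = q.QDAConfig(n_agents=6, seed=1, init_spread=0.2)
        pix = _mixture(1, n=100)
        st_ = q.init_swarm(cfg, BOUNDS, np.array([20.0, 80.0, 140.0, 220.0]), pix)
        prev = st_.food_fit
        for _ in range(10):
            q.da_step(st_, None, pix, cfg)
            assert st_.food_fit <= prev + 1e-15
            prev = st_.food_fit

    def test_positions_stay_in_bounds(self):
        cfg = q.QDAConfig(n_agents=5, seed=2, init_spread=0.5)
        pix = _mixture(2, n=80)
        st_ = q.init_swarm(cfg, BOUNDS, np.array([20.0, 80.0, 140.0, 220.0]), pix)
        for _ in range(15):
            q.da_step(st_, None, pix, cfg)
            assert st_.positions.min() >= BOUNDS.lo
            assert st_.positions.max() <= BOUNDS.hi


class TestLevyAndMutation:
    def test_levy_update_stays_in_bounds(self):
        cfg = q.QDAConfig(seed=0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            x = rng.uniform(BOUNDS.lo, BOUNDS.hi)
            out = q.levy_qcm_update(x, BOUNDS, cfg.theta, 0, cfg, rng)
            assert BOUNDS.lo <= out <= BOUNDS.hi

    def test_levy_draws_heavy_tailed(self):
        from scipy.stats import kurtosis

        rng = np.random.default_rng(7)
        draws = q.levy_step(rng, beta=1.5, size=1000)
        assert kurtosis(draws) > 0  # heavier tail than any Gaussian fit

    def test_mutation_probability_zero_is_identity(self):
        cfg = q.QDAConfig(mutation_prob=0.0, seed=0)
        x = np.array([10.0, 20.0])
        out = q.gaussian_mutation(x, cfg, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_mutation_arithmetic(self):
        class StubRng:
            def uniform(self):
                return 0.0  # always mutate

            def standard_normal(self):
                return 0.5

        cfg = q.QDAConfig(mutation_prob=1.0, mutation_k=1.0, seed=0)
        out = q.gaussian_mutation(np.array([100.0]), cfg, StubRng())
        assert out[0] == pytest.approx(150.0)


class TestOptimize:
    def test_zero_iterations_returns_seed(self):
        pix = _mixture(3, n=200)
        km = kmeans(pix, 4)
        cfg = q.QDAConfig(n_iter=0, seed=0)
        best, hist = q.optimize(pix, km, cfg)
        assert best is km
        assert len(hist) == 1

    def test_history_monotone_and_beats_seed(self):
        pix = _mixture(4, n=300)
        km = kmeans(pix, 4)
        cfg = q.QDAConfig(seed=4, n_iter=40)
        b = q.Bounds(float(pix.min()), float(pix.max()) + 1e-9)
        best, hist = q.optimize(pix, km, cfg, b)
        assert all(y <= x + 1e-15 for x, y in zip(hist, hist[1:]))
        assert hist[-1] <= q.fitness(km.centroids, pix, b) + 1e-15

    def test_full_determinism(self):
        pix = _mixture(5, n=300)
        km = kmeans(pix, 4)
        runs = []
        for _ in range(2):
            best, hist = q.optimize(pix, km, q.QDAConfig(seed=9, n_iter=30))
            runs.append((best.centroids.copy(), list(hist)))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]

    def test_beats_random_search_with_equal_budget(self):
        wins = 0
        for seed in range(10):
            pix = _mixture(100 + seed, n=300)
            km = kmeans(pix, 4)
            cfg = q.QDAConfig(seed=seed, n_iter=20, n_agents=10)
            b = q.Bounds(float(pix.min()), float(pix.max()) + 1e-9)
            best, hist = q.optimize(pix, km, cfg, b)
            budget = cfg.n_agents * (len(hist))
            rng = np.random.default_rng(1000 + seed)
            cand = rng.uniform(b.lo, b.hi, size=(budget, 4))
            rand_best = min(q.fitness(c, pix, b) for c in cand)
            if hist[-1] <= rand_best:
                wins += 1
        assert wins >= 8
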