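import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hybwave import hybwwoa as hw


class _StubRng:
    """Deterministic stand-in for a Generator: scripted draw sequences."""

    def __init__(self, uniforms=(), integers=()):
        self._uniform = list(uniforms)
        self._integers = list(integers)

    def uniform(self, *args, **kwargs):
        return self._uniform.pop(0)

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)


def _wave(x, delta=0.5, h=6, f=0.0):
    return hw.Wave(position=np.asarray(x, dtype=float), wavelength=delta,
                   height=h, fitness=f)


class TestPropagate:
    def test_zero_wavelength_keeps_position(self):
        b = hw.SearchBounds.cube(3, -5, 5)
        w = _wave([1.0, -2.0, 0.0], delta=0.0)
        out = hw.propagate(w, b, np.random.default_rng(0))
        assert np.array_equal(out.position, w.position)

    def test_stays_in_bounds(self):
        b = hw.SearchBounds.cube(4, -1, 1)
        rng = np.random.default_rng(1)
        w = _wave([0.9, -0.9, 0.0, 0.5], delta=2.0)
        for _ in range(200):
            w = hw.propagate(w, b, rng)
            assert np.all(w.position >= b.lb) and np.all(w.position <= b.ub)

    def test_mean_step_magnitude(self):
        """E|x' - x| = delta * L / 2 (mean of |U(-1,1)|) in-bounds."""
        d = 100_000
        b = hw.SearchBounds.cube(d, -100, 100)
        w = _wave(np.zeros(d), delta=0.001)
        out = hw.propagate(w, b, np.random.default_rng(2))
        mean_step = np.abs(out.position - w.position).mean()
        expected = 0.001 * 200 / 2
        assert abs(mean_step - expected) / expected < 0.02


class TestUpdateWavelength:
    def test_worst_wave_shrinks_by_alpha(self):
        cfg = hw.HybConfig(alpha=1.5, epsilon=1e-12)
        w = _wave([0.0], delta=2.0, f=10.0)
        assert hw.update_wavelength(w, fmax=10.0, fmin=0.0, cfg=cfg) == \
            pytest.approx(2.0 / 1.5)

    def test_best_wave_nearly_unchanged(self):
        cfg = hw.HybConfig(alpha=1.5, epsilon=1e-12)
        w = _wave([0.0], delta=2.0, f=0.0)
        assert hw.update_wavelength(w, fmax=10.0, fmin=0.0, cfg=cfg) == \
            pytest.approx(2.0, rel=1e-9)

    def test_midway_half_power(self):
        cfg = hw.HybConfig(alpha=2.0, epsilon=1e-15)
        w = _wave([0.0], delta=1.0, f=5.0)
        assert hw.update_wavelength(w, fmax=10.0, fmin=0.0, cfg=cfg) == \
            pytest.approx(2.0 ** -0.5, rel=1e-6)


class TestRefract:
    def test_degenerate_gaussian_lands_on_best(self):
        cfg = hw.HybConfig()
        w = _wave([1.0, 2.0], f=3.0)
        best = _wave([1.0, 2.0], f=1.0)
        out = hw.refract(w, best, cfg, np.random.default_rng(0))
        assert np.allclose(out.position, best.position)
        assert out.height == cfg.h_max

    def test_sample_mean_matches_midpoint(self):
        d = 100_000
        cfg = hw.HybConfig()
        w = _wave(np.zeros(d), f=2.0)
        best = _wave(np.full(d, 4.0), f=1.0)
        out = hw.refract(w, best, cfg, np.random.default_rng(3))
        se = 2.0 / np.sqrt(d)  # sd = |x*-x|/2 = 2 per dim
        assert abs(out.position.mean() - 2.0) < 3 * se

    def test_wavelength_scaled_by_fitness_ratio(self):
        cfg = hw.HybConfig()
        w = _wave([0.0], delta=1.0, f=2.0)
        best = _wave([0.0], f=1.0)
        out = hw.refract(w, best, cfg, np.random.default_rng(0),
                         evaluate=lambda x: 1.0)
        assert out.wavelength == pytest.approx(2.0)


class TestWoaCoefficients:
    def test_a_zero_gives_zero_A(self):
        A, C = hw.woa_coefficients(0.0, _StubRng(uniforms=[0.3, 0.8]))
        assert A == 0.0

    def test_forced_arithmetic(self):
        A, C = hw.woa_coefficients(1.0, _StubRng(uniforms=[0.75, 0.75]))
        assert A == pytest.approx(0.5)
        assert C == pytest.approx(1.5)

    def test_empirical_coverage(self):
        rng = np.random.default_rng(4)
        As, Cs = zip(*(hw.woa_coefficients(2.0, rng) for _ in range(10_000)))
        assert min(As) < -1.9 and max(As) > 1.9
        assert min(Cs) < 0.01 and max(Cs) > 1.99
        assert all(-2 <= A <= 2 for A in As)


class TestWoaMove:
    CFG = hw.HybConfig()

    def test_encircle_A_zero_lands_on_best(self):
        # draws: p (below threshold), l, r1/r2 for (A, C): A=0 needs r1=0.5
        rng = _StubRng(uniforms=[0.1, 0.0, 0.5, 0.5])
        out = hw.woa_move(np.array([3.0]), np.array([5.0]), [np.array([9.0])],
                          self.CFG, a=2.0, rng=rng)
        assert out == pytest.approx(5.0)

    def test_encircle_hand_value(self):
        # X*=5, X=3, A=0.5, C=1 -> D=|C X* - X|=2, X'=5-0.5*2=4
        rng = _StubRng(uniforms=[0.1, 0.0, 0.75, 0.5])  # a=1: A=0.5, C=1
        out = hw.woa_move(np.array([3.0]), np.array([5.0]), [np.array([9.0])],
                          self.CFG, a=1.0, rng=rng)
        assert out == pytest.approx(4.0)

    def test_explore_hand_value(self):
        # X_rand=10, X=2, A=2, C=1 -> D=8, X'=10-2*8=-6
        rng = _StubRng(uniforms=[0.1, 0.0, 1.0, 0.5], integers=[0])
        out = hw.woa_move(np.array([2.0]), np.array([0.0]),
                          [np.array([10.0])], self.CFG, a=2.0, rng=rng)
        assert out == pytest.approx(-6.0)

    def test_spiral_at_best_stays_at_best(self):
        rng = _StubRng(uniforms=[0.9, 0.25, 0.1, 0.1])
        out = hw.woa_move(np.array([5.0]), np.array([5.0]), [np.array([0.0])],
                          self.CFG, a=1.0, rng=rng)
        assert out == pytest.approx(5.0)


class TestOptimize:
    def test_elitism_trace_monotone(self):
        b = hw.SearchBounds.cube(5, -5, 5)
        spec = hw.ObjectiveSpec(evaluate=hw.rastrigin, dim=5, bounds=b)
        for seed in range(3):
            cfg = hw.HybConfig(pop_size=8, iterations=40, seed=seed)
            _, best, trace = hw.optimize(spec, cfg)
            assert np.all(np.diff(trace) <= 0)
            assert trace[-1] == best

    def test_best_within_bounds(self):
        b = hw.SearchBounds.cube(6, -2, 3)
        spec = hw.ObjectiveSpec(evaluate=hw.sphere, dim=6, bounds=b)
        pos, _, _ = hw.optimize(spec, hw.HybConfig(pop_size=6, iterations=30,
                                                   seed=5))
        assert np.all(pos >= b.lb) and np.all(pos <= b.ub)

    def test_seed_reproducibility(self):
        b = hw.SearchBounds.cube(4, -5, 5)
        spec = hw.ObjectiveSpec(evaluate=hw.sphere, dim=4, bounds=b)
        cfg = hw.HybConfig(pop_size=6, iterations=25, seed=11)
        r1 = hw.optimize(spec, cfg)
        r2 = hw.optimize(spec, cfg)
        assert np.array_equal(r1[0], r2[0])
        assert np.array_equal(r1[2], r2[2])

    def test_never_worse_than_initial_population(self):
        """With an optimal initial agent the result can only equal it."""
        b = hw.SearchBounds.cube(3, -1, 1)
        calls = []

        def f(x):
            calls.append(hw.sphere(x))
            return calls[-1]

        spec = hw.ObjectiveSpec(evaluate=f, dim=3, bounds=b)
        cfg = hw.HybConfig(pop_size=5, iterations=20, seed=2)
        _, best, _ = hw.optimize(spec, cfg)
        assert best <= min(calls[:cfg.pop_size])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            hw.HybConfig(pop_size=1)
        with pytest.raises(ValueError):
            hw.HybConfig(iterations=0)


class TestBinarize:
    def test_saturation(self):
        mask = hw.binarize(np.array([10.0, -10.0]))
        assert mask.selected.tolist() == [True, False]

    def test_empty_guard_forces_argmax(self):
        mask = hw.binarize(np.array([-10.0, -3.0, -10.0]))
        assert mask.selected.tolist() == [False, True, False]

    @given(st.integers(0, 1000))
    def test_matches_elementwise_threshold(self, seed):
        x = np.random.default_rng(seed).normal(size=12)
        mask = hw.binarize(x)
        if (x > 0).any():
            assert np.array_equal(mask.selected, x > 0)
        else:
            assert mask.count == 1


class TestFeatureFitness:
    @staticmethod
    def _separable(n=60, d=6):
        rng = np.random.default_rng(0)
        y = np.arange(n) % 2
        X = rng.normal(size=(n, d)) * 0.01
        X[:, 0] += y * 100.0  # column 0 separates perfectly
        X[:, 1] += y * 100.0
        return X, y

    def test_separable_all_features(self):
        X, y = self._separable()
        mask = hw.SelectionMask(np.ones(X.shape[1], dtype=bool))
        fit = hw.feature_fitness(mask, X, y, omega=0.99, seed=0)
        assert fit == pytest.approx(0.01 * 1.0)

    def test_fewer_features_at_equal_error_wins(self):
        X, y = self._separable()
        full = hw.SelectionMask(np.ones(X.shape[1], dtype=bool))
        sub = np.zeros(X.shape[1], dtype=bool)
        sub[0] = True
        small = hw.SelectionMask(sub)
        assert hw.feature_fitness(small, X, y, seed=0) < \
            hw.feature_fitness(full, X, y, seed=0)

    def test_true_mask_beats_random_masks(self, feature_dataset):
        X, y, true_mask = feature_dataset
        true_fit = hw.feature_fitness(hw.SelectionMask(true_mask), X, y,
                                      seed=0)
        rng = np.random.default_rng(7)
        rand_fits = []
        for _ in range(20):
            sel = np.zeros(X.shape[1], dtype=bool)
            sel[rng.choice(X.shape[1], true_mask.sum(), replace=False)] = True
            rand_fits.append(
                hw.feature_fitness(hw.SelectionMask(sel), X, y, seed=0))
        assert true_fit < np.median(rand_fits)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        mask = hw.SelectionMask(np.array([True, False, False]))
        with pytest.raises(ValueError):
            hw.feature_fitness(mask, X, np.zeros(10, dtype=int))


class TestSelectFeatures:
    def test_predictive_column_found(self):
        """D=2 with one perfectly predictive column: the exhaustive 3-mask
        oracle shows {0} is optimal; selection should find it in >= 9/10
        seeds."""
        rng = np.random.default_rng(0)
        n = 60
        y = np.arange(n) % 2
        X = np.column_stack([y * 10.0 + rng.normal(size=n) * 0.01,
                             rng.normal(size=n)])
        # oracle: enumerate all non-empty masks
        fits = {}
        for bits in ((True, False), (False, True), (True, True)):
            m = hw.SelectionMask(np.array(bits))
            fits[bits] = hw.feature_fitness(m, X, y, seed=0)
        assert min(fits, key=fits.get) == (True, False)

        hits = 0
        for seed in range(10):
            cfg = hw.HybConfig(pop_size=8, iterations=15, seed=seed)
            mask, _ = hw.select_features(X, y, cfg)
            hits += mask.selected.tolist() == [True, False]
        assert hits >= 9

    def test_mask_length_and_reproducibility(self, feature_dataset):
        X, y, _ = feature_dataset
        cfg = hw.HybConfig(pop_size=6, iterations=8, seed=3)
        m1, t1 = hw.select_features(X, y, cfg)
        m2, t2 = hw.select_features(X, y, cfg)
        assert len(m1.selected) == X.shape[1]
        assert np.array_equal(m1.selected, m2.selected)
        assert np.array_equal(t1, t2)

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            hw.select_features(np.zeros((10, 1)), np.zeros(10, dtype=int),
                               hw.HybConfig())


class TestMaskAndBounds:
    def test_mask_never_empty(self):
        with pytest.raises(ValueError):
            hw.SelectionMask(np.zeros(4, dtype=bool))

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            hw.SearchBounds(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    @given(st.integers(0, 200))
    def test_woa_move_then_clamp_in_bounds(self, seed):
        rng = np.random.default_rng(seed)
        b = hw.SearchBounds.cube(3, -2, 2)
        x = rng.uniform(-2, 2, 3)
        best = rng.uniform(-2, 2, 3)
        out = hw.woa_move(x, best, [rng.uniform(-2, 2, 3)], hw.HybConfig(),
                          a=rng.uniform(0, 2), rng=rng)
        out = np.clip(out, b.lb, b.ub)
        assert np.all(out >= b.lb) and np.all(out <= b.ub)
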