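import math

import numpy as np
import pytest

from barn_cgwo.chaotic_gwo import (
    CoefficientSet,
    SearchSpace,
    chaotic_coefficients,
    coeff_A,
    linear_decay_a,
    optimize,
    update_position,
)


class _ForcedRng:
    """Stub generator returning a fixed uniform draw."""

    def __init__(self, value: float):
        self.value = value

    def random(self, dim):
        return np.full(dim, self.value)


class TestLinearDecay:
    @pytest.mark.parametrize("n,nmax,expected", [(0, 20, 2.0), (20, 20, 0.0), (10, 20, 1.0)])
    def test_boundaries_and_midpoint(self, n, nmax, expected):
        assert linear_decay_a(n, nmax) == expected

    def test_zero_nmax_invalid(self):
        with pytest.raises(ValueError):
            linear_decay_a(0, 0)

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            linear_decay_a(21, 20)

    @pytest.mark.parametrize("n", range(0, 21))
    def test_exact_formula_over_grid(self, n):
        assert linear_decay_a(n, 20) == 2.0 - 2.0 * (n / 20)


class TestCoeffA:
    def test_a_zero_collapses(self, rng):
        np.testing.assert_array_equal(coeff_A(0.0, rng, 5), np.zeros(5))

    def test_forced_upper_bound(self):
        np.testing.assert_allclose(coeff_A(2.0, _ForcedRng(1.0), 3), [2.0, 2.0, 2.0])

    def test_forced_quarter(self):
        np.testing.assert_allclose(coeff_A(1.0, _ForcedRng(0.25), 1), [-0.5])

    def test_magnitude_bounded_by_a(self, rng):
        for a in (0.3, 1.0, 2.0):
            for _ in range(50):
                assert np.all(np.abs(coeff_A(a, rng, 4)) <= a)

    def test_invalid_a(self, rng):
        with pytest.raises(ValueError):
            coeff_A(2.5, rng)


class TestChaoticCoefficients:
    def test_at_zero(self):
        c1, c2, c3 = chaotic_coefficients(0, 20)
        assert c1 == 1.0
        assert c2 == 1.0
        assert c3 == 0.0

    @pytest.mark.parametrize("n", [1, 10, 20])
    def test_matches_independent_hand_evaluation(self, n):
        nmax = 20
        exp_c1 = 0.5 + 0.5 * math.exp(-n / 500) + 1.4 * math.sin(n) / 30
        exp_c2 = 1 + 1.4 * (1 - math.exp(-n / 500)) + 1.4 * math.sin(n) / 30
        exp_c3 = 1 / (1 + math.exp(-0.0001 * n / nmax)) * (0.5 - 2.5) * (n / nmax) ** 2
        c1, c2, c3 = chaotic_coefficients(n, nmax)
        assert c1 == pytest.approx(exp_c1, abs=1e-12)
        assert c2 == pytest.approx(exp_c2, abs=1e-12)
        assert c3 == pytest.approx(exp_c3, abs=1e-12)

    def test_c3_at_final_iteration_near_minus_one(self):
        _, _, c3 = chaotic_coefficients(20, 20)
        assert c3 == pytest.approx(-1.0, abs=1e-3)

    def test_c3_nonpositive_everywhere(self):
        assert all(chaotic_coefficients(n, 50)[2] <= 0 for n in range(51))

    def test_deterministic(self):
        assert chaotic_coefficients(7, 20) == chaotic_coefficients(7, 20)

    def test_zero_nmax_invalid(self):
        with pytest.raises(ValueError):
            chaotic_coefficients(0, 0)


class TestUpdatePosition:
    space = SearchSpace.cube(-5.0, 5.0, 2)

    def _coeffs(self, a, A, C):
        A = np.full(2, A)
        return CoefficientSet(a=a, A1=A, A2=A, A3=A, C1=C, C2=C, C3=C)

    def test_leaders_at_common_point_zero_A(self):
        p = np.array([1.5, -2.0])
        out = update_position(np.array([0.0, 0.0]), (p, p, p), self._coeffs(1.0, 0.0, 1.0), self.space)
        np.testing.assert_allclose(out, p)

    def test_wolf_at_leader_position_is_fixed_point(self):
        p = np.array([1.0, 1.0])
        out = update_position(p, (p, p, p), self._coeffs(1.0, 0.7, 1.0), self.space)
        np.testing.assert_allclose(out, p)

    def test_one_dimensional_hand_case(self):
        space = SearchSpace.cube(-5.0, 5.0, 1)
        A = np.array([0.5])
        coeffs = CoefficientSet(a=1.0, A1=A, A2=A, A3=A, C1=2.0, C2=2.0, C3=2.0)
        one = np.array([1.0])
        out = update_position(np.array([0.0]), (one, one, one), coeffs, space)
        np.testing.assert_allclose(out, [0.0])

    def test_result_clamped(self):
        space = SearchSpace.cube(0.0, 1.0, 1)
        A = np.array([-10.0])  # violent step
        coeffs = CoefficientSet(a=2.0, A1=A, A2=A, A3=A, C1=1.0, C2=1.0, C3=1.0)
        out = update_position(
            np.array([0.0]), (np.array([1.0]), np.array([1.0]), np.array([1.0])), coeffs, space
        )
        assert 0.0 <= out[0] <= 1.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            update_position(
                np.zeros(3),
                (np.zeros(2), np.zeros(2), np.zeros(2)),
                self._coeffs(1.0, 0.0, 1.0),
                self.space,
            )


def _naive_gwo(objective, lower, upper, M, nmax, seed):
    """Independent straightforward re-implementation of the canonical update
    equations, used as an oracle for the variant='gwo' path.  Written as a
    plain loop directly from the distance/move/mean equations."""
    rng = np.random.default_rng(seed)
    dim = len(lower)
    pos = rng.uniform(lower, upper, size=(M, dim))
    fit = np.array([objective(p) for p in pos])
    best_trace = []

    def leaders():
        order = sorted(range(M), key=lambda i: (fit[i], i))
        return order[:3]

    ia, ib, id_ = leaders()
    best = fit[ia]
    best_trace.append(best)
    for n in range(1, nmax + 1):
        a = 2.0 - 2.0 * (n / nmax)
        ua, ub, ud = pos[ia].copy(), pos[ib].copy(), pos[id_].copy()
        for i in range(M):
            news = []
            for lead in (ua, ub, ud):
                r1 = rng.random(dim)
                A = 2 * a * r1 - a
                r2 = rng.random(dim)
                C = 2 * r2
                L = np.abs(C * lead - pos[i])
                news.append(lead - A * L)
            cand = np.clip((news[0] + news[1] + news[2]) / 3.0, lower, upper)
            f = objective(cand)
            if f < fit[i]:
                pos[i] = cand
                fit[i] = f
        ia, ib, id_ = leaders()
        best = min(best, fit[ia])
        best_trace.append(best)
    return best_trace


class TestOptimize:
    space3 = SearchSpace.cube(-5.0, 5.0, 3)

    @staticmethod
    def sphere(x):
        return float(np.sum(x**2))

    def test_sphere_converges(self):
        res = optimize(self.sphere, self.space3, M=20, nmax=100, seed=3, variant="cgwo")
        assert res.best_fitness < 1e-3

    def test_constant_objective(self):
        res = optimize(lambda x: 7.0, self.space3, M=6, nmax=10, seed=0)
        assert res.best_fitness == 7.0
        assert all(v == 7.0 for v in res.trace)

    def test_same_seed_identical_trace(self):
        a = optimize(self.sphere, self.space3, M=8, nmax=15, seed=42, variant="cgwo")
        b = optimize(self.sphere, self.space3, M=8, nmax=15, seed=42, variant="cgwo")
        assert a.trace == b.trace
        np.testing.assert_array_equal(a.best_position, b.best_position)

    @pytest.mark.parametrize("variant", ["gwo", "cgwo"])
    def test_trace_non_increasing(self, variant):
        res = optimize(self.sphere, self.space3, M=6, nmax=30, seed=11, variant=variant)
        assert all(x >= y for x, y in zip(res.trace, res.trace[1:]))

    def test_positions_stay_in_bounds(self):
        space = SearchSpace.cube(0.5, 2.0, 2)
        seen = []

        def probe(x):
            seen.append(x.copy())
            return float(np.sum(x**2))

        optimize(probe, space, M=5, nmax=20, seed=1)
        seen = np.array(seen)
        assert np.all(seen >= 0.5) and np.all(seen <= 2.0)

    def test_gwo_matches_naive_oracle(self):
        lower, upper = np.full(2, -5.0), np.full(2, 5.0)
        expected = _naive_gwo(self.sphere, lower, upper, M=6, nmax=5, seed=123)
        res = optimize(self.sphere, SearchSpace(lower, upper), M=6, nmax=5, seed=123, variant="gwo")
        assert res.trace == expected  # bit-for-bit

    def test_non_finite_objective_reports_position(self):
        with pytest.raises(ValueError, match="position"):
            optimize(lambda x: float("nan"), self.space3, M=4, nmax=2, seed=0)

    def test_small_pack_rejected(self):
        with pytest.raises(ValueError):
            optimize(self.sphere, self.space3, M=3, nmax=5, seed=0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            optimize(self.sphere, self.space3, variant="pso")

    def test_trace_csv(self):
        res = optimize(self.sphere, self.space3, M=5, nmax=3, seed=0)
        lines = res.trace_csv().strip().splitlines()
        assert lines[0] == "iteration,best_fitness,alpha_0,alpha_1,alpha_2"
        assert len(lines) == 5  # header + init + 3 iterations


class TestSearchSpace:
    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_clamp(self):
        s = SearchSpace.cube(0.0, 1.0, 2)
        np.testing.assert_allclose(s.clamp(np.array([-1.0, 2.0])), [0.0, 1.0])
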