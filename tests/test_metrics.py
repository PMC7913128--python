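"""Early-recognition metrics against closed forms and brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from moscreen.metrics import (
    RankedScreen,
    auac,
    bedroc,
    enrichment_factor,
    rie,
    rie_bounds,
    solve_alpha,
)


def screen_from_ranks(active_ranks, N):
    flags = np.zeros(N, dtype=bool)
    flags[np.asarray(active_ranks) - 1] = True
    return RankedScreen(tuple(f"c{i}" for i in range(N)), flags)


class TestRankedScreen:
    def test_rank_bookkeeping(self):
        s = screen_from_ranks([1, 4], 5)
        assert s.N == 5 and s.n == 2
        assert s.active_ranks.tolist() == [1, 4]
        assert np.allclose(s.relative_ranks, [0.2, 0.8])

    def test_from_scores_orders_descending_with_id_ties(self):
        s = RankedScreen.from_scores(
            ["b", "a", "c"], [0.5, 0.5, 0.9], actives=["c"]
        )
        assert s.ids == ("c", "a", "b")  # tie between a and b -> id order
        assert s.active_flags.tolist() == [True, False, False]

    @pytest.mark.parametrize("flags", [[True] * 3, [False] * 3])
    def test_degenerate_screens_rejected(self, flags):
        with pytest.raises(ValueError):
            RankedScreen(("a", "b", "c"), np.array(flags))

    def test_rank_order_invariant_under_monotone_transform(self, rng):
        ids = [f"c{i}" for i in range(30)]
        scores = rng.random(30)
        actives = ids[:4]
        s1 = RankedScreen.from_scores(ids, scores, actives)
        s2 = RankedScreen.from_scores(ids, np.exp(5 * scores), actives)
        assert s1.ids == s2.ids
        assert bedroc(s1, 20.0) == bedroc(s2, 20.0)


class TestAuac:
    def test_direct_formula_examples(self):
        assert auac(screen_from_ranks([1, 2], 100)) == pytest.approx(0.985)
        assert auac(screen_from_ranks([100], 100)) == pytest.approx(0.0)

    def test_matches_direct_summation_on_random_screens(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 21))
            n = int(rng.integers(1, N))
            ranks = rng.choice(N, size=n, replace=False) + 1
            s = screen_from_ranks(sorted(ranks), N)
            expected = 1.0 - sum(r / N for r in ranks) / n
            assert auac(s) == pytest.approx(expected, abs=1e-12)


class TestEnrichmentFactor:
    def test_perfect_retrieval_attains_inverse_chi_eff(self):
        s = screen_from_ranks([1, 2, 3], 100)
        chi = 0.05  # cutoff 5, chi_eff 0.05
        assert enrichment_factor(s, chi) == pytest.approx(1 / 0.05)

    def test_no_actives_in_top_is_zero(self):
        s = screen_from_ranks([99, 100], 100)
        assert enrichment_factor(s, 0.01) == 0.0

    def test_count_oracle(self):
        s = screen_from_ranks([2, 5, 9, 500, 600, 700, 800, 900, 950, 1000],
                              1000)
        # cutoff ceil(0.01*1000)=10 -> 3 retrieved of n=10
        assert enrichment_factor(s, 0.01) == pytest.approx(3 / (0.01 * 10))

    def test_chi_one_is_unity(self):
        s = screen_from_ranks([3, 7], 10)
        assert enrichment_factor(s, 1.0) == pytest.approx(1.0)


class TestRie:
    def test_scalar_arithmetic_oracle(self):
        # N=100, n=1, active at rank 1, alpha=20
        s = screen_from_ranks([1], 100)
        num = math.exp(-20 * 0.01)
        den = (1 / 100) * (1 - math.exp(-20)) / (math.exp(20 / 100) - 1)
        assert rie(s, 20.0) == pytest.approx(num / den, rel=1e-12)
        assert rie(s, 20.0) == pytest.approx(18.13, abs=0.005)

    def test_small_alpha_limit_is_one(self):
        s = screen_from_ranks([7, 20, 33], 40)
        assert rie(s, 1e-8) == pytest.approx(1.0, abs=1e-6)

    def test_bounded_by_closed_form_bounds_exhaustively(self):
        for N in (5, 8):
            for n in (1, 2, 3):
                lo, hi = rie_bounds(n, N, 8.0)
                for ranks in itertools.combinations(range(1, N + 1), n):
                    r = rie(screen_from_ranks(ranks, N), 8.0)
                    assert lo - 1e-9 <= r <= hi + 1e-9

    def test_large_alpha_no_overflow(self):
        s = screen_from_ranks([1], 1000)
        assert np.isfinite(rie(s, 160.9))
        assert np.isfinite(bedroc(s, 160.9))


class TestBedroc:
    def test_perfect_and_worst_screens(self):
        N, n = 50, 5
        best = screen_from_ranks(range(1, n + 1), N)
        worst = screen_from_ranks(range(N - n + 1, N + 1), N)
        assert bedroc(best, 160.9) == pytest.approx(1.0, abs=1e-9)
        assert bedroc(worst, 160.9) == pytest.approx(0.0, abs=1e-9)

    def test_in_unit_interval_everywhere(self):
        for N in (6, 8):
            for n in (1, 3):
                for ranks in itertools.combinations(range(1, N + 1), n):
                    b = bedroc(screen_from_ranks(ranks, N), 20.0)
                    assert -1e-9 <= b <= 1 + 1e-9

    def test_single_active_top_rank_near_one(self):
        s = screen_from_ranks([1], 100)
        lo, hi = rie_bounds(1, 100, 20.0)
        expected = (rie(s, 20.0) - lo) / (hi - lo)
        assert bedroc(s, 20.0) == pytest.approx(expected, rel=1e-12)
        assert bedroc(screen_from_ranks([1], 100), 160.9) == pytest.approx(
            1.0, abs=1e-3
        )

    @given(st.data())
    def test_promoting_an_active_never_decreases_metrics(self, data):
        N = data.draw(st.integers(5, 25))
        n = data.draw(st.integers(1, min(4, N - 1)))
        ranks = sorted(
            data.draw(
                st.lists(st.integers(1, N), min_size=n, max_size=n,
                         unique=True)
            )
        )
        s = screen_from_ranks(ranks, N)
        movable = [r for r in ranks if r > 1 and (r - 1) not in ranks]
        if not movable:
            return
        r = movable[0]
        better = sorted({r - 1} | set(ranks) - {r})
        s2 = screen_from_ranks(better, N)
        for alpha in (5.0, 160.9):
            assert bedroc(s2, alpha) >= bedroc(s, alpha) - 1e-12
            assert rie(s2, alpha) >= rie(s, alpha) - 1e-12
        assert auac(s2) >= auac(s) - 1e-12


class TestSolveAlpha:
    def test_screening_calibration(self):
        assert solve_alpha(0.8, 0.01) == pytest.approx(160.9, abs=0.05)

    def test_against_bisection_oracle(self):
        theta, z = 0.8, 0.05

        def f(a):
            return theta * (1 - math.exp(-a)) - 1 + math.exp(-a * z)

        lo, hi = 1e-9, 1e4
        for _ in range(200):  # plain bisection, independent of brentq
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert solve_alpha(theta, z) == pytest.approx((lo + hi) / 2, abs=1e-6)
        assert solve_alpha(theta, z) == pytest.approx(32.19, abs=0.05)

    def test_residual_below_tolerance(self):
        for theta, z in [(0.8, 0.01), (0.6, 0.1), (0.95, 0.02)]:
            a = solve_alpha(theta, z)
            res = theta * (1 - math.exp(-a)) - 1 + math.exp(-a * z)
            assert abs(res) < 1e-10

    def test_asymptotic_small_z(self):
        # alpha * z -> -ln(1 - theta) as z -> 0; for theta=0.8 that is ln 5
        for z in (1e-3, 1e-4):
            assert solve_alpha(0.8, z) * z == pytest.approx(
                math.log(5), rel=1e-2
            )

    def test_invalid_inputs(self):
        for theta, z in [(0.0, 0.01), (1.0, 0.01), (0.8, 0.0), (0.1, 0.5)]:
            with pytest.raises(ValueError):
                solve_alpha(theta, z)
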