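"""Weir-Cockerham Fst and windowed nucleotide diversity."""

import numpy as np
import pytest

from oracles import pi_hamming_oracle, wc_fst_oracle
from sweepscan.classic_stats import (FstSiteComponents, fst_site_components,
                                     fst_windowed, pi_site, pi_windowed,
                                     window_grid)


def random_counts(rng, max_n=12):
    n = rng.integers(2, max_n + 1)
    parts = rng.multinomial(n, rng.dirichlet([1, 1, 1]))
    return tuple(int(x) for x in parts)


class TestFstSite:
    def test_fixed_difference_is_one(self):
        c = fst_site_components((10, 0, 0), (0, 0, 10))
        assert c.fst_site == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        c = fst_site_components((2, 6, 2), (2, 6, 2))
        a, den, theta = wc_fst_oracle((2, 6, 2), (2, 6, 2))
        assert c.fst_site == pytest.approx(theta, abs=1e-12)
        assert c.fst_site <= 0

    def test_example_table_matches_oracle(self):
        c = fst_site_components((4, 2, 4), (1, 2, 7))
        _, _, theta = wc_fst_oracle((4, 2, 4), (1, 2, 7))
        assert c.fst_site == pytest.approx(theta, abs=1e-12)

    def test_monomorphic_both_groups_undefined(self):
        c = fst_site_components((10, 0, 0), (8, 0, 0))
        assert c.den == pytest.approx(0.0, abs=1e-15)
        assert np.isnan(c.fst_site)

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 200:
            c1, c2 = random_counts(rng), random_counts(rng)
            a, den, theta = wc_fst_oracle(c1, c2)
            got = fst_site_components(c1, c2)
            assert got.num == pytest.approx(a, abs=1e-10)
            assert got.den == pytest.approx(den, abs=1e-10)
            if den > 1e-12:
                assert got.fst_site == pytest.approx(theta, abs=1e-10)
                assert got.fst_site <= 1 + 1e-12
            checked += 1

    def test_equals_one_only_for_fixed_difference(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            c1, c2 = random_counts(rng), random_counts(rng)
            got = fst_site_components(c1, c2)
            if np.isfinite(got.fst_site) and got.fst_site \
                    == pytest.approx(1.0, abs=1e-12):
                p1 = (c1[1] + 2 * c1[2]) / (2 * sum(c1))
                p2 = (c2[1] + 2 * c2[2]) / (2 * sum(c2))
                assert {p1, p2} == {0.0, 1.0}


def comp(num, den, pos=None):
    fst = num / den if den else float("nan")
    return FstSiteComponents(0, 0, 0, num, den, fst)


class TestFstWindows:
    def test_single_site_window_equals_site(self):
        wins = fst_windowed([25_000], [comp(0.3, 1.0)])
        at = [w for w in wins if w.start <= 25_000 <= w.end]
        assert all(w.value == pytest.approx(0.3) for w in at)

    def test_weighted_is_ratio_of_sums(self):
        wins = fst_windowed([10_000, 12_000], [comp(1, 2), comp(1, 2)],
                            window_bp=50_000, step_bp=50_000)
        (w,) = [w for w in wins if w.n_snps == 2]
        assert w.value == pytest.approx(0.5)

    def test_interior_snp_in_exactly_four_windows(self):
        pos = [200_000, 400_000, 600_000]
        wins = fst_windowed(pos, [comp(1, 2)] * 3, 50_000, 12_500)
        for p in pos:
            n = sum(1 for w in wins if w.start <= p <= w.end)
            assert n == 50_000 // 12_500

    def test_weighted_window_between_site_extremes(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(40_000, 12, replace=False)) + 1
        comps = [comp(rng.uniform(-0.1, 0.8), rng.uniform(0.5, 2.0))
                 for _ in pos]
        wins = fst_windowed(pos, comps, 50_000, 50_000)
        sites = [c.fst_site for c in comps]
        for w in wins:
            if w.n_snps == len(pos):
                assert min(sites) - 1e-12 <= w.value <= max(sites) + 1e-12

    def test_mean_mode_averages_defined_sites(self):
        wins = fst_windowed([1000, 2000], [comp(0.2, 1), comp(0.6, 1)],
                            50_000, 50_000, mode="mean")
        (w,) = [w for w in wins if w.n_snps == 2]
        assert w.value == pytest.approx(0.4)


class TestPi:
    @pytest.mark.parametrize("k,n,expected", [
        (2, 4, 2 * 2 * 2 / 12), (0, 10, 0.0), (1, 2, 1.0)])
    def test_site_values(self, k, n, expected):
        assert pi_site(k, n) == pytest.approx(expected)

    def test_site_matches_hamming_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(2, 20)
            col = rng.integers(0, 2, n)
            assert pi_site(int(col.sum()), n) == pytest.approx(
                pi_hamming_oracle(col), abs=1e-12)

    def test_window_normalizes_by_length(self):
        wins = pi_windowed([500], [2 / 3], window_bp=1000, step_bp=1000)
        assert wins[0].value == pytest.approx(2 / 3 / 1000)

    def test_doubling_window_halves_value(self):
        (w1,) = pi_windowed([500], [0.5], window_bp=1000, step_bp=1000)
        w2 = pi_windowed([500], [0.5], window_bp=2000, step_bp=2000)[0]
        assert w2.value == pytest.approx(w1.value / 2)

    def test_invariant_to_monomorphic_sites(self):
        base = pi_windowed([100, 300], [0.4, 0.2], 1000, 1000)[0].value
        with_mono = pi_windowed([100, 200, 300], [0.4, 0.0, 0.2],
                                1000, 1000)[0].value
        assert with_mono == pytest.approx(base)

    def test_empty_window_value_zero(self):
        wins = pi_windowed([100, 60_000], [0.5, 0.5], 10_000, 10_000)
        gaps = [w for w in wins if w.n_snps == 0]
        assert gaps and all(w.value == 0.0 for w in gaps)


def test_window_grid_step_aligned_and_covering():
    grid = window_grid(60_000, 120_000, 50_000, 12_500)
    assert np.all((grid - 1) % 12_500 == 0)
    assert grid[0] <= 60_000 <= grid[0] + 49_999
    assert grid[-1] <= 120_000
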