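import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import unseenest as u
from conftest import random_histogram


class TestBuildGrid:
    @pytest.mark.parametrize(
        "x_min,x_max,ratio,expected",
        [
            (0.25, 1.0, 2.0, [0.25, 0.5, 1.0]),
            (0.5, 0.5, 1.05, [0.5]),
        ],
    )
    def test_examples(self, x_min, x_max, ratio, expected):
        np.testing.assert_allclose(u.build_grid(x_min, x_max, ratio).points, expected)

    def test_length_matches_logarithm(self):
        g = u.build_grid(1e-6, 1.0, 1.05)
        assert len(g) == math.ceil(math.log(1e6) / math.log(1.05)) + 1
        assert g.points[0] == 1e-6 and g.points[-1] == 1.0
        assert np.all(np.diff(g.points) > 0)

    @pytest.mark.parametrize(
        "kwargs", [dict(x_min=0.0, x_max=1.0), dict(x_min=0.5, x_max=0.2),
                   dict(x_min=0.1, x_max=1.0, ratio=1.0), dict(x_min=0.1, x_max=1.5)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            u.build_grid(**{"ratio": 1.05, **kwargs})


class TestBinomialKernel:
    def test_simple_values(self):
        assert u.binomial_kernel(0.5, 2, 1) == pytest.approx(0.5)
        assert u.binomial_kernel(1.0, 10, 10) == pytest.approx(1.0)

    def test_poisson_matches_exact_in_rare_regime(self):
        exact = u.binomial_kernel(1e-4, 10_000, 2, approx=False)
        pois = u.binomial_kernel(1e-4, 10_000, 2, approx=True)
        assert exact == pytest.approx(math.exp(-1) / 2, rel=1e-3)
        assert abs(exact - pois) < 1e-4

    def test_poisson_agreement_lattice(self):
        # |exact - Poisson| <= 1e-3 whenever k*x <= 5 and k >= 1000
        for k in (1000, 5000, 20_000):
            for lam in (0.1, 0.5, 1.0, 2.0, 5.0):
                x = lam / k
                for i in range(0, 12):
                    d = abs(
                        u.binomial_kernel(x, k, i) - u.binomial_kernel(x, k, i, approx=True)
                    )
                    assert d <= 1e-3

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            u.binomial_kernel(1.2, 10, 1)
        with pytest.raises(ValueError):
            u.binomial_kernel(0.5, 10, 11)


class TestMixingMatrix:
    def test_degenerate_columns(self):
        B = u.build_mixing_matrix(u.FrequencyGrid(np.array([1.0])), k=5, i_max=5)
        np.testing.assert_allclose(B.entries[:, 0], [0, 0, 0, 0, 0, 1], atol=1e-12)
        B2 = u.build_mixing_matrix(u.FrequencyGrid(np.array([0.5])), k=2, i_max=2)
        np.testing.assert_allclose(B2.entries[:, 0], [0.25, 0.5, 0.25])

    def test_matches_elementwise_kernel(self):
        grid = u.build_grid(1e-4, 0.05, 1.3)
        B = u.build_mixing_matrix(grid, k=1000, i_max=20)
        for i in range(21):
            for j, x in enumerate(grid.points):
                assert B.entries[i, j] == pytest.approx(
                    u.binomial_kernel(x, 1000, i), abs=1e-12
                )

    def test_column_sums(self):
        grid = u.build_grid(0.01, 1.0, 1.5)
        partial = u.build_mixing_matrix(grid, k=50, i_max=10)
        assert np.all(partial.entries.sum(axis=0) <= 1 + 1e-12)
        full = u.build_mixing_matrix(grid, k=50, i_max=50)
        np.testing.assert_allclose(full.entries.sum(axis=0), 1.0, rtol=1e-10)

    def test_i_max_beyond_k_rejected(self):
        with pytest.raises(ValueError):
            u.build_mixing_matrix(u.FrequencyGrid(np.array([0.5])), k=5, i_max=6)


class TestExpectedSfs:
    def test_fixed_variants(self):
        h = u.FrequencyHistogram(u.FrequencyGrid(np.array([1.0])), np.array([7.0]))
        E = u.expected_sfs(h, 4)
        np.testing.assert_allclose(E, [0, 0, 0, 0, 7], atol=1e-12)

    def test_exact_binomial_half(self):
        h = u.FrequencyHistogram(u.FrequencyGrid(np.array([0.5])), np.array([100.0]))
        np.testing.assert_allclose(u.expected_sfs(h, 2), [25, 50, 25])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        h = random_histogram(rng)
        k = int(rng.integers(2, 300))
        total = u.expected_sfs(h, k).sum()
        assert total == pytest.approx(h.total, rel=1e-8)

    def test_frequent_part_contributes(self):
        grid = u.FrequencyGrid(np.array([0.001]))
        h = u.FrequencyHistogram(grid, np.array([0.0]), frequent_part=((0.5, 100.0),))
        np.testing.assert_allclose(u.expected_sfs(h, 2), [25, 50, 25])

    def test_monte_carlo_mixture(self):
        h = u.FrequencyHistogram(
            u.FrequencyGrid(np.array([0.01, 0.1])), np.array([1000.0, 100.0])
        )
        k, reps = 50, 20_000
        rng = np.random.default_rng(42)
        freqs = np.repeat([0.01, 0.1], [1000, 100])
        draws = rng.binomial(k, freqs, size=(reps, len(freqs)))
        E = u.expected_sfs(h, k)
        for i in range(0, 8):
            per_rep = (draws == i).sum(axis=1)
            se = per_rep.std(ddof=1) / math.sqrt(reps)
            assert abs(per_rep.mean() - E[i]) <= 3 * se + 1e-9


class TestExpectedUnique:
    def test_fixed_and_zero(self):
        h = u.FrequencyHistogram(u.FrequencyGrid(np.array([1.0])), np.array([42.0]))
        assert u.expected_unique(h, 1) == pytest.approx(42.0)
        assert u.expected_unique(h, 0) == 0.0

    def test_closed_form_vs_simulation(self):
        h = u.FrequencyHistogram(u.FrequencyGrid(np.array([0.001])), np.array([10_000.0]))
        closed = u.expected_unique(h, 1000)
        assert closed == pytest.approx(10_000 * (1 - 0.999 ** 1000), rel=1e-12)
        rng = np.random.default_rng(7)
        reps = 500
        distinct = (rng.binomial(1000, 0.001, size=(reps, 10_000)) > 0).sum(axis=1)
        se = distinct.std(ddof=1) / math.sqrt(reps)
        assert abs(distinct.mean() - closed) <= 3 * se

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_n(self, seed):
        rng = np.random.default_rng(seed)
        h = random_histogram(rng)
        ns = np.sort(rng.integers(0, 100_000, size=6))
        vals = [u.expected_unique(h, int(n)) for n in ns]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        assert all(v <= h.total + 1e-9 for v in vals)

    def test_negative_n_rejected(self):
        h = u.FrequencyHistogram(u.FrequencyGrid(np.array([0.5])), np.array([1.0]))
        with pytest.raises(ValueError):
            u.expected_unique(h, -1)


class TestSerialisation:
    def test_sfs_round_trip(self, tmp_path):
        sfs = u.SiteFrequencySpectrum(k=100, counts={1: 10, 2: 5, 99: 1}, label="demo")
        p = tmp_path / "sfs.tsv"
        u.write_sfs(sfs, p)
        back = u.read_sfs(p)
        assert back.k == sfs.k and back.counts == sfs.counts and back.label == "demo"

    def test_sfs_reader_tolerates_comments_and_blanks(self, tmp_path):
        p = tmp_path / "messy.tsv"
        p.write_text("# a comment\n\n#k=10\ncount\tnum_variants\n1\t3\n\n2\t1\n")
        sfs = u.read_sfs(p)
        assert sfs.k == 10 and sfs.counts == {1: 3, 2: 1}

    def test_histogram_round_trip(self, tmp_path):
        h = u.FrequencyHistogram(
            u.build_grid(1e-4, 0.1, 2.0),
            np.array([1.5, 2.5, 0.0, 4.0, 1.0, 0.25, 3.5, 0.75, 2.0, 1.25, 0.5]),
            frequent_part=((0.5, 12.0),),
        )
        p = tmp_path / "hist.tsv"
        u.write_histogram(h, p)
        back = u.read_histogram(p)
        np.testing.assert_array_equal(back.grid.points, h.grid.points)
        np.testing.assert_array_equal(back.mass, h.mass)
        assert back.frequent_part == h.frequent_part
        assert back.total == pytest.approx(h.total)


class TestInvariants:
    def test_sfs_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            u.SiteFrequencySpectrum(k=5, counts={6: 1})
        with pytest.raises(ValueError):
            u.SiteFrequencySpectrum(k=5, counts={0: 1})
        with pytest.raises(ValueError):
            u.SiteFrequencySpectrum(k=5, counts={1: -2})

    def test_histogram_rejects_negative_mass(self):
        with pytest.raises(ValueError):
            u.FrequencyHistogram(u.FrequencyGrid(np.array([0.5])), np.array([-1.0]))

    def test_simulated_cohort_sfs_matches_expected(self, neutral_cohort):
        # chi-square-style bound: observed F_i within MC noise of E[F_i]
        h_true, cohort = neutral_cohort
        E = u.expected_sfs(h_true, cohort.k, 30)
        F = cohort.sfs.to_array(30)
        for i in range(1, 31):
            sd = math.sqrt(max(E[i], 1.0))
            assert abs(F[i] - E[i]) <= 5 * sd
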