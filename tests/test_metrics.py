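"""Unit and property tests for the pairwise dependence metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from nlfnc import (
    HistogramConfig,
    boosted_connectivity,
    dependence,
    entropy_from_counts,
    explicit_nonlinear_nmi,
    joint_histogram,
    normalized_mutual_information,
    pearson_correlation,
    remove_linear,
    rice_rule,
)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [-2, -4, -6], -1.0),
            ([1, 2, 3, 4], [1, -1, -1, 1], 0.0),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self, rng):
        x, y = rng.standard_normal((2, 50))
        assert pearson_correlation(x, y) == pytest.approx(pearson_correlation(y, x))

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pearson_correlation([1, 2, 3], [1, 2])


class TestRemoveLinear:
    def test_exact_linear_gives_zero_residual(self):
        x = np.arange(10.0)
        fit = remove_linear(x, 2 * x)
        assert fit.alpha == pytest.approx(2.0)
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.residual, 0.0, atol=1e-12)

    def test_residual_uncorrelated_with_regressor(self, rng):
        # normal equations: residual orthogonal to x, zero mean
        for _ in range(100):
            x = rng.standard_normal(159)
            y = rng.standard_normal(159) + 0.5 * x
            fit = remove_linear(x, y)
            assert abs(pearson_correlation(x, fit.residual)) < 1e-10
            assert abs(fit.residual.mean()) < 1e-10

    def test_residual_identity(self, rng):
        x, y = rng.standard_normal((2, 40))
        fit = remove_linear(x, y)
        np.testing.assert_allclose(fit.residual, y - fit.fitted, atol=1e-14)

    def test_constant_regressor_raises(self):
        with pytest.raises(ValueError, match="degenerate regressor"):
            remove_linear(np.ones(10), np.arange(10.0))


class TestJointHistogram:
    def test_unit_square_corners(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        counts = joint_histogram(x, y, HistogramConfig(bins=2, bin_rule="fixed"))
        np.testing.assert_array_equal(counts, [[1, 1], [1, 1]])

    def test_counts_conserved(self, rng):
        x, y = rng.standard_normal((2, 137))
        counts = joint_histogram(x, y, HistogramConfig(bins=7, bin_rule="fixed"))
        assert counts.sum() == 137

    def test_matches_bruteforce_assignment(self, rng):
        b = 5
        x, y = rng.uniform(-3, 5, (2, 200))
        counts = joint_histogram(x, y, HistogramConfig(bins=b, bin_rule="fixed"))
        # independent brute-force loop: equal-width bins over [min, max],
        # internal-edge values to the higher bin, max in the top bin
        expected = np.zeros((b, b), dtype=int)
        for xi, yi in zip(x, y):
            bx = min(int((xi - x.min()) / (x.max() - x.min()) * b), b - 1)
            by = min(int((yi - y.min()) / (y.max() - y.min()) * b), b - 1)
            expected[bx, by] += 1
        np.testing.assert_array_equal(counts, expected)

    def test_constant_variable_collapses_to_one_bin(self):
        counts = joint_histogram(np.ones(20), np.arange(20.0),
                                 HistogramConfig(bins=4, bin_rule="fixed"))
        assert counts.sum(axis=1)[0] == 20
        assert entropy_from_counts(counts.sum(axis=1)) == 0.0


class TestEntropy:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1, 1, 1, 1], 2.0),
            ([4], 0.0),
            ([2, 1, 1], 1.5),
            ([0, 8, 0], 0.0),
        ],
    )
    def test_known_values(self, counts, expected):
        assert entropy_from_counts(counts) == pytest.approx(expected, abs=1e-14)

    def test_empty_histogram_raises(self):
        with pytest.raises(ValueError, match="empty"):
            entropy_from_counts([0, 0, 0])

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError, match="negative"):
            entropy_from_counts([3, -1])


class TestNMI:
    def test_identical_series_give_one(self, rng):
        x = rng.standard_normal(500)
        for norm in ("joint", "max"):
            for b in (4, 10, 20):
                cfg = HistogramConfig(bins=b, bin_rule="fixed", normalization=norm)
                est = normalized_mutual_information(x, x, cfg)
                assert est.nmi == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_gives_zero(self):
        est = normalized_mutual_information(np.ones(50), np.arange(50.0))
        assert est.nmi == 0.0
        assert est.mi == pytest.approx(0.0, abs=1e-12)

    def test_mi_matches_direct_formula(self, rng):
        # oracle: MI = sum_ij p_ij log2(p_ij / (p_i p_j)) on the same grid
        for _ in range(20):
            x = rng.standard_normal(300)
            y = rng.standard_normal(300) + 0.7 * x * x
            cfg = HistogramConfig(bins=8, bin_rule="fixed")
            counts = joint_histogram(x, y, cfg)
            p = counts / counts.sum()
            px = p.sum(axis=1, keepdims=True)
            py = p.sum(axis=0, keepdims=True)
            nz = p > 0
            mi_direct = float((p[nz] * np.log2(p[nz] / (px @ py)[nz])).sum())
            est = normalized_mutual_information(x, y, cfg)
            assert est.mi == pytest.approx(mi_direct, abs=1e-12)

    def test_bounds_over_random_pairs(self, rng):
        for _ in range(250):
            n = int(rng.integers(20, 400))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + rng.uniform(-1, 1) * x
            for b in (4, 10, 20, 64):
                for norm in ("joint", "max"):
                    cfg = HistogramConfig(bins=b, bin_rule="fixed", normalization=norm)
                    est = normalized_mutual_information(x, y, cfg)
                    assert 0.0 <= est.nmi <= 1.0 + 1e-12
                    assert 0.0 <= est.mi <= min(est.hx, est.hy) + 1e-12
                    assert est.hxy <= est.hx + est.hy + 1e-12

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal((2, 200))
        cfg = HistogramConfig(bins=12, bin_rule="fixed")
        base = normalized_mutual_information(x, y, cfg).nmi
        shifted = normalized_mutual_information(3.0 * x + 7.0, 0.25 * y - 2.0, cfg).nmi
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_independent_series_near_zero(self, rng):
        # plug-in bias bound: large-sample independent pairs stay small
        x = rng.standard_normal(10_000)
        y = rng.standard_normal(10_000)
        cfg = HistogramConfig(bins=10, bin_rule="fixed")
        for norm in ("joint", "max"):
            cfg = HistogramConfig(bins=10, bin_rule="fixed", normalization=norm)
            assert normalized_mutual_information(x, y, cfg).nmi < 0.05


class TestExplicitNonlinearNMI:
    def test_symmetric_exactly(self, rng):
        x = rng.standard_normal(159)
        y = rng.standard_normal(159) + x * x
        assert explicit_nonlinear_nmi(x, y) == explicit_nonlinear_nmi(y, x)

    def test_pure_affine_pair_gives_zero_residual_dependence(self):
        x = np.linspace(0, 1, 100)
        y = -3.0 * x + 2.0
        # residuals are identically zero vectors -> constant -> NMI 0
        assert explicit_nonlinear_nmi(x, y) == 0.0

    def test_constant_series_gives_zero(self):
        assert explicit_nonlinear_nmi(np.ones(30), np.arange(30.0)) == 0.0

    def test_quadratic_dependence_survives_residualization(self, rng):
        x = rng.uniform(0, 1, 1000)
        y = 5 * (x - 0.5) ** 2 + rng.normal(0, 0.1, 1000)
        before = normalized_mutual_information(x, y).nmi
        after = explicit_nonlinear_nmi(x, y)
        assert after > 0.15
        assert abs(before - after) < 0.05


class TestBoosted:
    def test_formula_against_components(self, rng):
        x = rng.uniform(0, 1, 400)
        y = 2 * x + rng.normal(0, 0.3, 400)
        rho = pearson_correlation(x, y)
        enmi = explicit_nonlinear_nmi(x, y)
        boosted = boosted_connectivity(x, y)
        assert boosted == pytest.approx(rho + math.copysign(enmi, rho), abs=1e-14)
        assert abs(boosted) >= abs(rho)

    def test_negative_correlation_boosts_negatively(self, rng):
        x = rng.uniform(0, 1, 400)
        y = -2 * x + rng.normal(0, 0.3, 400)
        boosted = boosted_connectivity(x, y)
        rho = pearson_correlation(x, y)
        assert boosted < rho < 0

    def test_dependence_bundles_consistently(self, rng):
        x = rng.uniform(0, 1, 300)
        y = 5 * (x - 0.5) ** 2 + rng.normal(0, 0.1, 300)
        res = dependence(x, y)
        assert res.rho == pytest.approx(pearson_correlation(x, y))
        assert res.enmi == pytest.approx(explicit_nonlinear_nmi(x, y))
        assert abs(res.boosted) >= abs(res.rho)


class TestMetricProperties:
    """Invariants that must hold for arbitrary finite inputs."""

    @staticmethod
    def _series(min_size=10, max_size=200):
        return hnp.arrays(
            np.float64,
            st.shared(st.integers(min_size, max_size), key="n"),
            elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
        )

    @given(x=_series(), y=_series(), bins=st.integers(2, 32))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_nmi_bounded_and_mi_consistent(self, x, y, bins):
        cfg = HistogramConfig(bins=bins, bin_rule="fixed")
        est = normalized_mutual_information(x, y, cfg)
        assert 0.0 <= est.nmi <= 1.0 + 1e-12
        assert -1e-12 <= est.mi <= min(est.hx, est.hy) + 1e-12
        assert est.hxy <= est.hx + est.hy + 1e-12

    @given(x=_series(), y=_series())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_enmi_symmetric_and_bounded(self, x, y):
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            assert explicit_nonlinear_nmi(x, y) == 0.0
            return
        forward = explicit_nonlinear_nmi(x, y)
        assert forward == explicit_nonlinear_nmi(y, x)
        assert 0.0 <= forward <= 1.0 + 1e-12


class TestConfig:
    @pytest.mark.parametrize("n, expected", [(1000, 20), (159, 11), (8, 4)])
    def test_rice_rule(self, n, expected):
        assert rice_rule(n) == expected

    def test_rice_default_resolves_from_length(self):
        cfg = HistogramConfig()
        assert cfg.n_bins(1000) == 20
        assert cfg.n_bins(159) == 11

    def test_invalid_configs_raise(self):
        with pytest.raises(ValueError):
            HistogramConfig(bins=1)
        with pytest.raises(ValueError):
            HistogramConfig(bin_rule="fixed")
        with pytest.raises(ValueError):
            HistogramConfig(normalization="geometric")
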