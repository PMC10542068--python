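import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filmrelease import (
    ModelKind,
    PartitionParameters,
    ReleaseGeometry,
    RootSet,
    compute_alpha,
    find_roots,
    fractional_release_erfc,
    fractional_release_series,
    partition_coefficient,
    select_model,
    series_weights,
)

from conftest import bisect_root


class TestAlphaAndPartition:
    @pytest.mark.parametrize(
        "V_S, V_F, K, expected",
        [
            (1.0, 1.0, 1.0, 1.0),
            (4.0, 1.0, 2.0, 2.0),
            (2e-4, 2e-8, 0.681, 2e-4 / (0.681 * 2e-8)),  # ~1.468e4
        ],
    )
    def test_volume_ratio(self, V_S, V_F, K, expected):
        assert compute_alpha(V_S, V_F, K) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", ["V_S", "V_F", "K_FS"])
    def test_nonpositive_argument_is_named_in_error(self, bad):
        kwargs = {"V_S": 1.0, "V_F": 1.0, "K_FS": 1.0, bad: 0.0}
        with pytest.raises(ValueError, match=bad):
            compute_alpha(**kwargs)

    @pytest.mark.parametrize(
        "cf, cs, expected", [(0.681, 1.0, 0.681), (0.0, 1.0, 0.0), (5.0, 5.0, 1.0)]
    )
    def test_partition_coefficient(self, cf, cs, expected):
        assert partition_coefficient(cf, cs) == pytest.approx(expected)

    def test_no_release_at_equilibrium_is_undefined(self):
        with pytest.raises(ValueError, match="C_S_inf"):
            partition_coefficient(1.0, 0.0)

    def test_partition_parameters_from_geometry(self):
        geom = ReleaseGeometry(1e-4, 2e-8, 2e-4)
        pp = PartitionParameters.from_geometry(geom, K_FS=0.681)
        assert pp.alpha == pytest.approx(compute_alpha(2e-4, 2e-8, 0.681))


class TestGeometry:
    def test_two_sided_uses_half_thickness(self):
        geom = ReleaseGeometry(1e-4, 1e-7, 1e-4, exposure="two_sided")
        assert geom.characteristic_length == pytest.approx(5e-5)

    def test_one_sided_uses_full_thickness(self):
        geom = ReleaseGeometry(1e-4, 1e-7, 1e-4, exposure="one_sided")
        assert geom.characteristic_length == pytest.approx(1e-4)

    @pytest.mark.parametrize("field", ["thickness", "volume_film", "volume_simulant"])
    def test_rejects_nonpositive_dimensions(self, field):
        kwargs = {"thickness": 1e-4, "volume_film": 1e-7, "volume_simulant": 1e-4}
        kwargs[field] = -1.0
        with pytest.raises(ValueError, match=field):
            ReleaseGeometry(**kwargs)


class TestRoots:
    def test_first_root_alpha_one(self):
        # frozen from the independent bisection oracle (tan form, tol 1e-12)
        rs = find_roots(1.0, 1)
        assert rs.roots[0] == pytest.approx(2.028757838110, abs=1e-9)

    def test_small_alpha_limit_approaches_k_pi(self):
        rs = find_roots(1e-9, 6)
        assert rs.roots == pytest.approx(np.arange(1, 7) * np.pi, rel=1e-6)

    def test_large_alpha_limit_approaches_poles(self):
        rs = find_roots(1e9, 6)
        assert rs.roots == pytest.approx((2 * np.arange(1, 7) - 1) * np.pi / 2, rel=1e-6)

    def test_default_root_count_is_twelve(self):
        assert find_roots(0.5).n_roots == 12

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.floats(min_value=-4.0, max_value=4.0))
    def test_roots_satisfy_characteristic_equation_in_brackets(self, log_alpha):
        alpha = 10.0**log_alpha
        rs = find_roots(alpha, 12)
        k = np.arange(1, 13)
        assert np.all(rs.roots > (k - 0.5) * np.pi)
        assert np.all(rs.roots < k * np.pi)
        assert np.all(np.diff(rs.roots) > 0)
        # residual of the tan form, evaluated away from the tangent poles
        q = rs.roots
        safe = np.abs(np.cos(q)) > 1e-3
        assert np.all(np.abs(np.tan(q[safe]) + alpha * q[safe]) < 1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-3.0, max_value=3.0),
        st.integers(min_value=1, max_value=12),
    )
    def test_roots_match_independent_bisection(self, log_alpha, k):
        alpha = 10.0**log_alpha
        rs = find_roots(alpha, k)
        assert rs.roots[k - 1] == pytest.approx(bisect_root(alpha, k), abs=1e-8)

    def test_rootset_validates_bracket_membership(self):
        with pytest.raises(ValueError, match="bracket|lie in"):
            RootSet(alpha=1.0, roots=np.array([1.0]))  # below (1/2)pi

    def test_rootset_requires_increasing_roots(self):
        good = find_roots(1.0, 3).roots
        with pytest.raises(ValueError, match="increasing"):
            RootSet(alpha=1.0, roots=good[::-1])


class TestSeriesModel:
    def test_weights_sum_approaches_one_with_more_roots(self):
        alpha = 0.05
        deficits = [
            1.0 - series_weights(alpha, find_roots(alpha, n)).sum()
            for n in (12, 100, 400, 1600)
        ]
        assert all(d > 0 for d in deficits)
        assert np.all(np.diff(deficits) < 0)
        # tail of the weight sum decays like 2(1+a)/(a pi^2 N)
        bound = 2 * (1 + alpha) / (alpha * np.pi**2 * 1600)
        assert deficits[-1] < 1.1 * bound

    def test_value_at_time_zero_is_the_truncation_deficit(self, geometry_for_alpha):
        alpha = 5.0
        geom = geometry_for_alpha(alpha)
        roots = find_roots(alpha)
        raw = fractional_release_series(0.0, 1e-13, geom, alpha, roots, clip=False)
        deficit = 1.0 - series_weights(alpha, roots).sum()
        assert raw == pytest.approx(deficit, abs=1e-14)
        assert 0.0 < raw < 0.05

    def test_equilibrium_limit_is_one(self, geometry_for_alpha):
        geom = geometry_for_alpha(0.5)
        roots = find_roots(0.5)
        assert fractional_release_series(1e12, 1e-13, geom, 0.5, roots) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha", [0.05, 0.5, 5.0])
    def test_monotone_in_time_and_diffusivity(self, geometry_for_alpha, alpha):
        geom = geometry_for_alpha(alpha)
        roots = find_roots(alpha)
        t = np.linspace(0.0, 2e5, 80)
        v1 = fractional_release_series(t, 1e-13, geom, alpha, roots)
        assert np.all(np.diff(v1) >= -1e-15)
        v2 = fractional_release_series(t, 3e-13, geom, alpha, roots)
        assert np.all(v2 - v1 >= -1e-12)

    def test_output_stays_in_unit_interval(self, geometry_for_alpha):
        geom = geometry_for_alpha(0.0147)
        roots = find_roots(0.0147)
        t = np.geomspace(1.0, 1e7, 50)
        v = fractional_release_series(t, 2.114e-13, geom, 0.0147, roots)
        assert np.all((v >= 0.0) & (v <= 1.0))

    def test_mismatched_rootset_alpha_is_rejected(self, geometry_for_alpha):
        geom = geometry_for_alpha(0.5)
        roots = find_roots(0.4)
        with pytest.raises(ValueError, match="alpha"):
            fractional_release_series(10.0, 1e-13, geom, 0.5, roots)

    def test_scalar_in_scalar_out(self, geometry_for_alpha):
        geom = geometry_for_alpha(1.0)
        v = fractional_release_series(100.0, 1e-13, geom, 1.0, find_roots(1.0))
        assert isinstance(v, float)


class TestErfcModel:
    def test_zero_at_time_zero(self, geometry_for_alpha):
        geom = geometry_for_alpha(0.005)
        assert fractional_release_erfc(0.0, 1e-14, geom, 0.005) == 0.0

    def test_large_time_asymptote_is_one_plus_alpha_and_flagged(self, geometry_for_alpha):
        alpha = 0.005
        geom = geometry_for_alpha(alpha)
        with pytest.warns(RuntimeWarning, match="exceeds 1"):
            v = fractional_release_erfc(1e9, 1e-12, geom, alpha)
        assert v == pytest.approx(1.0 + alpha, rel=1e-4)
        assert np.isfinite(v)  # scaled erfc: no overflow at huge omega

    def test_monotone_in_time(self, geometry_for_alpha):
        geom = geometry_for_alpha(0.005)
        t = np.linspace(0.0, 5.0, 200)
        v = fractional_release_erfc(t, 1e-14, geom, 0.005)
        assert np.all(np.diff(v) > 0)

    def test_agrees_with_converged_series_at_small_release(self, geometry_for_alpha):
        # the short-time erfc form and the eigenfunction series describe the
        # same solution; with enough roots they coincide below release ~0.1
        alpha, D = 0.005, 1e-14
        geom = geometry_for_alpha(alpha)
        roots = find_roots(alpha, 2000)
        L = geom.characteristic_length
        t = alpha**2 * L**2 / D * np.array([0.002, 0.004, 0.006, 0.008])
        e = fractional_release_erfc(t, D, geom, alpha)
        s = fractional_release_series(t, D, geom, alpha, roots)
        assert np.all(e <= 0.1)
        assert np.max(np.abs(e - s)) < 1e-3


class TestModelSelection:
    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (0.0147, ModelKind.SERIES),
            (7.34e-4, ModelKind.ERFC),
            (0.01, ModelKind.SERIES),  # boundary is inclusive for the series
        ],
    )
    def test_alpha_rule(self, alpha, expected):
        assert select_model(alpha) is expected

    def test_above_validated_range_warns_but_uses_series(self):
        with pytest.warns(RuntimeWarning, match="validated"):
            assert select_model(1500.0) is ModelKind.SERIES
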