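"""Delta arithmetic, Rayleigh fractionation and mixing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nitriso.isotope import (
    STANDARD_RATIOS,
    DeltaValue,
    RayleighParams,
    delta_from_ratio,
    denitrification_trajectory,
    mix_pools,
    ratio_from_delta,
    rayleigh_accumulated_product,
    rayleigh_residual,
)


class TestDeltaNotation:
    @pytest.mark.parametrize(
        "r_sample, r_standard, expected",
        [
            (0.0020052, 0.0020052, 0.0),
            (2 * 0.0020052, 0.0020052, 1000.0),
            (1.01 * 0.0020052, 0.0020052, 10.0),
        ],
    )
    def test_delta_from_ratio(self, r_sample, r_standard, expected):
        assert delta_from_ratio(r_sample, r_standard) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "delta, factor", [(0.0, 1.0), (1000.0, 2.0), (-500.0, 0.5)]
    )
    def test_ratio_from_delta(self, delta, factor):
        r_std = STANDARD_RATIOS["AIR"]
        assert ratio_from_delta(delta, r_std) == pytest.approx(factor * r_std, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_ratio_rejected(self, bad):
        with pytest.raises(ValueError, match="r_sample"):
            delta_from_ratio(bad, 1.0)
        with pytest.raises(ValueError, match="r_standard"):
            delta_from_ratio(1.0, bad)

    def test_delta_below_physical_floor_rejected(self):
        with pytest.raises(ValueError):
            ratio_from_delta(-1000.0, 1.0)
        with pytest.raises(ValueError):
            DeltaValue(-1000.5, "V-SMOW")

    def test_unknown_standard_rejected(self):
        with pytest.raises(ValueError, match="SMOW-X"):
            DeltaValue(5.0, "SMOW-X")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(delta=st.floats(-999.0, 5000.0), std=st.sampled_from(sorted(STANDARD_RATIOS)))
    def test_roundtrip_delta_ratio_delta(self, delta, std):
        r_std = STANDARD_RATIOS[std]
        back = delta_from_ratio(ratio_from_delta(delta, r_std), r_std)
        assert back == pytest.approx(delta, abs=1e-9)


class TestRayleighResidual:
    def test_respired_o2_worked_value(self):
        # 88% O2 consumption enriches residual O2 from 27 to ~70 permil
        exact = rayleigh_residual(RayleighParams(27.0, 20.0, "exact"), 0.12)
        linear = rayleigh_residual(RayleighParams(27.0, 20.0, "linear"), 0.12)
        assert exact == pytest.approx(71.4868, abs=1e-3)
        assert linear == pytest.approx(69.4053, abs=1e-3)
        assert abs(exact - 70.0) < 2.5
        assert abs(linear - 70.0) < 2.5

    @pytest.mark.parametrize("form", ["exact", "linear"])
    def test_no_consumption_returns_initial(self, form):
        assert rayleigh_residual(RayleighParams(27.0, 20.0, form), 1.0) == pytest.approx(27.0)

    def test_half_consumed_exact(self):
        assert rayleigh_residual(RayleighParams(27.0, 20.0, "exact"), 0.5) == pytest.approx(
            41.3364, abs=1e-3
        )

    @pytest.mark.parametrize("bad_f", [0.0, -0.1, 1.0001])
    def test_f_out_of_domain(self, bad_f):
        with pytest.raises(ValueError):
            rayleigh_residual(RayleighParams(27.0, 20.0), bad_f)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        delta0=st.floats(-15.0, 15.0),
        epsilon=st.floats(0.5, 30.0),
        f=st.floats(0.01, 0.999),
    )
    def test_forms_agree_at_small_enrichment(self, delta0, epsilon, f):
        if epsilon * (-np.log(f)) >= 5.0:
            return
        exact = rayleigh_residual(RayleighParams(delta0, epsilon, "exact"), f)
        linear = rayleigh_residual(RayleighParams(delta0, epsilon, "linear"), f)
        assert abs(exact - linear) < 0.1

    @pytest.mark.parametrize("form", ["exact", "linear"])
    def test_monotone_enrichment_as_f_decreases(self, form):
        f = np.linspace(1.0, 0.01, 50)
        out = rayleigh_residual(RayleighParams(5.0, 12.0, form), f)
        assert np.all(np.diff(out) > 0)


class TestRayleighMassBalance:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        delta0=st.floats(-50.0, 80.0),
        epsilon=st.floats(-40.0, 40.0),
        f=st.floats(1e-3, 1.0 - 1e-6, exclude_max=True),
    )
    def test_ratio_space_balance_exact_form(self, delta0, epsilon, f):
        params = RayleighParams(delta0, epsilon, "exact")
        res = rayleigh_residual(params, f)
        prod = rayleigh_accumulated_product(params, f)
        lhs = f * (1000.0 + res) + (1.0 - f) * (1000.0 + prod)
        assert lhs == pytest.approx(1000.0 + delta0, rel=1e-9)

    def test_onset_limit_linear_form(self):
        # instantaneous product at onset: delta0 - epsilon
        prod = rayleigh_accumulated_product(RayleighParams(27.0, 20.0, "linear"), 1 - 1e-9)
        assert prod == pytest.approx(7.0, abs=1e-5)

    def test_no_fractionation_product_equals_substrate(self):
        assert rayleigh_accumulated_product(
            RayleighParams(0.0, 0.0, "exact"), 0.5
        ) == pytest.approx(0.0, abs=1e-12)

    def test_exact_form_against_numerical_integration(self):
        # frozen from midpoint integration of dR/dn = R(alpha-1)/n with
        # discrete heavy-atom accounting of the instantaneous product
        # (2e6 steps): 20.933620 permil at delta0=27, eps=20, f=0.12
        prod = rayleigh_accumulated_product(RayleighParams(27.0, 20.0, "exact"), 0.12)
        assert prod == pytest.approx(20.933620, abs=1e-4)

    @pytest.mark.parametrize("bad_f", [0.0, 1.0, 1.5])
    def test_f_domain_open_interval(self, bad_f):
        with pytest.raises(ValueError):
            rayleigh_accumulated_product(RayleighParams(10.0, 5.0), bad_f)


class TestMixPools:
    @pytest.mark.parametrize(
        "pools, expected",
        [
            ([(10.0, 0.0), (10.0, 10.0)], 5.0),
            ([(7.3, 4.2)], 4.2),
            ([(30.0, 12.0), (10.0, 4.0)], 10.0),
        ],
    )
    def test_weighted_mean(self, pools, expected):
        assert mix_pools(pools) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            mix_pools([(0.0, 5.0), (0.0, 7.0)])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mix_pools([(-1.0, 5.0), (2.0, 7.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mix_pools([])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(0.01, 100.0), st.floats(-100.0, 100.0)),
            min_size=1,
            max_size=6,
        )
    )
    def test_mixture_within_endmember_range(self, pools):
        mixed = mix_pools(pools)
        deltas = [d for _, d in pools]
        assert min(deltas) - 1e-9 <= mixed <= max(deltas) + 1e-9

    def test_ratio_space_alternative_close_to_delta_space(self):
        pools = [(30.0, 12.0), (10.0, -4.0), (5.0, 25.0)]
        assert mix_pools(pools, ratio_space=True) == pytest.approx(
            mix_pools(pools), abs=0.1
        )


class TestDenitrificationTrajectory:
    @staticmethod
    def _slope(points):
        return np.polyfit(points[:, 0], points[:, 1], 1)[0]

    def test_equal_fractionations_linear_slope_one(self):
        pts = denitrification_trajectory(
            4.4, 2.8, 15.0, 15.0, np.linspace(1.0, 0.1, 10), form="linear"
        )
        assert self._slope(pts) == pytest.approx(1.0, abs=1e-12)

    def test_slope_equals_fractionation_ratio(self):
        pts = denitrification_trajectory(
            4.4, 2.8, 15.0, 30.0, np.linspace(1.0, 0.1, 10), form="linear"
        )
        assert self._slope(pts) == pytest.approx(2.0, abs=1e-12)

    def test_exact_form_slope_near_one_for_small_deltas(self):
        # exact-form trajectories are collinear with slope
        # (1000 + delta18_0) / (1000 + delta15_0)
        pts = denitrification_trajectory(
            4.4, 2.8, 15.0, 15.0, np.linspace(1.0, 0.1, 10), form="exact"
        )
        assert self._slope(pts) == pytest.approx(1002.8 / 1004.4, abs=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            denitrification_trajectory(4.4, 2.8, 15.0, 15.0, [])

    def test_non_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            denitrification_trajectory(4.4, 2.8, 15.0, 15.0, [0.5, 0.5, 0.4])
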