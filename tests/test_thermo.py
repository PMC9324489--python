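"""Unit and property tests for the heat-balance / sweat-rate chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import citysweat.thermo as th

MMHG = 0.133322


def svp_oracle_kpa(t):
    """Direct single-expression evaluation of the saturation curve, mmHg→kPa."""
    return math.exp(18.6686 - 4030.183 / (t + 235.0)) * MMHG


def bisect_tcl(tsk, ta, tr, icl, fcl, hc, fr, hr, iters=200):
    """Independent bisection solve of the clothing conduction balance."""

    def f(t):
        return (tsk - t) / icl - fcl * hc * (t - ta) - fr * hr * (t - tr)

    lo = min(ta, tr, tsk) - 5.0
    hi = max(ta, tr, tsk) + 5.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@pytest.mark.parametrize(
    "ta, expected",
    [(0.0, 26.6), (23.0, 31.545), (34.0, 33.91)],
)
def test_skin_temperature_linear(ta, expected):
    assert th.skin_temperature(ta) == pytest.approx(expected)


class TestSaturationVaporPressure:
    def test_boiling_point_near_one_atmosphere(self):
        # unit-convention check: the Antoine constants are mmHg-native
        assert th.saturation_vapor_pressure(100.0) == pytest.approx(101.325, rel=0.02)

    @pytest.mark.parametrize("t", [26.6, 31.545, 100.0, -10.0, 0.0])
    def test_matches_direct_oracle(self, t):
        assert th.saturation_vapor_pressure(t) == pytest.approx(svp_oracle_kpa(t))

    def test_skin_vapor_pressure_is_saturation_at_tsk(self):
        tsk = th.skin_temperature(23.0)
        assert th.skin_vapor_pressure(tsk) == pytest.approx(svp_oracle_kpa(31.545))
        assert th.skin_vapor_pressure(tsk) == pytest.approx(4.63, abs=0.01)

    def test_cold_skin_value(self):
        assert th.skin_vapor_pressure(26.6) == pytest.approx(3.49, abs=0.01)

    @given(st.floats(min_value=-30, max_value=60), st.floats(min_value=0.01, max_value=5))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, t, dt):
        assert th.saturation_vapor_pressure(t + dt) > th.saturation_vapor_pressure(t)

    def test_domain_error_below_antoine_singularity(self):
        with pytest.raises(ValueError):
            th.saturation_vapor_pressure(-235.0)

    def test_as_printed_flag_skips_conversion(self):
        c = th.ModelConstants(vapor_unit="as_printed")
        assert th.saturation_vapor_pressure(30.0, c) == pytest.approx(
            svp_oracle_kpa(30.0) / MMHG
        )


class TestAmbientVaporPressure:
    def test_dry_air_is_zero(self):
        assert th.ambient_vapor_pressure(23.0, 0.0) == 0.0

    def test_saturated_and_half(self):
        sat = th.saturation_vapor_pressure(23.0)
        assert th.ambient_vapor_pressure(23.0, 1.0) == pytest.approx(sat)
        assert th.ambient_vapor_pressure(23.0, 0.5) == pytest.approx(0.5 * sat)

    def test_rejects_rh_outside_unit_interval(self):
        with pytest.raises(ValueError):
            th.ambient_vapor_pressure(23.0, 1.2)


class TestMetabolicRate:
    def test_unit_bracket_at_rq_one(self):
        assert th.metabolic_rate_from_gas(1.0, 1.8, 1.8) == pytest.approx(21.0)

    def test_hand_arithmetic(self):
        assert th.metabolic_rate_from_gas(0.85, 5.9, 1.8) == pytest.approx(
            21.0 * 0.9655 * (5.9 / 1.8)
        )

    def test_linear_in_vo2(self):
        one = th.metabolic_rate_from_gas(0.85, 3.0, 1.8)
        assert th.metabolic_rate_from_gas(0.85, 6.0, 1.8) == pytest.approx(2 * one)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            th.metabolic_rate_from_gas(0.85, 0.0, 1.8)
        with pytest.raises(ValueError):
            th.metabolic_rate_from_gas(0.85, 5.0, -1.0)


@pytest.mark.parametrize(
    "eta, m, expected", [(0.0, 220.0, 0.0), (0.05, 220.0, 11.0), (0.10, 75.0, 7.5)]
)
def test_mechanical_work(eta, m, expected):
    assert th.mechanical_work(m, eta) == pytest.approx(expected)


def test_mechanical_work_rejects_out_of_range_efficiency():
    with pytest.raises(ValueError):
        th.mechanical_work(100.0, 0.2)


class TestClothingSurfaceTemperature:
    def _call(self, tsk, ta, tr, icl_si, fcl, hc, fr, hr=4.7):
        env = th.Environment(ta=ta, tr=tr, rh=0.5)
        act = th.ActivityLevel("x", M=75.0, hc=hc, fr=fr)
        clo = th.ClothingEnsemble("x", fcl=fcl, Icl=icl_si, icl=0.5, Icl_unit="si")
        consts = th.ModelConstants(hr=hr)
        return th.clothing_surface_temperature(tsk, env, act, clo, consts)

    def test_zero_gradient_fixed_point(self):
        assert self._call(23.0, 23.0, 23.0, 0.155, 1.1, 4.0, 0.7) == pytest.approx(23.0)

    def test_vanishing_insulation_approaches_skin(self):
        tcl = self._call(31.5, 23.0, 23.0, 1e-8, 1.1, 4.0, 0.7)
        assert tcl == pytest.approx(31.5, abs=1e-4)

    def test_matches_bisection_oracle_on_spec_state(self):
        tcl = self._call(31.5, 23.0, 23.0, 0.155, 1.1, 4.0, 0.7)
        oracle = bisect_tcl(31.5, 23.0, 23.0, 0.155, 1.1, 4.0, 0.7, 4.7)
        assert tcl == pytest.approx(oracle, abs=1e-4)
        assert 23.0 <= tcl <= 31.5

    def test_matches_bisection_oracle_on_randomized_states(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            tsk = rng.uniform(27.0, 36.0)
            ta = rng.uniform(-5.0, 35.0)
            tr = ta + rng.uniform(-3.0, 3.0)
            icl = rng.uniform(0.02, 0.4)
            fcl = rng.uniform(1.0, 1.5)
            hc = rng.uniform(2.0, 10.0)
            fr = rng.uniform(0.2, 1.0)
            tcl = self._call(tsk, ta, tr, icl, fcl, hc, fr)
            oracle = bisect_tcl(tsk, ta, tr, icl, fcl, hc, fr, 4.7)
            assert tcl == pytest.approx(oracle, abs=1e-4)
        # between-bounds property when tr == ta
        tcl = self._call(33.0, 20.0, 20.0, 0.1, 1.2, 4.0, 0.7)
        assert 20.0 <= tcl <= 33.0


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (th.convective_loss, (1.1, 4.0, 28.0, 23.0), 22.0),
        (th.convective_loss, (1.1, 4.0, 23.0, 23.0), 0.0),
        (th.radiant_loss, (0.7, 4.7, 28.0, 23.0), 16.45),
        (th.radiant_loss, (0.7, 4.7, 23.0, 23.0), 0.0),
    ],
)
def test_dry_losses(fn, args, expected):
    assert fn(*args) == pytest.approx(expected)


def test_dry_loss_antisymmetry_and_linearity():
    assert th.convective_loss(1.1, 4.0, 20.0, 25.0) == pytest.approx(-22.0)
    assert th.radiant_loss(1.4, 4.7, 28.0, 23.0) == pytest.approx(
        2 * th.radiant_loss(0.7, 4.7, 28.0, 23.0)
    )


class TestRespiratoryLoss:
    def test_hand_arithmetic(self):
        assert th.respiratory_loss(40.0, 1.4, 23.0) == pytest.approx(
            0.0173 * 40 * (5.867 - 1.4) + 0.0014 * 40 * (34 - 23)
        )

    def test_vanishes_at_reference_state(self):
        assert th.respiratory_loss(40.0, 5.867, 34.0) == pytest.approx(0.0)

    def test_linear_in_metabolic_rate(self):
        one = th.respiratory_loss(40.0, 1.4, 23.0)
        assert th.respiratory_loss(80.0, 1.4, 23.0) == pytest.approx(2 * one)


def test_required_evaporation_is_exact_sum():
    assert th.required_evaporation(40, 0, 0, 0, 0) == 40
    assert th.required_evaporation(75, 0, 30, 15, 7.26) == pytest.approx(22.74)
    assert th.required_evaporation(75, 0, 31, 15, 7.26) < th.required_evaporation(
        75, 0, 30, 15, 7.26
    )


class TestEvaporativeResistance:
    def test_divide_convention(self):
        assert th.evaporative_resistance(0.36, 0.55, 16.5) == pytest.approx(
            0.36 / 9.075
        )

    def test_identity_at_unit_permeability_and_lewis(self):
        assert th.evaporative_resistance(0.2, 1.0, 1.0) == pytest.approx(0.2)

    def test_doubling_lewis_halves(self):
        one = th.evaporative_resistance(0.36, 0.55, 16.5)
        assert th.evaporative_resistance(0.36, 0.55, 33.0) == pytest.approx(one / 2)

    def test_product_convention(self):
        assert th.evaporative_resistance(0.36, 0.55, 16.5, grouping="product") == (
            pytest.approx(0.36 * 0.55 / 16.5)
        )

    def test_rejects_zero_permeability(self):
        with pytest.raises(ValueError):
            th.evaporative_resistance(0.36, 0.0, 16.5)


@pytest.mark.parametrize("hc, expected", [(2.7, 44.55), (4.0, 66.0), (8.2, 135.3)])
def test_mass_transfer_coefficient(hc, expected):
    assert th.mass_transfer_coefficient(hc) == pytest.approx(expected)


class TestMaxEvaporativeCapacity:
    def test_zero_gradient(self):
        assert th.max_evaporative_capacity(3.0, 3.0, 0.02, 1.1, 66.0) == 0.0

    def test_hand_arithmetic(self):
        assert th.max_evaporative_capacity(4.2, 1.0, 0.02, 1.1, 66.0) == pytest.approx(
            3.2 / (0.02 + 1.0 / (1.1 * 66.0))
        )

    def test_linear_in_driving_pressure(self):
        one = th.max_evaporative_capacity(4.0, 3.0, 0.02, 1.1, 66.0)
        assert th.max_evaporative_capacity(5.0, 3.0, 0.02, 1.1, 66.0) == pytest.approx(
            2 * one
        )


class TestSweatRate:
    def test_intercept(self):
        assert th.sweat_rate(0.0, 0.0) == (147.0, False)

    def test_hand_arithmetic(self):
        msw, clamped = th.sweat_rate(100.0, 100.0)
        assert msw == pytest.approx(212.7)
        assert not clamped

    def test_negative_prediction_clamped_with_flag(self):
        msw, clamped = th.sweat_rate(-200.0, 200.0)
        assert msw == 0.0
        assert clamped

    @given(
        st.floats(min_value=-100, max_value=300),
        st.floats(min_value=0, max_value=300),
        st.floats(min_value=1, max_value=50),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_increasing_ereq_decreasing_emax(self, ereq, emax, delta):
        base, _ = th.sweat_rate(ereq, emax)
        up, _ = th.sweat_rate(ereq + delta, emax)
        down, _ = th.sweat_rate(ereq, emax + delta)
        assert up >= base >= down


@pytest.mark.parametrize(
    "msw, ad, hours, expected",
    [(100.0, 1.8, 8.0, 1440.0), (100.0, 1.8, 0.0, 0.0)],
)
def test_person_evaporation_mass(msw, ad, hours, expected):
    assert th.person_evaporation_mass(msw, ad, hours) == pytest.approx(expected)


def test_person_evaporation_additive_over_time_split():
    whole = th.person_evaporation_mass(87.3, 1.8, 8.0)
    halves = 2 * th.person_evaporation_mass(87.3, 1.8, 4.0)
    assert whole == pytest.approx(halves)


class TestHeatBalanceChain:
    def test_components_match_single_expression_oracles(self):
        """Every closed-form component equals a direct evaluation, machine precision."""
        env = th.Environment(ta=24.0, tr=24.0, rh=0.45)
        act = th.LIGHT_WORK
        clo = th.SEASONAL_CLOTHING["spring"]
        hb = th.heat_balance(env, act, clo)
        icl = clo.Icl * 0.155
        tsk = 0.215 * 24.0 + 26.6
        psk = svp_oracle_kpa(tsk)
        pa = 0.45 * svp_oracle_kpa(24.0)
        assert hb.Tsk == tsk
        assert hb.Psk == pytest.approx(psk, rel=1e-15)
        assert hb.Pa == pytest.approx(pa, rel=1e-15)
        assert hb.C == pytest.approx(clo.fcl * act.hc * (hb.tcl - 24.0), rel=1e-15)
        assert hb.R == pytest.approx(act.fr * 4.7 * (hb.tcl - 24.0), rel=1e-15)
        assert hb.Qres == pytest.approx(
            0.0173 * act.M * (5.867 - pa) + 0.0014 * act.M * (34 - 24.0), rel=1e-14
        )
        assert hb.Ereq == pytest.approx(
            act.M - hb.W - hb.C - hb.R - hb.Qres, rel=1e-15
        )
        assert hb.Emax == pytest.approx(
            (psk - pa) / (icl / (clo.icl * 16.5) + 1.0 / (clo.fcl * 16.5 * act.hc)),
            rel=1e-14,
        )
        assert hb.msw == pytest.approx(
            147.0 + 1.527 * hb.Ereq - 0.87 * hb.Emax, rel=1e-14
        )

    @pytest.mark.parametrize("season", th.SEASONS)
    def test_whole_chain_monotone_in_air_temperature(self, season):
        """Warming the room (tr = ta, fixed rh) never decreases evaporation."""
        clo = th.SEASONAL_CLOTHING[season]
        rates = [
            th.heat_balance(th.Environment(ta=t, rh=0.5), th.SLEEP, clo).msw
            for t in np.linspace(20.0, 34.0, 29)
        ]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_clamped_flag_preserves_raw_value(self):
        # strongly ventilated cold dry state drives the regression negative
        env = th.Environment(ta=20.0, rh=0.0)
        clo = th.ClothingEnsemble("x", fcl=1.05, Icl=0.1, icl=1.0)
        hb = th.heat_balance(env, th.SLEEP, clo)
        if hb.clamped:
            assert hb.msw == 0.0
            assert hb.msw_raw < 0.0


class TestDomainTypes:
    def test_environment_validates_rh_and_defaults_tr(self):
        env = th.Environment(ta=23.0)
        assert env.tr == 23.0
        with pytest.raises(ValueError):
            th.Environment(ta=23.0, rh=1.5)
        with pytest.raises(ValueError):
            th.Environment(ta=70.0)

    def test_activity_and_clothing_invariants(self):
        with pytest.raises(ValueError):
            th.ActivityLevel("x", M=-1, hc=2.7, fr=0.35)
        with pytest.raises(ValueError):
            th.ActivityLevel("x", M=40, hc=2.7, fr=0.35, eta=0.5)
        with pytest.raises(ValueError):
            th.ClothingEnsemble("x", fcl=0.9, Icl=0.5, icl=0.5)
        with pytest.raises(ValueError):
            th.ClothingEnsemble("x", fcl=1.1, Icl=0.5, icl=0.0)

    def test_clo_conversion(self):
        clo = th.ClothingEnsemble("x", fcl=1.1, Icl=1.0, icl=0.5)
        assert clo.icl_si == pytest.approx(0.155)
        assert clo.with_unit("si").icl_si == pytest.approx(1.0)

    def test_person_profile_bounds_and_dubois(self):
        with pytest.raises(ValueError):
            th.PersonProfile(AD=0.9)
        p = th.PersonProfile.from_mass_height(70.0, 1.75)
        assert 1.6 < p.AD < 2.1

    def test_constants_immutable_and_positive(self):
        c = th.ModelConstants()
        with pytest.raises(AttributeError):
            c.hr = 5.0
        with pytest.raises(ValueError):
            th.ModelConstants(lewis_ratio=-1.0)
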