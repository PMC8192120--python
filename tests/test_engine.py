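"""Core master-equation engine: rate scaling, generators, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import monokin as mk
from monokin.scheme import IonConditions, KineticScheme, State, Transition


class TestVoltageScaledRate:
    def test_zero_charge_is_voltage_independent(self):
        assert mk.voltage_scaled_rate(10.0, 0.0, -0.09) == pytest.approx(10.0)

    def test_zero_voltage_leaves_rate_unchanged(self):
        assert mk.voltage_scaled_rate(10.0, 1.0, 0.0) == pytest.approx(10.0)

    def test_unit_charge_at_minus_60mV(self):
        # exp(-zQ F V / 2RT) = exp(96485*0.06/(2*8.314*293)) = 3.281
        rate = mk.voltage_scaled_rate(10.0, 1.0, -0.060, direction="fwd")
        assert rate == pytest.approx(32.81, rel=1e-3)

    def test_reverse_direction_is_reciprocal(self):
        fwd = mk.voltage_scaled_rate(10.0, 0.7, -0.055, direction="fwd")
        rev = mk.voltage_scaled_rate(10.0, 0.7, -0.055, direction="rev")
        assert fwd * rev == pytest.approx(100.0, rel=1e-12)

    @given(
        zq=st.floats(-2, 2),
        v=st.floats(-0.15, 0.15),
        k0=st.floats(1e-3, 1e6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_barrier_preserves_product(self, zq, v, k0):
        fwd = mk.voltage_scaled_rate(k0, zq, v, direction="fwd")
        rev = mk.voltage_scaled_rate(k0, zq, v, direction="rev")
        assert fwd * rev == pytest.approx(k0 * k0, rel=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            mk.voltage_scaled_rate(np.nan, 1.0, 0.0)
        with pytest.raises(ValueError):
            mk.voltage_scaled_rate(1.0, np.inf, 0.0)


class TestBuildGenerator:
    def test_two_state_columns_sum_to_zero(self, two_state_scheme, empty_conditions):
        Q = mk.build_generator(two_state_scheme, empty_conditions, 0.0)
        assert Q.shape == (2, 2)
        assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-14)
        assert Q[1, 0] == pytest.approx(2.0)
        assert Q[0, 1] == pytest.approx(1.0)

    def test_ligand_coupling_pseudo_first_order(self):
        scheme = KineticScheme(
            states=[State("T"), State("TS", bound_ligands={"S": 1})],
            transitions=[
                Transition("T", "TS", 1.0e6, 1.0, 0.0, ligand_fwd=("S", "out"))
            ],
        )
        cond = IonConditions({("S", "out"): 30e-6})
        Q = mk.build_generator(scheme, cond, 0.0)
        assert Q[1, 0] == pytest.approx(30.0)

    def test_unknown_species_rejected(self):
        scheme = KineticScheme(
            states=[State("T"), State("TX", bound_ligands={"X": 1})],
            transitions=[
                Transition("T", "TX", 1.0e6, 1.0, 0.0, ligand_fwd=("X", "out"))
            ],
        )
        with pytest.raises(ValueError, match="X"):
            mk.build_generator(scheme, IonConditions({("S", "out"): 1e-6}), 0.0)

    def test_fixture_generator_conserves_probability(self, dat_model, physiological):
        for V in (-0.09, 0.0, 0.03):
            Q = mk.build_generator(dat_model.scheme, physiological, V)
            assert np.allclose(Q.sum(axis=0), 0.0, atol=1e-9)
            off_diag = Q - np.diag(np.diag(Q))
            assert off_diag.min() >= 0.0


class TestSteadyState:
    def test_two_state_detailed_balance(self, two_state_scheme, empty_conditions):
        p = mk.steady_state(two_state_scheme, empty_conditions, 0.0)
        assert p == pytest.approx([1 / 3, 2 / 3], rel=1e-10)

    def test_disconnected_scheme_raises(self, empty_conditions):
        scheme = KineticScheme(
            states=[State("A"), State("B"), State("C"), State("D")],
            transitions=[
                Transition("A", "B", 1.0, 1.0, 0.0),
                Transition("C", "D", 1.0, 1.0, 0.0),
            ],
        )
        with pytest.raises(ValueError, match="disconnected"):
            mk.steady_state(scheme, empty_conditions, 0.0)

    def test_fixture_steady_state_is_distribution(self, sert_model, physiological):
        p = mk.steady_state(sert_model.scheme, physiological, -0.06)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert p.min() >= 0.0


class TestIntegration:
    def test_two_state_matches_closed_form(self, two_state_scheme, empty_conditions):
        protocol = mk.ApplicationProtocol(V=0.0, t_end=2.0)
        t = np.linspace(0, 2, 401)
        traj = mk.integrate_occupancies(
            two_state_scheme, empty_conditions, protocol,
            p0=np.array([1.0, 0.0]), t_grid=t,
        )
        expected = 1 / 3 + (2 / 3) * np.exp(-3.0 * t)
        assert np.max(np.abs(traj.state("A") - expected)) < 1e-6

    def test_probability_conservation_through_application(self, dat_application):
        traj = dat_application[0]
        sums = traj.occupancies.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-6
        assert traj.occupancies.min() > -1e-6

    def test_long_time_limit_equals_steady_state(self, dat_model, physiological):
        conc = 30e-6
        cond = physiological.with_updates({("S", "out"): conc})
        protocol = mk.ApplicationProtocol(
            V=-0.06, segments=[(0.0, 40.0, {("S", "out"): conc})]
        )
        p0 = mk.steady_state(dat_model.scheme, physiological, -0.06)
        traj = mk.integrate_occupancies(
            dat_model.scheme, physiological, protocol, p0=p0,
            t_grid=np.linspace(0, 40, 201),
        )
        ss = mk.steady_state(dat_model.scheme, cond, -0.06)
        assert np.max(np.abs(traj.occupancies[-1] - ss)) < 1e-5

    def test_initial_occupancies_must_normalize(self, two_state_scheme, empty_conditions):
        protocol = mk.ApplicationProtocol(V=0.0, t_end=1.0)
        with pytest.raises(ValueError, match="sum to 1"):
            mk.integrate_occupancies(
                two_state_scheme, empty_conditions, protocol,
                p0=np.array([0.7, 0.7]),
            )

    def test_concentration_exchange_follows_tau(self, physiological):
        protocol = mk.ApplicationProtocol(
            V=-0.06, segments=[(0.1, 1.0, {("S", "out"): 1e-4})], t_end=1.5
        )
        t = np.linspace(0, 1.5, 1501)
        prof = mk.concentration_profile(protocol, physiological, t)[("S", "out")]
        # one time constant after onset the step has covered 1 - 1/e
        idx = np.searchsorted(t, 0.1 + 0.010)
        assert prof[idx] == pytest.approx(1e-4 * (1 - np.exp(-1)), rel=1e-2)
        assert prof[0] == 0.0
        assert prof[np.searchsorted(t, 0.9)] == pytest.approx(1e-4, rel=1e-3)


class TestProtocolValidation:
    def test_segments_must_be_ordered(self):
        with pytest.raises(ValueError):
            mk.ApplicationProtocol(
                V=0.0,
                segments=[(0.5, 1.0, {}), (0.2, 0.6, {})],
            )

    def test_tau_app_positive(self):
        with pytest.raises(ValueError):
            mk.ApplicationProtocol(V=0.0, tau_app=0.0)
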