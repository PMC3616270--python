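"""Unit and property tests for the population model's building blocks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvacpg import (
    ChainCoupling,
    ContralateralSpec,
    DriveProtocol,
    NetworkSpec,
    PopulationSpec,
    Pulse,
    SensorySpec,
    SigmoidSpec,
    REFERENCE_PARAMS,
    default_network,
    drive_value,
    one_sided_rhs,
    response_ceiling,
    sensory_drive,
    sigmoid_response,
    two_sided_rhs,
)

E_SIGMOID = SigmoidSpec(1.3, 4.0)
I_SIGMOID = SigmoidSpec(2.0, 3.7)


class TestSigmoid:
    def test_zero_input_gives_zero(self):
        assert sigmoid_response(0.0, E_SIGMOID) == pytest.approx(0.0, abs=1e-15)

    def test_value_at_threshold(self):
        # closed form: G(theta) = 1/2 - 1/(1 + e^{lambda*theta})
        expected = 0.5 - 1.0 / (1.0 + math.exp(1.3 * 4.0))
        assert sigmoid_response(4.0, E_SIGMOID) == pytest.approx(expected, abs=1e-12)
        assert round(expected, 5) == 0.49451

    @pytest.mark.parametrize(
        "spec,expected",
        [(E_SIGMOID, 0.9945), (I_SIGMOID, 0.9994), (SigmoidSpec(0.7, 0.0), 0.5)],
    )
    def test_response_ceiling(self, spec, expected):
        assert round(response_ceiling(spec), 4) == expected

    def test_ceiling_matches_saturated_sigmoid(self):
        for spec in (E_SIGMOID, I_SIGMOID, SigmoidSpec(0.5, 1.0)):
            assert response_ceiling(spec) == pytest.approx(
                sigmoid_response(1000.0, spec), abs=1e-9
            )

    def test_non_finite_input_rejected(self):
        with pytest.raises(FloatingPointError):
            sigmoid_response(float("nan"), E_SIGMOID)
        with pytest.raises(FloatingPointError):
            sigmoid_response(float("inf"), E_SIGMOID)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            SigmoidSpec(0.0, 4.0)
        with pytest.raises(ValueError):
            SigmoidSpec(-1.3, 4.0)

    @settings(deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.1, 10),
        theta=st.floats(-5, 5),
        x1=st.floats(-50, 50),
        dx=st.floats(1e-6, 50),
    )
    def test_monotone_increasing_and_zero_at_origin(self, lam, theta, x1, dx):
        spec = SigmoidSpec(lam, theta)
        lo, hi = sigmoid_response(x1, spec), sigmoid_response(x1 + dx, spec)
        assert hi >= lo
        # strictness holds away from float saturation of the exponential
        if abs(lam * (x1 - theta)) < 20 and abs(lam * (x1 + dx - theta)) < 20:
            assert hi > lo
        assert sigmoid_response(0.0, spec) == pytest.approx(0.0, abs=1e-12)
        assert lo <= response_ceiling(spec)


class TestDrive:
    def test_pulse_window(self):
        proto = DriveProtocol.single(8, 1.7, 0.0, 2.0)
        assert drive_value(proto, 1.0, 8) == 1.7
        assert drive_value(proto, 2.5, 8) == 0.0
        assert drive_value(proto, 2.0, 8) == 0.0  # half-open window
        assert drive_value(proto, 1.0, 7) == 0.0

    def test_overlapping_pulses_superpose(self):
        proto = DriveProtocol(
            (Pulse(8, 1.0, 0.0, 2.0), Pulse(8, 0.5, 1.0, 2.0))
        )
        assert drive_value(proto, 1.5, 8) == pytest.approx(1.5)
        assert drive_value(proto, 0.5, 8) == pytest.approx(1.0)
        assert drive_value(proto, 2.5, 8) == pytest.approx(0.5)

    def test_side_matching(self):
        proto = DriveProtocol((Pulse(8, 1.7, 0.0, 2.0, side="left"),))
        assert drive_value(proto, 1.0, 8, "left") == 1.7
        assert drive_value(proto, 1.0, 8, "right") == 0.0

    def test_invalid_pulse_rejected(self):
        with pytest.raises(ValueError):
            Pulse(0, 1.7)
        with pytest.raises(ValueError):
            Pulse(8, -1.0)
        with pytest.raises(ValueError):
            Pulse(8, 1.7, duration=0.0)


class TestOneSidedRHS:
    def test_rest_is_equilibrium(self, reference_spec):
        state = np.zeros(16)
        deriv = one_sided_rhs(state, reference_spec, DriveProtocol(), 0.0)
        np.testing.assert_allclose(deriv, 0.0, atol=1e-15)

    def test_rest_with_drive_excites_only_driven_segment(self, reference_spec):
        proto = DriveProtocol.single(8, 1.7, 0.0, 2.0)
        deriv = one_sided_rhs(np.zeros(16), reference_spec, proto, 1.0)
        kE = reference_spec.excitatory.ceiling
        g = 1 / (1 + math.exp(-1.3 * (1.7 - 4.0))) - 1 / (1 + math.exp(1.3 * 4.0))
        expected = kE * g / 0.5
        assert deriv[7] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.084, abs=5e-4)
        np.testing.assert_allclose(np.delete(deriv, 7), 0.0, atol=1e-15)

    def test_ceiling_state_decays(self, reference_spec):
        state = np.zeros(16)
        kE = reference_spec.excitatory.ceiling
        state[3] = kE
        deriv = one_sided_rhs(state, reference_spec, DriveProtocol(), 0.0)
        assert deriv[3] == pytest.approx(-kE / 0.5, rel=1e-12)

    def test_dimension_mismatch(self, reference_spec):
        with pytest.raises(ValueError, match="shape"):
            one_sided_rhs(np.zeros(17), reference_spec, DriveProtocol(), 0.0)

    def test_zero_sensory_gains_match_plain_model(self, reference_spec):
        sens_spec = default_network(sensory=SensorySpec(0.0, 0.0, 0.0))
        rng = np.random.default_rng(7)
        state = rng.uniform(0, 0.5, 16)
        full = np.concatenate([state, rng.uniform(0, 0.5, 8)])
        proto = DriveProtocol.single(8, 1.7, 0.0, 2.0)
        d_plain = one_sided_rhs(state, reference_spec, proto, 1.0)
        d_sens = one_sided_rhs(full, sens_spec, proto, 1.0)
        np.testing.assert_array_equal(d_sens[:16], d_plain)


class TestSensoryDrive:
    SENS = SensorySpec(25.0, 20.0, 0.0)

    def test_uniform_activity_gives_no_stretch(self):
        assert np.all(sensory_drive(np.full(8, 0.37), self.SENS) == 0.0)

    def test_posterior_activity_stretches_anterior_neighbour(self):
        E = np.zeros(8)
        E[7] = 0.4  # A8 active
        s = sensory_drive(E, self.SENS)
        assert s[6] == pytest.approx(25 * 0.4)  # A7 feels the stretch
        assert s[7] == 0.0  # rectified: A8's neighbour is weaker
        np.testing.assert_allclose(s[:6], 0.0)

    def test_rectification_of_negative_difference(self):
        E = np.zeros(8)
        E[6], E[7] = 0.2, 0.5
        s = sensory_drive(E, self.SENS)
        assert s[7] == 0.0  # [E7 - E8]_+ = 0
        assert s[6] == pytest.approx(25 * 0.3)

    def test_interior_segment_sums_both_neighbours(self):
        E = np.zeros(8)
        E[2], E[4] = 0.2, 0.3
        s = sensory_drive(E, self.SENS)
        assert s[3] == pytest.approx(25 * 0.2 + 25 * 0.3)


class TestTwoSidedRHS:
    PROTO = DriveProtocol(
        (Pulse(8, 1.7, 0.0, 2.0, "left"), Pulse(8, 1.7, 0.0, 2.0, "right"))
    )

    def _random_state(self, rng, size=32):
        return rng.uniform(0, 0.5, size)

    def test_zero_weight_matches_one_sided_per_side(self, reference_spec, rng):
        spec = default_network(contralateral=ContralateralSpec("EE", 0.0))
        state = self._random_state(rng)
        d = two_sided_rhs(state, spec, self.PROTO, 1.0)
        one_proto = DriveProtocol.single(8, 1.7, 0.0, 2.0)
        np.testing.assert_array_equal(
            d[:16], one_sided_rhs(state[:16], reference_spec, one_proto, 1.0)
        )
        np.testing.assert_array_equal(
            d[16:], one_sided_rhs(state[16:], reference_spec, one_proto, 1.0)
        )

    @pytest.mark.parametrize("kind", ["EE", "IE", "EI", "II"])
    def test_left_right_exchange_symmetry(self, kind, rng):
        spec = default_network(contralateral=ContralateralSpec(kind, -3.5))
        state = self._random_state(rng)
        swapped = np.concatenate([state[16:], state[:16]])
        d = two_sided_rhs(state, spec, self.PROTO, 0.7)
        d_swapped = two_sided_rhs(swapped, spec, self.PROTO, 0.7)
        np.testing.assert_array_equal(d_swapped, np.concatenate([d[16:], d[:16]]))

    @pytest.mark.parametrize("kind,target", [("EE", "E"), ("IE", "E"), ("EI", "I"), ("II", "I")])
    def test_coupling_kind_targets_correct_population(self, kind, target, rng):
        spec0 = default_network(contralateral=ContralateralSpec(kind, 0.0))
        spec1 = default_network(contralateral=ContralateralSpec(kind, 4.0))
        state = self._random_state(rng)
        d0 = two_sided_rhs(state, spec0, self.PROTO, 0.5)
        d1 = two_sided_rhs(state, spec1, self.PROTO, 0.5)
        delta = d1 - d0
        e_rows = np.r_[0:8, 16:24]
        i_rows = np.r_[8:16, 24:32]
        changed, unchanged = (e_rows, i_rows) if target == "E" else (i_rows, e_rows)
        assert np.any(delta[changed] != 0)
        np.testing.assert_array_equal(delta[unchanged], 0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            ContralateralSpec("XX", 1.0)


class TestSpecs:
    def test_default_network_matches_reference_table(self, reference_spec):
        s = reference_spec
        assert s.n_segments == 8
        assert s.segment.self_excitation == REFERENCE_PARAMS["a"]
        assert s.segment.i_to_e == REFERENCE_PARAMS["c"]
        assert s.segment.e_to_i == REFERENCE_PARAMS["e"]
        assert s.segment.i_to_i == REFERENCE_PARAMS["f"]
        assert set(s.chain.e_edge_weights) == {REFERENCE_PARAMS["b"]}
        assert set(s.chain.i_edge_weights) == {REFERENCE_PARAMS["d"]}
        assert s.excitatory.time_constant == REFERENCE_PARAMS["tau_E"]
        assert s.excitatory.sigmoid == SigmoidSpec(REFERENCE_PARAMS["b_E"], REFERENCE_PARAMS["theta_E"])
        assert s.inhibitory.sigmoid == SigmoidSpec(REFERENCE_PARAMS["b_I"], REFERENCE_PARAMS["theta_I"])
        assert round(s.excitatory.ceiling, 4) == 0.9945
        assert round(s.inhibitory.ceiling, 4) == 0.9994

    def test_chain_length_validation(self):
        with pytest.raises(ValueError, match="edges"):
            NetworkSpec(
                n_segments=8,
                excitatory=PopulationSpec.with_derived_ceiling(0.5, E_SIGMOID),
                inhibitory=PopulationSpec.with_derived_ceiling(0.5, I_SIGMOID),
                segment=default_network().segment,
                chain=ChainCoupling.uniform(20, -20, n_segments=5),
            )

    def test_uniform_chain_construction(self):
        chain = ChainCoupling.uniform(20.0, -20.0)
        assert chain.e_edge_weights == (20.0,) * 7
        assert chain.i_edge_weights == (-20.0,) * 7

    def test_negative_stretch_gain_rejected(self):
        with pytest.raises(ValueError):
            SensorySpec(-1.0, 0.0, 0.0)
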