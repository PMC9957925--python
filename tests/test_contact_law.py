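"""Unit and property tests of the point-wise interface law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osseodebond.contact_law import (
    AdhesiveFrictionParams,
    BondPointState,
    ContactLaw,
    ContactPointKinematics,
    PointStatus,
    calibrate_t0,
    friction_coefficient,
    normal_traction,
    sliding_limit,
    slip_update,
    smooth_penalty,
    state_function,
    update_damage,
)

A_S, B_S = 22e-6, 0.74


class TestStateFunction:
    @pytest.mark.parametrize("g_d,phi0,expected", [
        (0.0, 1.0, 1.0),                       # intact below the threshold
        (2 * A_S * (1 + 2 * B_S), 0.7, 0.0),   # fully broken beyond cutoff
        (A_S * (1 + B_S), 1.0, 0.5),           # transition midpoint
        (0.999 * A_S, 0.3, 0.3),
    ])
    def test_branch_values(self, g_d, phi0, expected):
        assert state_function(g_d, phi0, A_S, B_S) == pytest.approx(expected, abs=1e-12)

    def test_continuous_and_monotone_on_dense_sweep(self):
        g = np.linspace(0.0, 2 * A_S * (1 + 2 * B_S), 200001)
        phi = state_function(g, 1.0, A_S, B_S)
        assert np.all(np.diff(phi) <= 1e-15)
        # jumps across branch joints vanish with the grid spacing
        assert np.max(np.abs(np.diff(phi))) < 1e-4
        for joint in (A_S, A_S * (1 + 2 * B_S)):
            lo = state_function(joint * (1 - 1e-9), 1.0, A_S, B_S)
            hi = state_function(joint * (1 + 1e-9), 1.0, A_S, B_S)
            assert abs(hi - lo) < 1e-7

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            state_function(-1e-9, 1.0, A_S, B_S)
        with pytest.raises(ValueError):
            state_function(0.0, 1.5, A_S, B_S)
        with pytest.raises(ValueError):
            state_function(0.0, 1.0, -A_S, B_S)


class TestFriction:
    @pytest.mark.parametrize("phi,expected", [(1.0, 0.44), (0.0, 0.3), (0.5, 0.37)])
    def test_endpoints_and_blend(self, phi, expected):
        assert friction_coefficient(phi, 0.44, 0.3) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            friction_coefficient(1.2, 0.44, 0.3)


class TestNormalTraction:
    def test_czm_peak_at_g0(self, emc_params):
        t = normal_traction(emc_params.g0 * (1 - 1e-12), 1.0, emc_params, phi0=1.0)
        assert t == pytest.approx(1.8e6, rel=1e-9)

    def test_cutoff_and_broken(self, emc_params):
        assert normal_traction(emc_params.g_b, 1.0, emc_params) == 0.0
        assert normal_traction(0.5 * emc_params.g0, 0.0, emc_params) == 0.0

    def test_penalty_compression(self, emc_params):
        assert normal_traction(-1e-6, 1.0, emc_params) == pytest.approx(-1.8e6)

    def test_mc_has_no_tension(self, mc_params):
        assert normal_traction(mc_params.g0, 1.0, mc_params) == 0.0

    def test_zero_at_zero_gap_and_amplitude_scales_with_phi0(self, emc_params):
        assert normal_traction(0.0, 1.0, emc_params) == 0.0
        full = normal_traction(emc_params.g0, 0.7, emc_params, phi0=1.0)
        half = normal_traction(emc_params.g0, 0.7, emc_params, phi0=0.5)
        assert half == pytest.approx(0.5 * full)


class TestSlidingLimit:
    def test_emc_adhesion_fully_mobilized(self, emc_params):
        assert sliding_limit(1.8e6, 1.0, emc_params, phi0=1.0) == 0.0

    def test_emc_zero_normal_traction(self, emc_params):
        got = sliding_limit(0.0, 0.0, emc_params, phi0=1.0)
        assert got == pytest.approx(0.3 * 1.8e6)  # 0.54 MPa

    def test_mc_classical_coulomb(self, mc_params):
        assert sliding_limit(-1e6, 0.0, mc_params) == pytest.approx(0.3e6)

    def test_clamped_at_zero(self, emc_params):
        assert sliding_limit(5e6, 1.0, emc_params, phi0=1.0) == 0.0


class TestSlipUpdate:
    def test_stick_below_limit(self):
        t, status = slip_update(np.array([0.2e6, 0.0, 0.0]), 0.54e6)
        assert status is PointStatus.STICK
        np.testing.assert_allclose(t, [0.2e6, 0.0, 0.0])

    def test_radial_return_preserves_direction(self):
        trial = np.array([0.8e6, 0.6e6, 0.0])
        t, status = slip_update(trial, 0.54e6)
        assert status is PointStatus.SLIP
        assert np.linalg.norm(t) == pytest.approx(0.54e6)
        np.testing.assert_allclose(t / np.linalg.norm(t), trial / np.linalg.norm(trial))

    def test_zero_limit_free_sliding(self):
        t, status = slip_update(np.array([1.0, 0.0, 0.0]), 0.0)
        assert status is PointStatus.SLIP
        np.testing.assert_allclose(t, 0.0)

    @given(tx=st.floats(-1e7, 1e7), ty=st.floats(-1e7, 1e7),
           lim=st.floats(0.0, 1e7))
    @settings(max_examples=200, deadline=None)
    def test_slip_criterion_never_violated(self, tx, ty, lim):
        t, _ = slip_update(np.array([tx, ty, 0.0]), lim)
        assert np.linalg.norm(t) <= lim * (1 + 1e-12) + 1e-300


class TestSmoothPenalty:
    def test_value(self):
        assert smooth_penalty(1.0, 1.8e6, 66e-6) == pytest.approx(7.4135e10, rel=1e-4)

    def test_degenerate(self):
        assert smooth_penalty(0.0, 1.8e6, 66e-6) == 0.0

    def test_slope_continuity_at_zero_gap(self, table_params):
        par = dict(table_params)
        par["eps_n"] = smooth_penalty(1.0, par["t0"], par["g0"])
        p = AdhesiveFrictionParams(law=ContactLaw.EMC, **par)
        h = 1e-12
        left = (normal_traction(0.0, 1.0, p) - normal_traction(-h, 1.0, p)) / h
        right = (normal_traction(h, 1.0, p) - normal_traction(0.0, 1.0, p)) / h
        assert right == pytest.approx(left, rel=1e-4)


class TestCalibration:
    def test_pullout_data(self):
        assert calibrate_t0(9.0, 0.26, 2.5e-3) == pytest.approx(1.76e6, rel=0.01)
        assert calibrate_t0(35.0, 1.0, 2.5e-3) == pytest.approx(1.78e6, rel=0.01)

    def test_zero_force(self):
        assert calibrate_t0(0.0, 0.5, 2.5e-3) == 0.0

    def test_uncalibratable(self):
        with pytest.raises(ValueError):
            calibrate_t0(9.0, 0.0, 2.5e-3)


class TestDegenerations:
    """EMC -> MC for t0 = 0; MC -> classical Coulomb for phi0 = 0."""

    def test_emc_with_zero_t0_equals_mc(self, table_params, rng):
        par = {**table_params, "t0": 0.0}
        emc = AdhesiveFrictionParams(law=ContactLaw.EMC, **par)
        mc = AdhesiveFrictionParams(law=ContactLaw.MC, **par)
        g_n = rng.uniform(-1e-5, 1e-4, 2000)
        phi = rng.uniform(0.0, 1.0, 2000)
        np.testing.assert_array_equal(
            normal_traction(g_n, phi, emc), normal_traction(g_n, phi, mc))
        t_n = np.minimum(normal_traction(g_n, phi, emc), 0.0)
        np.testing.assert_allclose(
            sliding_limit(t_n, phi, emc), sliding_limit(t_n, phi, mc), atol=1e-12)

    def test_mc_with_zero_phi0_is_coulomb(self, table_params, rng):
        mc = AdhesiveFrictionParams(law=ContactLaw.MC, **table_params)
        cb = AdhesiveFrictionParams(law=ContactLaw.COULOMB, **table_params)
        p = rng.uniform(0.0, 5e6, 2000)
        # fully debonded state: phi = 0
        np.testing.assert_allclose(
            sliding_limit(-p, 0.0, mc), sliding_limit(-p, 0.0, cb), rtol=1e-15)


def _kin(x_k, x_l, n=(0.0, 0.0, 1.0)):
    return ContactPointKinematics(np.asarray(x_k, float), np.asarray(x_l, float),
                                  np.asarray(n, float))


class TestDamageAccumulation:
    def test_zero_motion_leaves_state_unchanged(self, emc_params):
        s = BondPointState(phi0=1.0, phi=1.0)
        k = _kin([0, 0, 1e-6], [0, 0, 0])
        s1 = update_damage(s, k, k, emc_params)
        assert s1.g_s == 0.0 and s1.g_sn == 0.0 and s1.phi == 1.0

    def test_pure_tangential_slide(self, emc_params):
        s = BondPointState(phi0=1.0, phi=1.0)
        prev = _kin([0, 0, -1e-6], [0, 0, 0])
        now = _kin([10e-6, 0, -1e-6], [10e-6, 0, 0])
        s1 = update_damage(s, now, prev, emc_params)
        assert s1.g_s == pytest.approx(10e-6)
        assert s1.g_sn == pytest.approx(0.0, abs=1e-18)

    def test_reversed_slip_path_keeps_accumulating(self, emc_params):
        s = BondPointState(phi0=1.0, phi=1.0)
        a = _kin([0, 0, 0], [0, 0, 0])
        b = _kin([10e-6, 0, 0], [10e-6, 0, 0])
        s1 = update_damage(s, b, a, emc_params)
        s1.g_en_prev = b.g_en
        s2 = update_damage(s1, a, b, emc_params)
        assert s2.g_s == pytest.approx(20e-6)

    def test_oscillating_normal_gap(self, emc_params):
        g0 = emc_params.g0
        s = BondPointState(phi0=1.0, phi=1.0)
        closed = _kin([0, 0, 0], [0, 0, 0])
        opened = _kin([0, 0, g0], [0, 0, 0])
        s1 = update_damage(s, opened, closed, emc_params)
        s2 = update_damage(s1, closed, opened, emc_params)
        assert s2.g_sn == pytest.approx(2 * g0)

    @given(steps=st.lists(st.tuples(st.floats(-2e-5, 2e-5), st.floats(-2e-5, 2e-5)),
                          min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_damage_monotone_under_arbitrary_paths(self, emc_params, steps):
        s = BondPointState(phi0=1.0, phi=1.0)
        prev = _kin([0, 0, 0], [0, 0, 0])
        g_d_hist = [0.0]
        phi_hist = [1.0]
        x, z = 0.0, 0.0
        for dx, dz in steps:
            x += dx
            z += dz
            now = _kin([x, 0, max(z, 0.0)], [x, 0, 0])
            s = update_damage(s, now, prev, emc_params)
            g_d_hist.append(s.g_d)
            phi_hist.append(s.phi)
            prev = now
        assert np.all(np.diff(g_d_hist) >= -1e-18)
        assert np.all(np.diff(phi_hist) <= 1e-15)

    def test_mc_damage_ignores_normal_gap(self, mc_params):
        s = BondPointState(phi0=1.0, phi=1.0)
        closed = _kin([0, 0, 0], [0, 0, 0])
        opened = _kin([0, 0, 1e-4], [0, 0, 0])
        s1 = update_damage(s, opened, closed, mc_params)
        assert s1.g_sn == pytest.approx(1e-4)   # accumulated ...
        assert s1.phi == 1.0                    # ... but not damaging under MC
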