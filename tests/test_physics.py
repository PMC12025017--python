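"""Forward-model unit and property tests.

Expected values are computed inline by direct arithmetic on the defining
formulas (independent of the implementation's code paths) or by grid-search
oracles over finely sampled frequency axes.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import magvisc as mv
from magvisc.physics import _response_prefactor


def test_strain_amplitude_matches_direct_arithmetic(sensor, coil):
    d_lambda = 3 * sensor.lambda_s * sensor.M_DC / sensor.M_s**2
    expected = d_lambda * sensor.chi_AC * coil.N * coil.I_AC / (coil.km * coil.lc)
    eps0, f0 = mv.strain_amplitude(sensor, coil)
    assert eps0 == pytest.approx(expected, rel=1e-12)
    assert f0 == pytest.approx(sensor.E * sensor.ws * sensor.hs * expected, rel=1e-12)


def test_strain_is_linear_in_drive(sensor, coil):
    base = mv.strain_amplitude(sensor, coil).eps0
    doubled_n = mv.default_coil(N=2 * coil.N)
    assert mv.strain_amplitude(sensor, doubled_n).eps0 == pytest.approx(2 * base)
    doubled_i = mv.default_coil(I_AC=2 * coil.I_AC)
    assert mv.strain_amplitude(sensor, doubled_i).eps0 == pytest.approx(2 * base)


def test_shear_stress_direct_arithmetic():
    liq = mv.Liquid(eta_L=1.0e-3, rho_L=998.0)
    omega = 2 * math.pi * 1.2e5
    expected = math.sqrt(omega * 1.0e-3 * 998.0 / 2.0)
    assert mv.shear_stress_amplitude(liq, omega, 1.0) == pytest.approx(expected, rel=1e-12)
    # sqrt(omega) scaling: quadrupling omega doubles the stress
    assert mv.shear_stress_amplitude(liq, 4 * omega, 1.0) == pytest.approx(
        2 * expected, rel=1e-12
    )
    assert mv.shear_stress_amplitude(mv.Liquid(0.0, 998.0), omega, 1.0) == 0.0


def test_damping_coefficient_direct_arithmetic():
    """beta_L = (D0 + ws*sqrt(2*omega*eta*rho)) / (2*As*rho_s), evaluated by hand."""
    s = mv.default_sensor(D0=0.0)
    liq = mv.Liquid(eta_L=1.0e-3, rho_L=1000.0)
    omega = 2 * math.pi * 1.2e5
    expected = 0.003 * math.sqrt(2 * omega * 1.0e-3 * 1000.0) / (2 * 0.003 * 29e-6 * 7900.0)
    assert expected == pytest.approx(2680.0, rel=1e-4)  # hand-checked magnitude
    assert mv.damping_coefficient(s, liq, omega) == pytest.approx(expected, rel=1e-12)


def test_damping_vacuum_limit(sensor):
    omega = 2 * math.pi * 1.2e5
    vacuum = mv.Liquid(eta_L=0.0, rho_L=1000.0)
    expected = sensor.D0 / (2 * sensor.A_s * sensor.rho_s)
    assert mv.damping_coefficient(sensor, vacuum, omega) == pytest.approx(expected)


@given(
    vdv=st.floats(min_value=0.0, max_value=10.0),
    omega_khz=st.floats(min_value=50.0, max_value=300.0),
)
@settings(max_examples=50, derandomize=True)
def test_damping_linear_in_vdv_and_increasing_in_omega(vdv, omega_khz):
    s = mv.default_sensor()
    omega = 2 * math.pi * omega_khz * 1e3
    liq = mv.Liquid.from_vdv(vdv)
    beta = mv.damping_coefficient(s, liq, omega)
    floor = s.D0 / (2 * s.A_s * s.rho_s)
    assert beta >= floor
    # linear in vdv at fixed omega
    beta2 = mv.damping_coefficient(s, mv.Liquid.from_vdv(2 * vdv), omega)
    assert beta2 - floor == pytest.approx(2 * (beta - floor), rel=1e-9, abs=1e-12)


def test_natural_frequency_scalings(sensor):
    om0, f0 = mv.natural_frequency(sensor)
    assert om0 == pytest.approx(2 * math.pi * f0)
    quad_e = mv.default_sensor(E=4 * sensor.E)
    assert mv.natural_frequency(quad_e).omega0 == pytest.approx(2 * om0, rel=1e-12)
    half_l = mv.default_sensor(ls=sensor.ls / 2)
    assert mv.natural_frequency(half_l).omega0 == pytest.approx(2 * om0, rel=1e-12)


def test_default_modulus_reproduces_observed_water_resonance(sensor):
    """E_eff is calibrated so the unloaded half-wave mode sits at 120898.3 Hz."""
    assert mv.natural_frequency(sensor).f0 == pytest.approx(120898.3, abs=1e-6)


def test_displacement_zero_drive_is_zero(sensor, water_liquid):
    coil = mv.default_coil(I_AC=1e-30)  # effectively zero drive
    state = mv.displacement_solution(sensor, coil, water_liquid, 2 * math.pi * 1.2e5)
    assert state.u0 == pytest.approx(0.0, abs=1e-20)
    assert np.all(state.u_amp(np.linspace(0, sensor.ls, 5)) <= 1e-20)


def test_displacement_resonance_dominance(sensor, coil, water_liquid):
    om0 = mv.natural_frequency(sensor).omega0
    at_res = mv.displacement_solution(sensor, coil, water_liquid, om0).u0
    off_res = mv.displacement_solution(sensor, coil, water_liquid, 1.2 * om0).u0
    assert at_res > off_res


def test_displacement_grid_peak_matches_analytic_condition(sensor, coil, water_liquid):
    """On a 1 Hz grid with damping frozen at omega0, the displacement maximum
    sits at sqrt(omega0^2 - 2 beta_L^2) -- the amplitude-resonance condition."""
    om0 = mv.natural_frequency(sensor).omega0
    beta = mv.damping_coefficient(sensor, water_liquid, om0)
    f_analytic = math.sqrt(om0**2 - 2 * beta**2) / (2 * math.pi)
    freqs = np.arange(f_analytic - 500, f_analytic + 500, 1.0)
    amps = [
        mv.displacement_solution(
            sensor, coil, water_liquid, 2 * math.pi * f, beta_at="natural"
        ).u0
        for f in freqs
    ]
    f_grid = freqs[int(np.argmax(amps))]
    assert abs(f_grid - f_analytic) <= 1.0


def test_response_zero_coupling_is_zero(coil, water_liquid):
    s = mv.default_sensor(chi_AC=0.0)
    grid = 2 * math.pi * np.linspace(110e3, 135e3, 20)
    assert np.all(mv.response_amplitude(s, coil, water_liquid, grid) == 0.0)


def test_response_grid_peak_is_velocity_resonance(sensor, coil, water_liquid):
    """The response is an induced EMF (proportional to omega times the
    displacement), so with frequency-frozen damping its maximum lies at
    omega0 exactly, not at the displacement-resonance frequency."""
    f0 = mv.natural_frequency(sensor).f0
    freqs = np.arange(f0 - 500, f0 + 500, 1.0)
    amps = mv.response_amplitude(
        sensor, coil, water_liquid, 2 * math.pi * freqs, beta_at="natural"
    )
    assert abs(freqs[int(np.argmax(amps))] - f0) <= 1.0


def test_resonance_value_matches_grid_peak_value(sensor, coil, water_liquid):
    """The closed-form U_R agrees with the swept peak value to O((beta/omega0)^2),
    even though the peak locations differ by tens of Hz."""
    f0 = mv.natural_frequency(sensor).f0
    freqs = np.arange(f0 - 2000, f0 + 2000, 1.0)
    amps = mv.response_amplitude(sensor, coil, water_liquid, 2 * math.pi * freqs)
    u_r = mv.resonance_point(sensor, coil, water_liquid).U_R
    assert np.max(amps) == pytest.approx(u_r, rel=1e-3)


def test_peak_amplitude_monotone_in_damping(sensor, coil):
    """More viscous damping, lower resonance peak (and non-increasing f_R)."""
    prev_u, prev_f = math.inf, math.inf
    for vdv in [0.5, 1.0, 2.0, 4.0, 8.0]:
        f_r, u_r = mv.resonance_point(sensor, coil, mv.Liquid.from_vdv(vdv))
        assert u_r < prev_u
        assert f_r <= prev_f
        prev_u, prev_f = u_r, f_r


def test_resonance_low_damping_limit_approaches_f0(coil, water_liquid):
    s = mv.default_sensor(D0=1e-6)
    vac = mv.Liquid(eta_L=0.0, rho_L=1000.0)
    f_r, _ = mv.resonance_point(s, coil, vac)
    assert f_r == pytest.approx(mv.natural_frequency(s).f0, rel=1e-9)


def test_resonance_zero_damping_raises(coil):
    s = mv.default_sensor(D0=0.0)
    vac = mv.Liquid(eta_L=0.0, rho_L=1000.0)
    with pytest.raises(mv.ZeroDampingError):
        mv.resonance_point(s, coil, vac)


def test_resonance_overdamped_raises(coil, water_liquid):
    s = mv.default_sensor(D0=2000.0)  # beta_L ~ 1.5e6 > omega0/sqrt(2)
    with pytest.raises(mv.OverdampedError):
        mv.resonance_point(s, coil, water_liquid)


def test_reciprocal_linearity_of_closed_form(sensor, coil):
    """1/U_R over a sqrt(eta*rho) grid fits a line with R^2 >= 0.9999."""
    from scipy import stats

    vdv = np.linspace(0.0, 10.0, 7)
    y = [1 / mv.resonance_point(sensor, coil, mv.Liquid.from_vdv(v)).U_R for v in vdv]
    res = stats.linregress(vdv, y)
    assert res.rvalue**2 >= 0.9999


def test_linear_coefficients_intercept_carries_only_intrinsic_damping(coil):
    s = mv.default_sensor(D0=0.0)
    a, b = mv.reciprocal_linear_coefficients(s, coil)
    assert b == 0.0
    assert a > 0.0


def test_linear_coefficients_scale_inversely_with_drive(sensor, coil):
    a1, b1 = mv.reciprocal_linear_coefficients(sensor, coil)
    doubled = mv.default_coil(I_AC=2 * coil.I_AC)
    a2, b2 = mv.reciprocal_linear_coefficients(sensor, doubled)
    assert a2 == pytest.approx(a1 / 2, rel=1e-12)
    assert b2 == pytest.approx(b1 / 2, rel=1e-12)


def test_linear_coefficients_agree_with_two_point_solve(sensor, coil):
    """(a, b) must match a two-point solve of 1/U_R at vdv in {0, 1}.

    Exact to machine precision against the simplified resonance voltage, and
    within 0.1% against the full closed form (whose beta^2 corrections are
    second order).
    """
    a, b = mv.reciprocal_linear_coefficients(sensor, coil)
    for simplified, tol in [(True, 1e-12), (False, 1e-3)]:
        y0 = 1 / mv.resonance_point(
            sensor, coil, mv.Liquid(0.0, 1000.0), simplified=simplified
        ).U_R
        y1 = 1 / mv.resonance_point(
            sensor, coil, mv.Liquid.from_vdv(1.0), simplified=simplified
        ).U_R
        assert y1 - y0 == pytest.approx(a, rel=tol)
        assert y0 == pytest.approx(b, rel=tol)


def test_response_prefactor_internal_consistency(sensor, coil, water_liquid):
    """U_id at omega0 equals prefactor*omega0/(2*beta*omega0) = prefactor/(2*beta)."""
    om0 = mv.natural_frequency(sensor).omega0
    beta = mv.damping_coefficient(sensor, water_liquid, om0)
    u = mv.response_amplitude(sensor, coil, water_liquid, om0, beta_at="natural")
    assert u == pytest.approx(_response_prefactor(sensor, coil) / (2 * beta), rel=1e-12)


def test_frequency_shift_reference_direct_arithmetic(sensor):
    liq = mv.Liquid(eta_L=1.01e-3, rho_L=998.23)
    f0 = 120898.3
    expected = -(
        math.sqrt(math.pi * f0) / (2 * math.pi * sensor.rho_s * sensor.hs)
    ) * math.sqrt(1.01e-3 * 998.23)
    got = mv.frequency_shift_reference(sensor, liq, f0)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got < 0
    # scales with sqrt(eta*rho)
    quad = mv.Liquid(eta_L=4 * 1.01e-3, rho_L=998.23)
    assert mv.frequency_shift_reference(sensor, quad, f0) == pytest.approx(
        2 * got, rel=1e-12
    )
    vac = mv.Liquid(eta_L=0.0, rho_L=998.23)
    assert mv.frequency_shift_reference(sensor, vac, f0) == 0.0


def test_invalid_parameters_raise():
    with pytest.raises(mv.InvalidParameterError):
        mv.default_sensor(ls=-1.0)
    with pytest.raises(mv.InvalidParameterError):
        mv.default_sensor(M_DC=1e9)  # exceeds M_s
    with pytest.raises(mv.InvalidParameterError):
        mv.default_coil(lc=0.0)
    with pytest.raises(mv.InvalidParameterError):
        mv.Liquid(eta_L=-1e-3, rho_L=1000.0)
    with pytest.raises(mv.InvalidParameterError):
        mv.shear_stress_amplitude(mv.Liquid(1e-3, 1000.0), -5.0, 1.0)


def test_sensor_derived_fields(sensor):
    assert sensor.A_s == pytest.approx(sensor.ws * sensor.hs)
    assert sensor.d_lambda == pytest.approx(
        3 * sensor.lambda_s * sensor.M_DC / sensor.M_s**2
    )


def test_liquid_vdv_roundtrip():
    liq = mv.Liquid.from_vdv(2.5, rho_L=1050.0)
    assert liq.vdv == pytest.approx(2.5, rel=1e-12)
    assert liq.eta_L * liq.rho_L == pytest.approx(2.5**2, rel=1e-12)
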