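"""Forward model of a magnetostrictive ribbon resonator in a viscous liquid.

The sensing element is a thin amorphous ferromagnetic ribbon lying free inside
a solenoid. An AC drive current magnetizes the ribbon, magnetostriction turns
the small magnetization swing into a longitudinal strain, and the ribbon rings
as a damped driven bar. The surrounding liquid loads the ribbon through the
oscillating-plate (Stokes' second problem) shear stress, which scales with
sqrt(omega * eta_L * rho_L); the inverse magnetostrictive (Villari) effect
converts the vibration back into a magnetization swing that induces the
response voltage in the same coil.

The chain implemented here:

    drive current -> strain amplitude eps0 and equivalent tip force F0
    liquid        -> per-length damping, lumped with intrinsic damping into beta_L
    bar dynamics  -> steady-state displacement profile u(x, t)
    Villari + coil-> response amplitude U_id(omega), its resonance point
                     (f_R, U_R) and the linear law 1/U_R = a*sqrt(eta*rho) + b

All computation is in SI units (m, s, rad/s, V, Pa); Hz appears only in
convenience fields and at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "MU0",
    "DEFAULTS",
    "SensorElement",
    "CoilDrive",
    "Liquid",
    "VibrationState",
    "SweepCurve",
    "InvalidParameterError",
    "OverdampedError",
    "ZeroDampingError",
    "default_sensor",
    "default_coil",
    "water",
    "StrainResult",
    "NaturalFrequency",
    "ResonancePoint",
    "LinearCoefficients",
    "strain_amplitude",
    "shear_stress_amplitude",
    "damping_coefficient",
    "natural_frequency",
    "displacement_solution",
    "response_amplitude",
    "resonance_point",
    "reciprocal_linear_coefficients",
    "frequency_shift_reference",
]

#: Vacuum permeability (H/m).
MU0 = 4e-7 * math.pi


class InvalidParameterError(ValueError):
    """A physical parameter is outside the model's validity range."""


class OverdampedError(InvalidParameterError):
    """Damping too large for an underdamped resonance (2*beta_L**2 >= omega0**2)."""


class ZeroDampingError(InvalidParameterError):
    """Zero total damping: the resonance amplitude diverges."""


# ---------------------------------------------------------------------------
# Default configuration
#
# Geometry and drive settings follow the reference instrument (18 x 3 mm x
# 29 um Fe-based amorphous ribbon, 500-turn 40 mm coil of 12 mm bore,
# 0.05 mA AC drive on a 3 mA bias, 110-135 kHz sweep in 50 Hz steps).
# Material constants are not direct measurements: E_eff is calibrated so the
# unloaded half-wave resonance lands on the observed 120898.3 Hz water-adjacent
# peak; lambda_s, M_s, M_DC, chi_AC are Metglas-2826MB-class orders of
# magnitude; D0 and chi_AC together place the simulated air/water resonance
# amplitudes on the mV scale of the glycerol calibration series. Every value
# is overridable through the structured config file (see magvisc.io).
# ---------------------------------------------------------------------------

DEFAULTS: dict[str, dict[str, float]] = {
    "sensor": {
        "ls_m": 0.018,
        "ws_m": 0.003,
        "hs_m": 29e-6,
        "rho_s_kg_m3": 7900.0,
        "E_pa": 7900.0 * (2 * 0.018 * 120898.3) ** 2,  # ~1.4965e11
        "D0_kg_m_s": 15.5,
        "lambda_s": 12e-6,
        "M_s_a_m": 7.0e5,
        "M_DC_a_m": 3.5e5,
        "chi_AC": 550.0,
    },
    "coil": {
        "N": 500,
        "lc_m": 0.040,
        "Ac_m2": math.pi * 0.006**2,
        "km": 1.0,
        "I_AC_A": 5e-5,
        "I_bias_A": 3e-3,
        "sweep_start_hz": 110e3,
        "sweep_stop_hz": 135e3,
        "sweep_step_hz": 50.0,
    },
    "liquid": {
        "eta_pa_s": 1.01e-3,
        "rho_kg_m3": 998.23,
    },
}


@dataclass(frozen=True)
class SensorElement:
    """Geometry, elasticity and magnetic linearization of the ribbon.

    ``E`` is the effective Young's modulus after Delta-E and Poisson
    correction; ``D0`` the intrinsic per-unit-length damping constant
    (kg m^-1 s^-1) lumping mechanical, eddy-current and hysteresis losses;
    ``d_lambda = 3 lambda_s M_DC / M_s**2`` the magnetostrictive linear
    coefficient at the bias point (m/A).
    """

    ls: float
    ws: float
    hs: float
    rho_s: float
    E: float
    D0: float
    lambda_s: float
    M_s: float
    M_DC: float
    chi_AC: float

    def __post_init__(self) -> None:
        for name in ("ls", "ws", "hs", "rho_s", "E", "lambda_s", "M_s", "M_DC"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"sensor field {name!r} must be > 0")
        if self.D0 < 0:
            raise InvalidParameterError("D0 must be >= 0")
        if self.chi_AC < 0:
            raise InvalidParameterError("chi_AC must be >= 0")
        if self.M_DC > self.M_s:
            raise InvalidParameterError("M_DC cannot exceed M_s")

    @property
    def A_s(self) -> float:
        """Cross-sectional area ws*hs (m^2)."""
        return self.ws * self.hs

    @property
    def d_lambda(self) -> float:
        """Magnetostrictive linear coefficient 3*lambda_s*M_DC/M_s**2 (m/A)."""
        return 3.0 * self.lambda_s * self.M_DC / self.M_s**2


@dataclass(frozen=True)
class CoilDrive:
    """Solenoid and excitation parameters.

    The excitation field amplitude is N*I_AC/(km*lc): a leakage coefficient
    km >= 1 reduces the field. ``I_bias`` is carried for provenance only; the
    bias enters the model through the sensor's M_DC and chi_AC.
    """

    N: int
    lc: float
    Ac: float
    km: float = 1.0
    I_AC: float = 5e-5
    I_bias: float = 3e-3
    sweep_start: float = 110e3
    sweep_stop: float = 135e3
    sweep_step: float = 50.0
    mu0: float = MU0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidParameterError("coil needs N >= 1 turns")
        if self.lc <= 0 or self.Ac <= 0 or self.km <= 0:
            raise InvalidParameterError("lc, Ac and km must be > 0")
        if self.I_AC <= 0:
            raise InvalidParameterError("I_AC must be > 0")
        if not (self.sweep_start < self.sweep_stop):
            raise InvalidParameterError("sweep_start must be < sweep_stop")
        if self.sweep_step <= 0:
            raise InvalidParameterError("sweep_step must be > 0")

    def sweep_grid(self) -> np.ndarray:
        """Frequency grid (Hz), both endpoints included when they align."""
        n = int(round((self.sweep_stop - self.sweep_start) / self.sweep_step))
        return self.sweep_start + self.sweep_step * np.arange(n + 1)


@dataclass(frozen=True)
class Liquid:
    """Newtonian liquid seen by the ribbon: dynamic viscosity and density."""

    eta_L: float
    rho_L: float

    def __post_init__(self) -> None:
        if self.eta_L < 0:
            raise InvalidParameterError("viscosity must be >= 0")
        if self.rho_L <= 0:
            raise InvalidParameterError("density must be > 0")

    @property
    def vdv(self) -> float:
        """Viscous damping value sqrt(eta_L*rho_L) (Pa^0.5 s^0.5 kg^0.5 m^-1.5)."""
        return math.sqrt(self.eta_L * self.rho_L)

    @classmethod
    def from_vdv(cls, vdv: float, rho_L: float = 1000.0) -> "Liquid":
        """Liquid with a prescribed viscous damping value at a given density."""
        if vdv < 0:
            raise InvalidParameterError("vdv must be >= 0")
        return cls(eta_L=vdv**2 / rho_L, rho_L=rho_L)


@dataclass(frozen=True)
class SweepCurve:
    """One frequency-sweep response: amplitude (V) on a monotone grid (Hz)."""

    freqs: np.ndarray
    amps: np.ndarray
    t: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "amps", np.asarray(self.amps, dtype=float))
        if self.freqs.ndim != 1 or self.freqs.size == 0:
            raise ValueError("freqs must be a non-empty 1-D array")
        if self.freqs.size != self.amps.size:
            raise ValueError("freqs and amps must have the same length")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")

    def __len__(self) -> int:
        return int(self.freqs.size)


def default_sensor(**overrides: float) -> SensorElement:
    d = DEFAULTS["sensor"]
    base = dict(
        ls=d["ls_m"], ws=d["ws_m"], hs=d["hs_m"], rho_s=d["rho_s_kg_m3"],
        E=d["E_pa"], D0=d["D0_kg_m_s"], lambda_s=d["lambda_s"],
        M_s=d["M_s_a_m"], M_DC=d["M_DC_a_m"], chi_AC=d["chi_AC"],
    )
    base.update(overrides)
    return SensorElement(**base)


def default_coil(**overrides: float) -> CoilDrive:
    d = DEFAULTS["coil"]
    base = dict(
        N=int(d["N"]), lc=d["lc_m"], Ac=d["Ac_m2"], km=d["km"],
        I_AC=d["I_AC_A"], I_bias=d["I_bias_A"],
        sweep_start=d["sweep_start_hz"], sweep_stop=d["sweep_stop_hz"],
        sweep_step=d["sweep_step_hz"],
    )
    base.update(overrides)
    return CoilDrive(**base)


def water() -> Liquid:
    d = DEFAULTS["liquid"]
    return Liquid(eta_L=d["eta_pa_s"], rho_L=d["rho_kg_m3"])


# ---------------------------------------------------------------------------
# Excitation: drive current -> magnetostrictive strain -> equivalent force
# ---------------------------------------------------------------------------

class StrainResult(NamedTuple):
    eps0: float
    F0: float


def strain_amplitude(sensor: SensorElement, coil: CoilDrive) -> StrainResult:
    """Magnetostrictive strain amplitude eps0 and equivalent force F0.

    The small AC field N*I_AC/(km*lc) magnetizes the ribbon linearly
    (susceptibility chi_AC about the bias point) and magnetostriction
    converts the magnetization swing into strain:

        eps0 = d_lambda * chi_AC * N * I_AC / (km * lc)

    The same deformation would be produced by an axial end force of amplitude
    F0 = E * A_s * eps0 (Hooke), which is how the field enters the vibration
    equation.
    """
    eps0 = sensor.d_lambda * sensor.chi_AC * coil.N * coil.I_AC / (coil.km * coil.lc)
    return StrainResult(eps0=eps0, F0=sensor.E * sensor.A_s * eps0)


# ---------------------------------------------------------------------------
# Liquid loading: oscillating-plate shear and total damping coefficient
# ---------------------------------------------------------------------------

def shear_stress_amplitude(liquid: Liquid, omega: float, v0: float) -> float:
    """Shear stress amplitude sqrt(omega*eta*rho/2)*v0 on an oscillating plate.

    Magnitude of the Stokes-second-problem wall shear for a plate oscillating
    with surface velocity amplitude ``v0`` at angular frequency ``omega``;
    the stress opposes the motion.
    """
    if omega <= 0:
        raise InvalidParameterError("omega must be > 0")
    if v0 < 0:
        raise InvalidParameterError("v0 must be >= 0")
    return math.sqrt(omega * liquid.eta_L * liquid.rho_L / 2.0) * v0


def damping_coefficient(sensor: SensorElement, liquid: Liquid, omega: float) -> float:
    """Total damping coefficient beta_L (s^-1) at drive frequency ``omega``.

    Both ribbon faces shed shear into the liquid, adding
    ws*sqrt(2*omega*eta*rho) per unit length to the intrinsic D0:

        beta_L = (D0 + ws*sqrt(2*omega*eta_L*rho_L)) / (2*A_s*rho_s)
    """
    if omega <= 0:
        raise InvalidParameterError("omega must be > 0")
    if sensor.A_s <= 0:
        raise InvalidParameterError("sensor cross-section must be > 0")
    liquid_term = sensor.ws * math.sqrt(2.0 * omega * liquid.eta_L * liquid.rho_L)
    return (sensor.D0 + liquid_term) / (2.0 * sensor.A_s * sensor.rho_s)


# ---------------------------------------------------------------------------
# Bar dynamics: natural frequency and steady-state displacement
# ---------------------------------------------------------------------------

class NaturalFrequency(NamedTuple):
    omega0: float
    f0: float


def natural_frequency(sensor: SensorElement) -> NaturalFrequency:
    """Fundamental longitudinal resonance: omega0 = (pi/ls)*sqrt(E/rho_s)."""
    omega0 = math.pi / sensor.ls * math.sqrt(sensor.E / sensor.rho_s)
    return NaturalFrequency(omega0=omega0, f0=omega0 / (2.0 * math.pi))


@dataclass(frozen=True)
class VibrationState:
    """Steady-state vibration of the ribbon at one drive frequency.

    The displacement profile is u(x, t) = u0*sin(pi*x/ls)*cos(omega*t -
    theta_u) with x measured from one end of the ribbon (x in [0, ls]); the
    half-wave mode peaks at the midpoint. ``v0`` is the velocity amplitude at
    the antinode, omega*u0.
    """

    omega: float
    beta_L: float
    omega0: float
    theta_u: float
    F0: float
    eps0: float
    u0: float
    ls: float

    @property
    def v0(self) -> float:
        return self.omega * self.u0

    def u_amp(self, x) -> np.ndarray:
        """Displacement amplitude |u|(x) along the ribbon (m)."""
        return self.u0 * np.abs(np.sin(np.pi * np.asarray(x, dtype=float) / self.ls))


def displacement_solution(
    sensor: SensorElement,
    coil: CoilDrive,
    liquid: Liquid,
    omega: float,
    beta_at: str = "drive",
) -> VibrationState:
    """Steady-state displacement of the driven, damped ribbon.

    Peak (antinode) amplitude

        u0 = 4*d_lambda*E*chi_AC*N*I_AC / (km*lc*rho_s*ls)
             / sqrt((omega^2 - omega0^2)^2 + 4*beta_L^2*omega^2)

    with phase lag theta_u = atan((omega^2 - omega0^2)/(2*beta_L*omega)).
    ``beta_at`` selects whether beta_L is evaluated at the drive frequency
    ("drive", the full model) or frozen at omega0 ("natural", the
    approximation used by the closed-form resonance expressions).
    """
    if omega <= 0:
        raise InvalidParameterError("omega must be > 0")
    if beta_at not in ("drive", "natural"):
        raise InvalidParameterError("beta_at must be 'drive' or 'natural'")
    omega0 = natural_frequency(sensor).omega0
    beta = damping_coefficient(sensor, liquid, omega if beta_at == "drive" else omega0)
    eps0, F0 = strain_amplitude(sensor, coil)
    denom = math.sqrt((omega**2 - omega0**2) ** 2 + 4.0 * beta**2 * omega**2)
    if denom == 0.0:
        raise ZeroDampingError("undamped drive exactly at resonance: amplitude diverges")
    prefac = (
        4.0 * sensor.d_lambda * sensor.E * sensor.chi_AC * coil.N * coil.I_AC
        / (coil.km * coil.lc * sensor.rho_s * sensor.ls)
    )
    theta_u = math.atan2(omega**2 - omega0**2, 2.0 * beta * omega) if beta > 0 else (
        0.0 if omega < omega0 else math.pi
    )
    return VibrationState(
        omega=omega, beta_L=beta, omega0=omega0, theta_u=theta_u,
        F0=F0, eps0=eps0, u0=prefac / denom, ls=sensor.ls,
    )


# ---------------------------------------------------------------------------
# Response signal: Villari effect -> induced voltage amplitude
# ---------------------------------------------------------------------------

def _response_prefactor(sensor: SensorElement, coil: CoilDrive) -> float:
    # 8*As*N^2*I_AC*(d_lambda*E*chi_AC)^2 / (km*lc*rho_s*ls^2); multiply by
    # omega and the resonance kernel to get U_id.
    g = sensor.d_lambda * sensor.E * sensor.chi_AC
    return (
        8.0 * sensor.A_s * coil.N**2 * coil.I_AC * g**2
        / (coil.km * coil.lc * sensor.rho_s * sensor.ls**2)
    )


def response_amplitude(
    sensor: SensorElement,
    coil: CoilDrive,
    liquid: Liquid,
    omega,
    beta_at: str = "drive",
):
    """Background-free response amplitude U_id(omega) in volts.

    The ribbon's elongation modulates its magnetization (Villari effect); the
    induced EMF in the coil, after the empty-coil excitation term has been
    subtracted, has amplitude

        U_id = 8*As*N^2*I_AC*(d_lambda*E*chi_AC)^2 * omega
               / (km*lc*rho_s*ls^2 * sqrt((omega^2-omega0^2)^2 + 4*beta_L^2*omega^2))

    an inverted-bell, single-peak function of omega. Accepts scalar or array
    ``omega`` (rad/s).
    """
    om = np.asarray(omega, dtype=float)
    if np.any(om <= 0):
        raise InvalidParameterError("omega must be > 0")
    omega0 = natural_frequency(sensor).omega0
    if beta_at == "drive":
        liquid_term = sensor.ws * np.sqrt(2.0 * om * liquid.eta_L * liquid.rho_L)
        beta = (sensor.D0 + liquid_term) / (2.0 * sensor.A_s * sensor.rho_s)
    elif beta_at == "natural":
        beta = damping_coefficient(sensor, liquid, omega0)
    else:
        raise InvalidParameterError("beta_at must be 'drive' or 'natural'")
    denom = np.sqrt((om**2 - omega0**2) ** 2 + 4.0 * beta**2 * om**2)
    if np.any(denom == 0.0):
        raise ZeroDampingError("undamped drive exactly at resonance: amplitude diverges")
    out = _response_prefactor(sensor, coil) * om / denom
    return float(out) if np.isscalar(omega) else out


class ResonancePoint(NamedTuple):
    f_R: float
    U_R: float


def resonance_point(
    sensor: SensorElement,
    coil: CoilDrive,
    liquid: Liquid,
    simplified: bool = False,
) -> ResonancePoint:
    """Closed-form resonance point (f_R in Hz, U_R in V).

    Uses the damping coefficient frozen at omega0 (its sweep variation is
    second order) and the classic amplitude-resonance condition

        omega_R = sqrt(omega0^2 - 2*beta_L^2)

    With ``simplified=True`` the peak voltage drops the beta_L^2 corrections
    (sqrt(omega0^2 - beta_L^2) ~ omega0, omega_R ~ omega0), giving
    U_R = prefactor/(2*beta_L) -- the form whose reciprocal is exactly linear
    in sqrt(eta*rho); ``simplified=False`` keeps the full expression.
    """
    omega0 = natural_frequency(sensor).omega0
    beta = damping_coefficient(sensor, liquid, omega0)
    if beta == 0.0:
        raise ZeroDampingError("beta_L = 0: resonance amplitude diverges")
    if 2.0 * beta**2 >= omega0**2:
        raise OverdampedError(
            f"overdamped: 2*beta_L^2 = {2*beta**2:.4g} >= omega0^2 = {omega0**2:.4g}"
        )
    omega_r = math.sqrt(omega0**2 - 2.0 * beta**2)
    pref = _response_prefactor(sensor, coil)
    if simplified:
        u_r = pref / (2.0 * beta)
    else:
        u_r = pref * omega_r / (2.0 * beta * math.sqrt(omega0**2 - beta**2))
    return ResonancePoint(f_R=omega_r / (2.0 * math.pi), U_R=u_r)


class LinearCoefficients(NamedTuple):
    a: float
    b: float


def reciprocal_linear_coefficients(
    sensor: SensorElement, coil: CoilDrive
) -> LinearCoefficients:
    """Closed-form coefficients of 1/U_R = a*sqrt(eta_L*rho_L) + b.

    Substituting beta_L(omega0) into the simplified resonance voltage gives

        a = ws*sqrt(2*omega0)*km*lc*ls^2 / (8*As^2*N^2*I_AC*(d_lambda*E*chi_AC)^2)
        b = D0*km*lc*ls^2            / (8*As^2*N^2*I_AC*(d_lambda*E*chi_AC)^2)

    so the slope carries the liquid loading and the intercept only the
    intrinsic damping D0 (the air blank).
    """
    omega0 = natural_frequency(sensor).omega0
    denom = sensor.A_s * sensor.rho_s * _response_prefactor(sensor, coil)
    a = sensor.ws * math.sqrt(2.0 * omega0) / denom
    b = sensor.D0 / denom
    return LinearCoefficients(a=a, b=b)


# ---------------------------------------------------------------------------
# Prior-theory reference (frequency-shift detection); comparison output only
# ---------------------------------------------------------------------------

def frequency_shift_reference(sensor: SensorElement, liquid: Liquid, f0: float) -> float:
    """Frequency-analysis prior: Delta_f of the resonance under liquid loading.

        Delta_f = -(sqrt(pi*f0) / (2*pi*rho_s*hs)) * sqrt(eta_L*rho_L)

    Provided only for comparison with frequency-based detection; the amplitude
    pipeline never uses it.
    """
    if f0 <= 0:
        raise InvalidParameterError("f0 must be > 0")
    return -(
        math.sqrt(math.pi * f0) / (2.0 * math.pi * sensor.rho_s * sensor.hs)
    ) * math.sqrt(liquid.eta_L * liquid.rho_L)
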