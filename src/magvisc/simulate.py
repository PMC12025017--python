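"""Synthetic data: calibration fixtures, noisy sweeps, coagulation runs.

Everything the inverse pipeline consumes can be generated here from the
forward model, with known ground truth and seeded randomness:

* the packaged glycerol calibration table (nine standards, 0-80 wt%,
  replicate means and standard deviations) as :func:`table1_fixture`;
* single noisy frequency sweeps (multiplicative Gaussian amplitude noise,
  default relative sd 0.5% -- the repeatability level of the reference
  instrument);
* full coagulation runs: the sample's viscous damping value follows a
  logistic lag/acceleration/plateau profile normalised to start exactly at
  1, the forward model renders each sweep, and the matching air sweep is
  emitted for the per-element blank.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationPoint, find_resonance, smooth_sweep
from .coagulation import CoagulationRun, MARegression, default_ma_regression
from .physics import (
    CoilDrive,
    InvalidParameterError,
    Liquid,
    SensorElement,
    SweepCurve,
    response_amplitude,
)

__all__ = [
    "CoagulationProfile",
    "NoiseSpec",
    "table1_fixture",
    "table1_dataframe",
    "simulate_sweep",
    "simulate_coag_run",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian amplitude noise, seeded for reproducibility.

    Optional additive frequency jitter (sd in Hz, applied to the reported
    grid, off by default) emulates synthesizer granularity.
    """

    rel_amp_sd: float = 0.005
    seed: int = 0
    freq_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rel_amp_sd < 0 or self.freq_jitter_sd < 0:
            raise InvalidParameterError("noise sds must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class CoagulationProfile:
    """Ground-truth damping profile of a clotting sample.

    A logistic sigma(t) = 1/(1 + exp(-rate*(t - lag_min))) is renormalised so
    the trace starts exactly at 1 and saturates at ``x_max``:

        x(t) = 1 + (x_max - 1) * (sigma(t) - sigma(0)) / (1 - sigma(0))

    which reproduces the three stages of a clotting curve -- baseline lag,
    acceleration, plateau -- with closed-form threshold crossings for tests.
    Times are minutes.
    """

    lag_min: float = 2.0
    rate: float = 2.0
    x_max: float = 2.2
    duration_min: float = 20.0

    def __post_init__(self) -> None:
        if self.lag_min < 0 or self.rate <= 0 or self.duration_min <= 0:
            raise InvalidParameterError("lag_min >= 0, rate > 0, duration > 0 required")
        if self.x_max < 1.0:
            raise InvalidParameterError("x_max must be >= 1")

    def x_true(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        sigma = 1.0 / (1.0 + np.exp(-self.rate * (t - self.lag_min)))
        sigma0 = 1.0 / (1.0 + math.exp(self.rate * self.lag_min))
        out = 1.0 + (self.x_max - 1.0) * (sigma - sigma0) / (1.0 - sigma0)
        return float(out) if np.isscalar(t_min) else out

    def crossing_time(self, x_level: float) -> float | None:
        """Closed-form t (min) where x(t) first reaches ``x_level``; None if never."""
        if x_level <= 1.0:
            return 0.0
        if x_level >= self.x_max:
            return None
        sigma0 = 1.0 / (1.0 + math.exp(self.rate * self.lag_min))
        sigma = sigma0 + (x_level - 1.0) / (self.x_max - 1.0) * (1.0 - sigma0)
        if sigma >= 1.0:
            return None
        return self.lag_min - math.log(1.0 / sigma - 1.0) / self.rate


# ---------------------------------------------------------------------------
# Packaged glycerol calibration table
# ---------------------------------------------------------------------------

def table1_dataframe() -> pd.DataFrame:
    """The packaged glycerol calibration table, verbatim as printed.

    Columns carry the printed units: viscosity in mPa s, amplitude in mV.
    """
    ref = importlib.resources.files("magvisc.data") / "glycerol_calibration.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table1_fixture() -> list[CalibrationPoint]:
    """Nine glycerol standards as calibration points in SI units (V, Pa s)."""
    df = table1_dataframe()
    points = []
    for row in df.itertuples(index=False):
        eta = row.viscosity_mpa_s * 1e-3
        points.append(
            CalibrationPoint(
                vdv=math.sqrt(eta * row.density_kg_m3),
                u_r=row.resonant_amplitude_mv * 1e-3,
                f_r=row.resonant_frequency_hz,
                u_r_sd=row.resonant_amplitude_sd_mv * 1e-3,
                f_r_sd=row.resonant_frequency_sd_hz,
                n_rep=20,
                label=f"{int(row.concentration_wt_pct)} wt%",
            )
        )
    return points


# ---------------------------------------------------------------------------
# Sweep and run simulators
# ---------------------------------------------------------------------------

def simulate_sweep(
    sensor: SensorElement,
    coil: CoilDrive,
    liquid: Liquid,
    noise: NoiseSpec | None = None,
    t: float | None = None,
    rng: np.random.Generator | None = None,
) -> SweepCurve:
    """Noisy forward-model sweep on the coil's configured frequency grid.

    Each amplitude is multiplied by (1 + eps), eps ~ N(0, rel_amp_sd). An
    explicit ``rng`` (used by the run simulator) takes precedence over the
    seed in ``noise``.
    """
    noise = noise or NoiseSpec(rel_amp_sd=0.0)
    grid = coil.sweep_grid()
    amps = response_amplitude(sensor, coil, liquid, 2.0 * np.pi * grid)
    if noise.rel_amp_sd > 0 or noise.freq_jitter_sd > 0:
        rng = rng if rng is not None else noise.rng()
        if noise.rel_amp_sd > 0:
            amps = amps * (1.0 + rng.normal(0.0, noise.rel_amp_sd, size=amps.shape))
        if noise.freq_jitter_sd > 0:
            grid = np.sort(grid + rng.normal(0.0, noise.freq_jitter_sd, size=grid.shape))
    return SweepCurve(
        freqs=grid,
        amps=np.maximum(amps, 0.0),
        t=t,
        meta={"simulated": True, "vdv": liquid.vdv},
    )


def simulate_coag_run(
    profile: CoagulationProfile,
    sensor: SensorElement,
    coil: CoilDrive,
    base_liquid: Liquid,
    noise: NoiseSpec | None = None,
    sweep_period_s: float = 6.0,
    window: int = 5,
    reg: MARegression | None = None,
) -> tuple[CoagulationRun, dict]:
    """Simulate one full coagulation measurement with ground truth.

    At each sweep time t the instantaneous liquid has viscous damping value
    x_true(t) * base_liquid.vdv; an air sweep (zero liquid loading, intrinsic
    damping only) provides the per-element blank. y0 and y1 are measured from
    the simulated sweeps through the standard conditioning (smoothing window
    ``window`` + peak picking), exactly as a real run would be processed.

    Returns the run and a ground-truth dict with the true profile values,
    the closed-form R-time of the baseline-subtracted clot-strength trace
    and the true MA under regression ``reg`` (default conversion).
    """
    if sweep_period_s <= 0:
        raise InvalidParameterError("sweep_period_s must be > 0")
    noise = noise or NoiseSpec(rel_amp_sd=0.0)
    reg = reg or default_ma_regression()
    rng = noise.rng()

    air = Liquid(eta_L=0.0, rho_L=base_liquid.rho_L)
    air_sweep = simulate_sweep(sensor, coil, air, noise, t=-sweep_period_s, rng=rng)
    _, u_air = find_resonance(smooth_sweep(air_sweep, window=window))

    t_s = np.arange(0.0, profile.duration_min * 60.0, sweep_period_s)
    x_true = profile.x_true(t_s / 60.0)
    sweeps = []
    for ti, xi in zip(t_s, x_true):
        liq = Liquid.from_vdv(xi * base_liquid.vdv, rho_L=base_liquid.rho_L)
        sweeps.append(simulate_sweep(sensor, coil, liq, noise, t=float(ti), rng=rng))
    _, u_first = find_resonance(smooth_sweep(sweeps[0], window=window))

    run = CoagulationRun(
        sweeps=sweeps,
        y0=1.0 / u_air,
        y1=1.0 / u_first,
        meta={
            "simulated": True,
            "seed": noise.seed,
            "sweep_period_s": sweep_period_s,
            "profile": {
                "lag_min": profile.lag_min,
                "rate": profile.rate,
                "x_max": profile.x_max,
                "duration_min": profile.duration_min,
            },
        },
    )
    run.meta["air_sweep"] = air_sweep

    # True R-time of the baseline-subtracted trace: amplitude slope*(x-1)
    # reaches 2 mm where x = 1 + 2/slope.
    true_r = profile.crossing_time(1.0 + 2.0 / reg.slope)
    truth = {
        "t_min": t_s / 60.0,
        "x_true": x_true,
        "max_x": float(profile.x_max),
        "true_ma_mm": float(reg(profile.x_max)),
        "true_r_min": true_r,
        "seed": noise.seed,
    }
    return run, truth
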