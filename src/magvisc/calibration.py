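"""Inverse method: from measured sweeps to a calibrated viscosity estimate.

Measured frequency sweeps are conditioned (empty-coil background subtraction,
zero-phase smoothing), the resonance point is located as the maximum of the
conditioned curve, and a calibration line

    1/U_R = slope * sqrt(eta_L*rho_L) + intercept

is fitted by ordinary least squares to a series of viscosity standards
(classically a glycerol dilution series). The slope is the device sensitivity
(V^-1 per Pa^0.5 s^0.5 kg^0.5 m^-1.5); inverting the line maps a resonant
amplitude to the liquid's viscous damping value sqrt(eta_L*rho_L).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .physics import InvalidParameterError, SweepCurve

__all__ = [
    "GridMismatchError",
    "DegenerateFitError",
    "BelowBlankWarning",
    "BoundaryPeakWarning",
    "CalibrationPoint",
    "CalibrationModel",
    "subtract_background",
    "smooth_sweep",
    "find_resonance",
    "fit_calibration",
    "estimate_vdv",
]


class GridMismatchError(ValueError):
    """Two sweeps do not share an identical frequency grid."""


class DegenerateFitError(ValueError):
    """Too few distinct abscissae for a least-squares line."""


class BelowBlankWarning(UserWarning):
    """Estimated viscous damping value fell below the blank (negative)."""


class BoundaryPeakWarning(UserWarning):
    """Sweep maximum sits on a grid boundary; the true peak may lie outside."""


@dataclass(frozen=True)
class CalibrationPoint:
    """One viscosity standard: known sqrt(eta*rho) and its measured response.

    ``u_r`` is the replicate-mean resonant amplitude in volts (means are taken
    on amplitudes, then inverted during fitting); ``f_r`` is informational.
    """

    vdv: float
    u_r: float
    f_r: float | None = None
    u_r_sd: float = 0.0
    f_r_sd: float = 0.0
    n_rep: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.vdv < 0:
            raise InvalidParameterError("vdv must be >= 0")
        if self.u_r <= 0:
            raise InvalidParameterError("u_r must be > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line 1/u_r vs sqrt(eta*rho), with diagnostics.

    ``sensitivity`` aliases the slope. ``detection_limit`` (3 sigma of the
    blank reciprocal amplitude over the slope) is present only when a blank
    series was supplied to :func:`fit_calibration`; this is the package's own
    convention for a limit of detection, not a reproduction of any published
    value.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    detection_limit: float | None = None
    blank_reciprocal_sd: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.slope

    def to_dict(self) -> dict:
        return {
            "slope_v_inv": self.slope,
            "intercept_v_inv": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "sensitivity_v_inv": self.sensitivity,
            "detection_limit": self.detection_limit,
            "blank_reciprocal_sd_v_inv": self.blank_reciprocal_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=d["slope_v_inv"],
            intercept=d["intercept_v_inv"],
            r_squared=d["r_squared"],
            n_points=int(d["n_points"]),
            detection_limit=d.get("detection_limit"),
            blank_reciprocal_sd=d.get("blank_reciprocal_sd_v_inv"),
        )


# ---------------------------------------------------------------------------
# Sweep conditioning
# ---------------------------------------------------------------------------

def subtract_background(sweep: SweepCurve, empty_coil: SweepCurve) -> SweepCurve:
    """Subtract the pre-measured empty-coil response, flooring at zero.

    The excitation field induces a coil voltage of its own that carries no
    information about the liquid; it is removed pointwise. The two sweeps must
    share an identical frequency grid -- no silent interpolation.
    """
    if len(sweep) != len(empty_coil) or not np.array_equal(
        sweep.freqs, empty_coil.freqs
    ):
        raise GridMismatchError("sweep and empty-coil grids differ")
    amps = np.maximum(sweep.amps - empty_coil.amps, 0.0)
    meta = dict(sweep.meta)
    meta["background_subtracted"] = True
    return SweepCurve(freqs=sweep.freqs, amps=amps, t=sweep.t, meta=meta)


def smooth_sweep(sweep: SweepCurve, window: int = 5) -> SweepCurve:
    """Zero-phase centered moving average with edge truncation.

    A symmetric window introduces no phase shift, so the peak location is
    preserved up to curvature effects. At the edges the window shrinks to the
    available points. ``window`` must be odd; ``window=1`` is the identity.
    """
    if window % 2 == 0 or window < 1 or window > len(sweep):
        raise InvalidParameterError(
            f"window must be odd and within [1, {len(sweep)}], got {window}"
        )
    if window == 1:
        return sweep
    kernel = np.ones(window)
    summed = np.convolve(sweep.amps, kernel, mode="same")
    counts = np.convolve(np.ones(len(sweep)), kernel, mode="same")
    meta = dict(sweep.meta)
    meta["smoothing_window"] = window
    return SweepCurve(freqs=sweep.freqs, amps=summed / counts, t=sweep.t, meta=meta)


def find_resonance(sweep: SweepCurve, refine: bool = False) -> tuple[float, float]:
    """Resonance point (f_R in Hz, U_R in V) as the sweep maximum.

    Pure argmax by default, matching how the instrument picks resonance
    points; ties break toward the lowest frequency. A warning is issued when
    the maximum sits on the first or last grid point, since the true peak may
    lie outside the swept range. ``refine=True`` applies a three-point
    parabolic interpolation around an interior maximum.
    """
    idx = int(np.argmax(sweep.amps))
    if idx in (0, len(sweep) - 1):
        warnings.warn(
            "sweep maximum on grid boundary; peak may lie outside sweep range",
            BoundaryPeakWarning,
            stacklevel=2,
        )
        return float(sweep.freqs[idx]), float(sweep.amps[idx])
    if refine and len(sweep) >= 3:
        fm, f0_, fp = sweep.freqs[idx - 1 : idx + 2]
        ym, y0, yp = sweep.amps[idx - 1 : idx + 2]
        denom = ym - 2.0 * y0 + yp
        if denom < 0:  # proper curvature for a maximum
            delta = 0.5 * (ym - yp) / denom
            step = 0.5 * (fp - fm)
            return float(f0_ + delta * step), float(y0 - 0.25 * (ym - yp) * delta)
    return float(sweep.freqs[idx]), float(sweep.amps[idx])


# ---------------------------------------------------------------------------
# Calibration line and inversion
# ---------------------------------------------------------------------------

def fit_calibration(
    points: list[CalibrationPoint],
    blank_reciprocal_sd: float | None = None,
) -> CalibrationModel:
    """OLS fit of 1/u_r (V^-1) against sqrt(eta*rho) over the standards.

    The slope is reported as the sensitivity. When the standard deviation of
    the blank's reciprocal amplitude is supplied, the detection limit
    3*sd/slope is attached.
    """
    if len(points) < 2 or len({p.vdv for p in points}) < 2:
        raise DegenerateFitError("need >= 2 standards with distinct vdv")
    x = np.array([p.vdv for p in points])
    y = 1.0 / np.array([p.u_r for p in points])
    res = stats.linregress(x, y)
    lod = None
    if blank_reciprocal_sd is not None:
        if blank_reciprocal_sd < 0:
            raise InvalidParameterError("blank_reciprocal_sd must be >= 0")
        lod = 3.0 * blank_reciprocal_sd / res.slope
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(points),
        detection_limit=lod,
        blank_reciprocal_sd=blank_reciprocal_sd,
    )


def estimate_vdv(u_r: float, model: CalibrationModel) -> float:
    """Invert the calibration line: vdv = (1/u_r - intercept)/slope.

    Strictly decreasing in ``u_r``. A result below zero (amplitude above the
    blank) is returned as-is with a :class:`BelowBlankWarning`.
    """
    if u_r <= 0:
        raise InvalidParameterError("u_r must be > 0")
    if model.slope <= 0:
        raise InvalidParameterError("calibration slope must be > 0")
    vdv = (1.0 / u_r - model.intercept) / model.slope
    if vdv < 0:
        warnings.warn(
            f"estimated vdv {vdv:.4g} below blank", BelowBlankWarning, stacklevel=2
        )
    return vdv
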