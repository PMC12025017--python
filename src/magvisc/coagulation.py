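"""Coagulation monitoring: sweep series -> damping trace -> TEG-style trace.

During clotting, fibrin polymerisation raises the sample's effective
viscosity while its density stays nearly constant, so the viscous damping
value sqrt(eta_L*rho_L) tracks clot formation. Because each disposable
sensing element differs slightly, every run is normalised per element from
two of its own measurements: the element's response in air (reciprocal
amplitude y0, the intercept of the calibration line) and the initial
in-sample response (y1, with the fresh sample's damping value defined as 1).
Any later reciprocal amplitude y then maps to

    x = (y - y0) / (y1 - y0)

a dimensionless viscous damping value normalised to the uncoagulated sample.
A fitted linear regression MA = slope*x + intercept (defaults 19.43 mm and
-13.19 mm, from a quality-control series against a reference
thromboelastograph) converts x(t) into a clot-strength trace in millimetres,
from which the standard TEG parameters R, K, alpha-angle and MA are read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibration import find_resonance, smooth_sweep
from .physics import InvalidParameterError, SweepCurve

__all__ = [
    "DEFAULT_MA_SLOPE",
    "DEFAULT_MA_INTERCEPT",
    "DegenerateNormalizationError",
    "CoagulationRun",
    "DampingTrace",
    "TEGTrace",
    "MARegression",
    "default_ma_regression",
    "resonance_trace",
    "damping_trace",
    "fit_ma_regression",
    "to_teg_trace",
    "extract_teg_params",
    "compare_traces",
    "analyze_run",
]

#: Default clot-strength conversion MA = 19.43*x - 13.19 (mm).
DEFAULT_MA_SLOPE = 19.43
DEFAULT_MA_INTERCEPT = -13.19

#: Clinical TEG thresholds: R at 2 mm, K from 2 mm to 20 mm.
R_THRESHOLD_MM = 2.0
K_THRESHOLD_MM = 20.0


class DegenerateNormalizationError(ValueError):
    """y1 == y0: the per-element normalisation is undefined."""


@dataclass(frozen=True)
class CoagulationRun:
    """Time-ordered sweeps of one coagulation measurement plus its blanks.

    ``y0``/``y1`` are the reciprocal resonant amplitudes (V^-1) of the element
    in air and of the fresh sample, measured under the same gain as the run.
    """

    sweeps: list[SweepCurve]
    y0: float
    y1: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise InvalidParameterError("run needs at least one sweep")
        times = [s.t for s in self.sweeps]
        if any(t is None for t in times):
            raise InvalidParameterError("every sweep in a run needs a timestamp")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InvalidParameterError("sweep timestamps must be strictly increasing")
        if not (self.y1 > self.y0 > 0):
            raise InvalidParameterError(
                "need y1 > y0 > 0 (liquid damps more than air)"
            )


@dataclass(frozen=True)
class DampingTrace:
    """Normalised viscous damping value x(t); initial sample == 1 by design."""

    t: np.ndarray  # minutes
    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.t.size != self.x.size or self.t.size == 0:
            raise ValueError("t and x must be non-empty and equally long")

    @property
    def max_x(self) -> float:
        return float(np.max(self.x))


@dataclass(frozen=True)
class MARegression:
    """Linear map from maximum damping value to TEG maximum amplitude (mm)."""

    slope: float
    intercept: float
    r_squared: float = 1.0
    n: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidParameterError("MA regression slope must be > 0")

    def __call__(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def default_ma_regression() -> MARegression:
    return MARegression(slope=DEFAULT_MA_SLOPE, intercept=DEFAULT_MA_INTERCEPT)


@dataclass(frozen=True)
class TEGTrace:
    """Clot-strength amplitude in mm over time, with extracted parameters.

    Only the upper half-trace is modelled; the mirrored lower half of a
    thromboelastograph display is a plotting artifact. ``params`` holds
    R_time/K_time (min), alpha_angle (degrees) and MA (mm), with None for
    parameters the trace never defines.
    """

    t: np.ndarray  # minutes
    amplitude: np.ndarray  # mm, >= 0
    params: dict = field(default_factory=dict)
    regression: MARegression | None = None
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "amplitude", np.asarray(self.amplitude, dtype=float))
        if self.t.size != self.amplitude.size or self.t.size == 0:
            raise ValueError("t and amplitude must be non-empty and equally long")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be >= 0")


# ---------------------------------------------------------------------------
# Sweep series -> resonance trace -> damping trace
# ---------------------------------------------------------------------------

def resonance_trace(
    run: CoagulationRun, window: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sweep conditioning and peak picking over a run.

    Returns (t_seconds, U_R volts, f_R hertz), one entry per sweep.
    """
    ts, urs, frs = [], [], []
    for i, sweep in enumerate(run.sweeps):
        if len(sweep) == 0:
            raise InvalidParameterError(f"sweep {i} is empty")
        f_r, u_r = find_resonance(smooth_sweep(sweep, window=window))
        ts.append(float(sweep.t))
        urs.append(u_r)
        frs.append(f_r)
    return np.array(ts), np.array(urs), np.array(frs)


def damping_trace(
    t_s: np.ndarray, urs: np.ndarray, y0: float, y1: float
) -> DampingTrace:
    """Per-element normalised damping values x(t) = (1/U_R - y0)/(y1 - y0).

    ``t_s`` is in seconds (converted to minutes for the trace); ``y0`` and
    ``y1`` must come from the same element and gain as the run, which is what
    cancels element-to-element scatter.
    """
    t_s = np.asarray(t_s, dtype=float)
    urs = np.asarray(urs, dtype=float)
    if y1 == y0:
        raise DegenerateNormalizationError("y1 == y0: normalisation undefined")
    if not (y1 > y0 > 0):
        raise InvalidParameterError("need y1 > y0 > 0")
    if np.any(urs <= 0):
        raise InvalidParameterError("all resonant amplitudes must be > 0")
    x = (1.0 / urs - y0) / (y1 - y0)
    return DampingTrace(t=t_s / 60.0, x=x)


# ---------------------------------------------------------------------------
# Damping trace -> TEG trace
# ---------------------------------------------------------------------------

def fit_ma_regression(pairs: list[tuple[float, float]]) -> MARegression:
    """OLS of reference MA (mm) on maximum damping value, over sample pairs."""
    if len(pairs) < 2 or len({p[0] for p in pairs}) < 2:
        raise InvalidParameterError("need >= 2 pairs with distinct max_x")
    x = np.array([p[0] for p in pairs], dtype=float)
    ma = np.array([p[1] for p in pairs], dtype=float)
    res = stats.linregress(x, ma)
    return MARegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
    )


def to_teg_trace(
    trace: DampingTrace,
    reg: MARegression | None = None,
    subtract_baseline: bool = False,
) -> TEGTrace:
    """Map a damping trace to clot-strength millimetres.

    Default mode clips the regression image at zero. With
    ``subtract_baseline=True`` the amplitude at t=0 (the regression image of
    the fresh sample, x ~ 1) is subtracted first so the trace starts at 0 mm
    like an instrument trace; both modes are legitimate readings of the
    conversion and extracted parameters differ accordingly.
    """
    reg = reg or default_ma_regression()
    amp = reg(trace.x)
    if subtract_baseline:
        amp = amp - amp[0]
    amp = np.maximum(amp, 0.0)
    teg = TEGTrace(
        t=trace.t, amplitude=amp, regression=reg,
        baseline_subtracted=subtract_baseline,
    )
    params = extract_teg_params(teg)
    return TEGTrace(
        t=trace.t, amplitude=amp, params=params, regression=reg,
        baseline_subtracted=subtract_baseline,
    )


def _first_crossing(t: np.ndarray, amp: np.ndarray, level: float) -> float | None:
    """First time amp reaches ``level``, linearly interpolated; None if never."""
    if amp[0] >= level:
        return float(t[0])
    above = np.nonzero(amp >= level)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    a0, a1 = amp[i - 1], amp[i]
    if a1 == a0:
        return float(t1)
    return float(t0 + (level - a0) * (t1 - t0) / (a1 - a0))


def extract_teg_params(trace: TEGTrace) -> dict:
    """Clinical TEG parameters from a clot-strength trace.

    R_time: first crossing of 2 mm. K_time: time from 2 mm to 20 mm (None if
    20 mm is never reached). alpha_angle: angle in degrees of the chord from
    the 2 mm crossing to the 20 mm crossing (mm per min); when 20 mm is not
    reached, the steepest tangent after the 2 mm crossing is used instead.
    MA: maximum amplitude. Threshold crossings are linearly interpolated
    between samples.
    """
    t, amp = trace.t, trace.amplitude
    ma = float(np.max(amp))
    r_time = _first_crossing(t, amp, R_THRESHOLD_MM)
    if r_time is None:
        return {"R_time": None, "K_time": None, "alpha_angle": None, "MA": ma}
    t20 = _first_crossing(t, amp, K_THRESHOLD_MM)
    if t20 is not None and t20 > r_time:
        k_time = t20 - r_time
        alpha = math.degrees(math.atan((K_THRESHOLD_MM - R_THRESHOLD_MM) / k_time))
    else:
        k_time = None if t20 is None else 0.0
        mask = t >= r_time
        if np.count_nonzero(mask) >= 2:
            slopes = np.diff(amp[mask]) / np.diff(t[mask])
            alpha = math.degrees(math.atan(float(np.max(slopes))))
        else:
            alpha = None
    return {"R_time": r_time, "K_time": k_time, "alpha_angle": alpha, "MA": ma}


# ---------------------------------------------------------------------------
# Trace comparison
# ---------------------------------------------------------------------------

def compare_traces(test: TEGTrace, reference: TEGTrace) -> dict:
    """RRMSE (%) and R^2 of a test trace against a reference trace.

    The reference is resampled onto the test grid by linear interpolation
    over the overlapping time span. RRMSE is the RMS error divided by the
    reference mean, in percent; R^2 treats the reference as truth
    (1 - SS_res/SS_tot of the reference amplitudes).
    """
    lo = max(test.t[0], reference.t[0])
    hi = min(test.t[-1], reference.t[-1])
    if lo >= hi:
        raise ValueError("traces have disjoint time spans")
    mask = (test.t >= lo) & (test.t <= hi)
    t = test.t[mask]
    a_test = test.amplitude[mask]
    a_ref = np.interp(t, reference.t, reference.amplitude)
    ref_mean = float(np.mean(a_ref))
    if ref_mean == 0:
        raise ValueError("reference trace has zero mean amplitude")
    rmse = math.sqrt(float(np.mean((a_test - a_ref) ** 2)))
    ss_res = float(np.sum((a_test - a_ref) ** 2))
    ss_tot = float(np.sum((a_ref - ref_mean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return {"rrmse_pct": 100.0 * rmse / ref_mean, "r_squared": r2}


# ---------------------------------------------------------------------------
# Convenience: full pipeline for one run
# ---------------------------------------------------------------------------

def analyze_run(
    run: CoagulationRun,
    window: int = 5,
    reg: MARegression | None = None,
    subtract_baseline: bool = False,
) -> tuple[DampingTrace, TEGTrace, dict]:
    """Run the whole pipeline: sweeps -> damping trace -> TEG trace -> params."""
    t_s, urs, _ = resonance_trace(run, window=window)
    dtrace = damping_trace(t_s, urs, run.y0, run.y1)
    teg = to_teg_trace(dtrace, reg=reg, subtract_baseline=subtract_baseline)
    return dtrace, teg, teg.params
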