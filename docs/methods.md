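# Methods

## Physical model and assumptions

The sensing element is modelled as a free-free elastic bar of length l_s,
width w_s, thickness h_s, density ρ_s and effective Young's modulus E,
driven in its fundamental longitudinal half-wave mode (shape sin(πx/l_s),
x ∈ [0, l_s] from one end; the antinode sits at the midpoint). The model is
linear throughout:

* **Magnetization and magnetostriction are linearised about the bias
  point.** A large DC bias sets the operating magnetization M_DC; the small
  AC field N·I_AC/(k_m·l_c) produces a magnetization swing χ_AC·H and a
  strain swing d_λ·ΔM with d_λ = 3λ_s·M_DC/M_s². Hysteresis, nonlinear
  magnetostriction and the ΔE effect beyond a corrected constant E are out
  of scope.
* **The drive field is replaced by an equivalent midpoint force** of
  amplitude F₀ = E·A_s·ε₀ producing the identical static deformation,
  ε₀ = d_λ·χ_AC·N·I_AC/(k_m·l_c).
* **The liquid acts through Stokes' second problem.** The sample cell is
  treated as infinite (the viscous penetration depth at ~120 kHz is
  micrometres), the liquid as Newtonian, and each ribbon face sheds a shear
  stress of amplitude √(ω·η_L·ρ_L/2)·v₀ opposing the motion. Both faces
  together add w_s·√(2ω·η_L·ρ_L) per unit length of damping.
* **All element-intrinsic losses are lumped into one constant D₀**
  (kg·m⁻¹·s⁻¹ per unit length): mechanical damping, eddy currents, elastic
  hysteresis. The total damping coefficient is
  β_L = (D₀ + w_s·√(2ω·η_L·ρ_L))/(2·A_s·ρ_s).

The steady-state displacement has antinode amplitude
u₀ = 4·d_λ·E·χ_AC·N·I_AC/(k_m·l_c·ρ_s·l_s) / √((ω²−ω₀²)² + 4β_L²ω²) and
phase lag θ_u = atan((ω²−ω₀²)/(2β_L·ω)). The ribbon's elongation modulates
its magnetization (Villari effect); the induced EMF amplitude, after
empty-coil background subtraction, is

    U_id(ω) = 8·A_s·N²·I_AC·(d_λ·E·χ_AC)²·ω
              / (k_m·l_c·ρ_s·l_s²·√((ω²−ω₀²)² + 4β_L²ω²)).

The flattened typography of the source expressions for U_id and for the
1/U_R line admits more than one reading of the l_s and ρ_s placement; the
package therefore re-derives the whole chain from the displacement solution
and validates the closed-form line coefficients against a two-point
numerical solve of 1/U_R — an internal-consistency check that is part of the
test suite rather than a typographic trust.

### Resonance conventions (and a deliberate discrepancy)

Two "resonance frequencies" coexist in this model:

* the **displacement (amplitude) resonance** √(ω₀² − 2β_L²), the maximizer
  of the resonance kernel 1/√((ω²−ω₀²)²+4β_L²ω²) for frequency-frozen β_L —
  this is the closed form `resonance_point` returns;
* the **velocity resonance** ω₀, the exact maximizer of U_id(ω) ∝
  ω/√(…) for frozen β_L, because the response is an induced EMF and carries
  a factor ω.

The two differ by ≈ β_L²/(2π·ω₀) Hz — about 40 Hz at water-like loading,
up to ~300 Hz at the top of the glycerol range. This is far below the 50 Hz
experimental sweep step, so the distinction is irrelevant to peak *value*
analysis (the swept peak value matches the closed-form U_R to
O((β_L/ω₀)²) ≈ 0.03%), but a 1 Hz-resolution argmax of U_id will locate ω₀,
not √(ω₀²−2β_L²). The package implements U_id faithfully with the ω factor,
keeps the conventional closed form for `resonance_point`, and reports the
gap between them as a diagnostic (`resonance_argmax_max_deviation_hz` in the
acceptance output). The amplitude pipeline is insensitive to this choice
because it consumes only peak values.

β_L is evaluated at the drive frequency when computing full sweep curves and
frozen at ω₀ inside the closed-form resonance expressions (its variation
across the peak is second order); `beta_at="natural"` exposes the frozen
variant for sensitivity studies. `resonance_point(simplified=True)` drops
the β_L² corrections entirely, giving the exactly-linear reciprocal law the
calibration coefficients are derived from; the default keeps them.

Degenerate regimes raise typed errors rather than returning complex or
infinite values: β_L = 0 (diverging amplitude) raises `ZeroDampingError`,
2β_L² ≥ ω₀² raises `OverdampedError`.

## Parameter defaults

Geometry and drive follow the reference instrument: l_s = 18 mm, w_s = 3 mm,
h_s = 29 µm; N = 500 turns, l_c = 40 mm, 12 mm bore (A_c = π·(6 mm)²),
k_m = 1, I_AC = 0.05 mA, bias 3 mA; sweep 110–135 kHz in 50 Hz steps.

The material constants of the amorphous ribbon are not directly measured;
the defaults are configuration values chosen once and documented here:

| parameter | default | units | rationale |
|---|---|---|---|
| ρ_s | 7900 | kg·m⁻³ | typical Fe-based amorphous ribbon |
| E (effective) | 1.4965·10¹¹ | Pa | calibrated: ρ_s·(2·l_s·f_obs)² with f_obs = 120898.3 Hz, the observed water-adjacent resonance |
| λ_s | 12·10⁻⁶ | – | Metglas-2826MB-class saturation magnetostriction |
| M_s | 7·10⁵ | A·m⁻¹ | saturation induction ≈ 0.88 T |
| M_DC | 3.5·10⁵ | A·m⁻¹ | bias near the d_λ maximum (≈ M_s/2) |
| χ_AC | 550 | – | sets the simulated resonance amplitudes on the observed mV scale (≈13.6 mV in water) |
| D₀ | 15.5 | kg·m⁻¹·s⁻¹ | sets the air/water amplitude ratio so the simulated intercept/slope ratio matches the glycerol calibration's (≈61/13.8) |

Every default lives in `magvisc.physics.DEFAULTS` and is overridable through
the TOML config ([sensor]/[coil]/[liquid] tables, unit-suffixed keys).

## Inverse method

Sweeps are conditioned by exact-grid empty-coil subtraction (no
interpolation; mismatched grids are an error) and a centered moving-average
filter (default window 5 points = 250 Hz). The moving average is zero-phase,
so it cannot bias the peak location; the edges truncate the window. The
resonance is the grid argmax (ties to the lowest frequency, boundary maxima
flagged), exactly as the instrument picks it; 3-point parabolic refinement
is available behind a flag but off by default.

Calibration is ordinary least squares of 1/U_R on √(η·ρ); replicate
amplitudes are averaged *before* inversion, matching how replicate tables
are reported. The slope is the sensitivity. When a blank (air) replicate
series is supplied, a detection limit 3·sd(blank reciprocal)/slope is
attached — this 3σ convention is the package's own; the blank mean needed to
reproduce any particular published detection limit is not available, so no
such reproduction is claimed.

## Coagulation pipeline

Each disposable element is self-normalised: y₀ (air) and y₁ (fresh sample)
are the element's own reciprocal resonant amplitudes, measured through the
identical conditioning as the run, and x = (y−y₀)/(y₁−y₀) with the fresh
sample's viscous damping value defined as 1 (clinically reasonable because
plasma-like samples start near water). This cancels element-to-element gain
scatter exactly when y₀, y₁ and the run share one gain — a property the
tests assert by perturbation.

The clot-strength conversion MA = 19.43·x − 13.19 mm ships as the default
`MARegression` (refittable from quality-control pairs via
`fit_ma_regression`). Since x = 1 maps to 6.24 mm, two trace conventions are
provided: the default clips negatives and starts at 6.24 mm; the
`subtract_baseline` mode removes the t = 0 amplitude so the trace starts at
0 mm like an instrument trace. TEG parameters follow the clinical
definitions — R at the 2 mm crossing, K from 2 to 20 mm, α as the chord
angle between those crossings (steepest-tangent fallback when 20 mm is
never reached), MA as the maximum — with linear interpolation between
samples for all crossings; parameters a trace never defines are reported as
missing (JSON null), never as 0. Trace agreement is quantified by RRMSE
(RMS error over the reference mean, %) and R² with the reference as truth,
after linear resampling onto the test grid. Fibrinolysis parameters and
clot-lysis modelling are out of scope.

## Synthetic data

The generators exist so every pipeline input can be produced with known
ground truth:

* **Glycerol table**: the nine-standard calibration series (0–80 wt%,
  viscosities 1.01–60.1 mPa·s, 20 replicates each) ships verbatim as a CSV
  fixture.
* **Sweeps**: forward-model curves on the 110–135 kHz grid with
  multiplicative Gaussian amplitude noise, default relative sd 0.5% — the
  repeatability level of the reference measurements. Optional frequency
  jitter is off by default.
* **Coagulation runs**: the true damping value follows a logistic
  renormalised to start exactly at 1, x(t) = 1 + (x_max−1)·(σ(t)−σ(0))/(1−σ(0)),
  σ(t) = 1/(1+e^(−rate·(t−lag))) — the simplest form with the observed
  lag/acceleration/plateau stages and closed-form threshold crossings for
  oracle tests. Defaults lag = 2 min, rate = 2 min⁻¹, x_max = 2.2 (a
  mid-range quality-control-like clot, MA ≈ 29.6 mm under the default
  conversion), 20 min at one sweep per 6 s (the sweep repetition period is
  a configurable assumption, not a measured value). The air sweep is
  simulated as η_L·ρ_L = 0 with D₀ only.

Every generator is a pure function of (parameters, seed).

What the synthetic data does *not* emulate: real blood rheology
(shear-thinning, hematocrit, non-Newtonian clot mechanics), sensor fouling,
element-to-element manufacturing scatter beyond the y₀/y₁ normalisation,
temperature drift, and electronics artifacts (anti-resonance peaks, gain
ripple). Passing recovery tests therefore demonstrates the pipeline's
correctness and noise robustness under the stated noise model, not clinical
performance.

## Problem sizes and tolerances

The recovery studies use 20 runs of 200 sweeps (501 points each), enough to
give stable pass/fail statistics while keeping the whole suite in seconds.
Recovery thresholds (max_x within 5% relative, R-time within 0.3 min, ≥18
of 20 seeded runs) are fixed study conditions, not fitted numbers. The
end-to-end R-time check runs in the baseline-subtracted mode: in clip mode
every trace starts above the 2 mm threshold and R is trivially zero.
Floating-point comparisons in tests use relative tolerances matched to the
arithmetic at hand (machine precision for algebraic identities, 0.1% for
simplified-vs-exact resonance forms, grid resolution for argmax checks).

## Known limitations

* The linear 1/U_R law degrades at high viscosity where the penetration
  depth and nonlinearity assumptions weaken; the calibration range ends at
  the 80 wt% glycerol standard (√(η·ρ) ≈ 8.5).
* D₀, χ_AC and the magnetic constants are order-of-magnitude defaults; the
  absolute simulated voltage scale is therefore representative, not
  predictive. Per-device calibration (the y₀/y₁ normalisation and the
  standards fit) is what carries quantitative weight.
* The model predicts smaller resonance-frequency shifts with loading than
  measured tables show; the amplitude pipeline does not depend on the shift.
* The velocity/displacement resonance distinction described above means
  closed-form peak *locations* are conventional to within ~β_L²/ω₀.
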