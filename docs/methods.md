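# Methods

This note records the models implemented in `nmrdyn`, the assumptions
behind them, the defaults and why they were chosen, and what the
synthetic-data validation does and does not demonstrate.

## Peak tables and chemical-shift perturbations

Peak tables are delimited text with a configurable column mapping; all
ppm values are written with six decimals so round trips are lossless at
any realistic spectrometer precision. Intensity normalisation across
acquisition conditions divides by the scans and dilution ratios and
multiplies by the ¹H 90° pulse-length ratio — the proportional-to-pulse
receiver-equivalence convention; an additional global scale factor
supports cross-temperature comparison where transverse-relaxation losses
change the overall signal level (e.g. ~70 % residual intensity at 25 °C
against a 50 °C reference).

Amide and methyl CSPs use the conventional nitrogen/carbon weights of
1/5 and 1/4. The significance threshold defaults to 0.05 ppm and is
applied globally (not per spectrum); both are configurable.

Secondary chemical shifts combine Δδ(Cα) − Δδ(Cβ) by default (the
difference mode separates helix from strand with opposite signs; a sum
mode is available). The 1-2-1 smoothing over (i−1)–i–(i+1) renormalises
the available weights at chain termini and around missing residues
rather than zero-padding, which would artificially damp terminal values;
missing residues are skipped, never interpolated.

## Backbone relaxation

Decay series are fitted to I(t) = I0·exp(−Rt) by nonlinear least
squares. Errors come from Monte-Carlo resampling: replicate datasets are
drawn around the fitted curve with per-point Gaussian noise (the stated
intensity errors, or the residual scatter when absent) and refitted; the
error is the replicate standard deviation. The seed is mandatory, so
errors are bit-reproducible; the default replicate count is 500.

R2 is derived from R1ρ by the off-resonance correction
R2 = R1ρ/sin²θ − R1/tan²θ with θ = arctan(ω/Ω). Tilt angles below 1°
are rejected as ill-conditioned (the correction then amplifies noise by
>10³). A helper reports the spin-lock timescale ceiling 1/(2πω); for
the 2 kHz field used throughout this is ≈ 80 µs — exchange slower than
that is invisible to R1ρ.

TRACT inverts the ¹⁵N DD/CSA transverse cross-correlated rate
ηxy = (R2β − R2α)/2 to the rotational correlation time using
ηxy = (1/8)·d·c·P2(cos β)·[4J(0) + 3J(ωN)] with the rigid-rotor
spectral density J(ω) = (2/5)τc/(1+(ωτc)²), dipolar constant
d = (μ0/4π)γHγNħ/r³ (r = 1.02 Å), CSA constant c = Δσ·ωN
(Δσ = −160 ppm) and β = 17° between the CSA principal axis and the N–H
bond (standard literature geometry). τc is found by bisection on
[0.1, 200] ns; the relation is monotone there, so the root is unique.
This is a rigid-rotor estimate: internal motion (S² < 1) biases it low,
and flexible residues overestimate apparent size — the method is meant
for folded-segment averages.

Model-free analysis (S², Rex per residue) is out of scope; the module
exposes the input rates (R1, R2(R1ρ), R2β, hetNOE, R1·R2β with
first-order error propagation) that such an analysis would consume.

## Methyl order parameters

The SQ/TQ intensity-ratio build-up
|Ia/Ib| = ¾η·tanh(√(η²+δ²)T)/(√(η²+δ²) − δ·tanh(√(η²+δ²)T)) is fitted
for (η, δ) with both bounded non-negative; δ absorbs relaxation coupling
to external protons and has no physical upper bound. The default delay
grid is eight values from 2 to 24 ms. The conversion
S²axis·τc = η/k uses k = (9/10)(μ0/4π)²[P2(cos 90°)]²γH⁴ħ²/r_HH⁶
evaluated from CODATA constants with r_HH = 1.813 Å, giving
k = 3.609×10⁹ s⁻²; the squared (μ0/4π)² form is the one consistent with
η ≈ 10.8 s⁻¹ ↔ S²axis·τc ≈ 3.0 ns. With an external τc (default
14.4 ns at 37 °C in D2O for this system class) S²axis itself is
reported.

## MQ-CPMG relaxation dispersion

R2,eff = −(1/T)·ln(I/I0) with a constant-time period T = 30 ms by
default. The forward model propagates the multiple-quantum coherence of
a two-site exchanging spin system numerically: a two-component complex
vector (one element per site, starting at the site populations in DQ)
evolves under generators L = K − R2·1 + i·diag(0, ±ΔωH ± ΔωC), where K
is the exchange matrix; every ¹³C 180° pulse swaps DQ↔ZQ (flips the
carbon-shift sign) and the mid-period ¹H 180° flips the proton-shift
sign. The number of pulses is the nearest integer to 2Tν, so modelled
profiles live on the experimentally attainable frequency grid
(ν = n/2T). Matrix exponentials use the closed 2×2 Putzer form; the
in-phase approximation ignores scalar-coupling evolution and
differential relaxation between sites (per-site R2 is a shared R2_0 per
profile).

The propagator reduces exactly to single-quantum Bloch-McConnell when
ΔωH = 0 and matches the Luz-Meiboom fast-exchange closed form within 1 %
for kex ≫ Δω (tested). Global fits share (kex, p_minor) across profiles
with per-profile Δω_C and R2_0, initialised by a coarse grid
kex ∈ {10², 10³, 10⁴} s⁻¹ × p_minor ∈ {0.01, 0.05, 0.15} with the
lowest-χ² start refined fully. τex = 1/kex (kex the sum of forward and
backward rates). Each temperature is fitted independently; ΔωH is fixed
at zero unless profiles state otherwise. All-flat profiles are flagged
unidentifiable rather than fitted silently.

## EXSY

The two-site longitudinal exchange solution (see README for the
eigenvalue form) is fitted simultaneously to all observed curves.
Degenerate eigenvalues (|λ1−λ2| < 10⁻⁸λ1) switch to the analytic t·e^-λt
limit. When the second cross peak is unobserved (overlap), setting
`constrain_iol` ties its amplitude to the observed one via
Io(0)·k_ol = Il(0)·k_lo — exact for a symmetric system and a first-order
approximation otherwise. Initial magnetizations are fitted, not fixed to
populations (long recycle delays equilibrate but scaling is unknown).
kex = k_lo + k_ol is reported alongside both directional rates, because
"exchange rate" in slow-exchange work sometimes denotes a directional
rate; the recovery benchmarks score the directional open→locked rate.
Rates converging below 10⁻⁴ s⁻¹ (under 0.01 % transfer over a 1 s mixing
range) are flagged as no exchange.

## Diffusion

The bipolar Stejskal-Tanner form is adopted with effective gradient
duration δeff = 2d and correction (Δ − δeff/3 − τ/2); defaults
d = 3.2 ms, Δ = 400 ms, τ = 0.1 ms. Absolute D values are
convention-dependent; the MW-calibration pathway is slope-ratio based
and insensitive to the constant. Gradient strengths may be arbitrary
units with a calibration factor (G/cm per unit) in the series.

Temperature normalisation applies D_corr = D·(η(T_obs)/η(T_ref))·
(T_ref/T_obs) to fitted D values (equivalent under the linear fit to
scaling intensities, and cleaner contractually). The bundled viscosity
tables (5-60 °C, 5 °C steps, linear interpolation) hold standard H2O
values and literature-typical D2O values; the exact D2O-buffer values
are approximate and the table is swappable package data. The MW
calibration is a log-log linear fit over ≥ 3 calibrants (the bundled
name/MW set spans GB1 at 6.2 kDa to a 360 kDa half-proteasome; D values
must be supplied, or a synthetic D = A·MW^(−1/3) set can be produced).
Oligomer fractions interpolate the fast-exchange-averaged D linearly
between two pure-state coefficients, clamped within a 5 % tolerance of
the bracket.

## Two-state thermal transition

The fit is parameterised internally as (ΔH, T_m) with ΔS = ΔH/T_m
derived — unit-safe (T_m in K) and numerically stable, since ΔH and ΔS
are almost perfectly correlated when fitted jointly. Probe intensities
are baseline + amplitude·p_open(T); the alternative normalisation to a
high-temperature reference is a special case (baseline 0, amplitude 1).
Temperatures are Kelvin throughout with °C reported additionally. The
model assumes exactly two states (no intermediates or unfolding in the
fitted range); the fitted ΔH/ΔS are equilibrium van't Hoff quantities of
the locked↔open transition, which the output metadata states explicitly.
Flat series are flagged unidentifiable. Four measured temperatures
under-determine the four-parameter-per-probe problem, so the synthetic
generator defaults to a denser 20-55 °C grid in 2.5 °C steps.

## Binding kinetics

Pseudo-first-order 1:1 Langmuir kinetics (k_obs = k_on·C + k_off) with
a 30 s association and 40 s dissociation window by default. Steady-state
responses are taken as the mean of the final 10 % of the association
phase when the curve has plateaued, else extrapolated from a
mono-exponential fit; the result is flagged either way. The steady-state
isotherm fit needs ≥ 4 concentrations bracketing K_d, the kinetic fit
≥ 3 sensorgrams; K_d values far outside the concentration range, and
dissociation windows too short to constrain k_off, are flagged.

## Synthetic data and validation scope

The generator draws per-point Gaussian noise with
σ_i = noise·√(I_i² + (0.1·I_max)²) — proportional noise with an additive
floor so weak signals are not unrealistically clean. CPMG profiles get
proportional noise on R2,eff directly, matching how dispersion
uncertainties are reported. Default ground-truth parameters are the
study conditions of the oligomer-transition system the package targets:
EXSY at 0.33 s⁻¹ with R1 = 1.5 s⁻¹ and mixing 50-1000 ms, dispersion at
τex = 2 ms with 5 % minor population and Δω_C of 0.5-2 ppm over five
probes, diffusion at 3.4×10⁻⁷ cm² s⁻¹, melts at ΔH = 241.7 kJ mol⁻¹
with a 36.8 °C midpoint, isotherms at K_d = 7.8 µM, and η set from
S²axis·τc = 3.0 ns.

What passing recovery shows: the fits are unbiased and correctly scaled
under the stated noise model on the stated grids. What it does not
show: robustness to real-spectrum pathologies — peak overlap, baseline
distortion, correlated noise, temperature miscalibration, convection in
diffusion data, mass-transport effects in BLI — none of which the
generator emulates.

The acceptance script uses 50 replicates for the fast fits (EXSY,
isotherm, η-ratio, thermal), 20 for diffusion and 10 for the global
dispersion fit; the dispersion count reflects that each global fit
propagates five profiles through the numerical propagator from nine grid
starts, and ten replicates already pin the mean to a few percent.

## Known limitations

- The MQ propagator's in-phase approximation omits scalar-coupling and
  differential-relaxation effects that matter for quantitative Δω_H
  extraction in real data.
- TRACT τc assumes a rigid rotor and a fixed 17° CSA/bond angle.
- The dispersion global fit assumes one shared exchange process; probes
  sensing different processes would need grouping by the caller.
- No multi-component diffusion: polydisperse mixtures outside fast
  exchange bias D toward the majority species.
- The EXSY model is strictly two-state; spin diffusion or a third state
  appear as rate biases, not detectable misfits at typical noise.
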