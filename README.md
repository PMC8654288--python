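# nmrdyn

Quantitative analysis of solution-NMR dynamics experiments for proteins
that switch oligomeric state — the kind of system exemplified by the
bacterial DegP protease, whose inactive hexamer dissociates into active
trimers as temperature rises, gated by an intermolecular lock between its
tandem PDZ domains.

The package turns plain tabular peak lists and intensity series into
fitted physical parameters across the full ladder of NMR timescales:

| Observable | Experiment | Fitted quantity |
|---|---|---|
| chemical-shift perturbations | titration HSQC/TROSY | Δδ per residue, significance map |
| R1, R1ρ, hetNOE, TRACT | backbone ¹⁵N relaxation | rates, R2(R1ρ), τc |
| SQ/TQ intensity ratios | methyl cross-correlated relaxation | η, S²axis·τc |
| R2,eff(νCPMG) | MQ-CPMG relaxation dispersion | kex, p_minor, Δω (global) |
| EXSY build-up curves | magnetization exchange | k_lo, k_ol, kex (s⁻¹ exchange) |
| gradient attenuation | BPP-LED diffusion | D, oligomer fraction, apparent MW |
| intensity vs temperature | two-state thermal transition | ΔH, ΔS, T_m, populations |
| BLI sensorgrams/isotherms | 1:1 binding | K_d, k_on, k_off |

Every fit carries seeded Monte-Carlo errors, and a synthetic-data module
generates each input type from its forward model at known ground truth,
so the whole pipeline is validated by parameter recovery.

## Core models

**CSPs** — amide Δδ(HN) = √(Δδ¹H² + (Δδ¹⁵N/5)²), methyl
Δδ(HC) = √(Δδ¹H² + (Δδ¹³C/4)²), significant at ≥ 0.05 ppm by default.

**R2 from R1ρ** — R2 = R1ρ/sin²θ − R1/tan²θ with tilt θ = arctan(ω/Ω);
a 2 kHz spin lock averages out exchange slower than 1/(2π·2000 Hz) ≈ 80 µs.

**Methyl order parameters** — intensity ratios follow
|Ia/Ib| = ¾·η·tanh(√(η²+δ²)·T)/(√(η²+δ²) − δ·tanh(√(η²+δ²)·T)), and
η ≈ (9/10)(μ0/4π)²[P2(cos Θaxis,HH)]²·S²axis·γH⁴·ħ²·τc/r_HH⁶
with r_HH = 1.813 Å and Θaxis,HH = 90°, giving S²axis·τc directly.

**MQ-CPMG** — R2,eff = −(1/T)·ln(I/I0) profiles are fitted with a
numerical two-site propagator: DQ/ZQ coherence vectors evolve under 2×2
complex Bloch-McConnell generators between refocusing pulses, alternating
coherence order at every ¹³C 180° pulse. Global fits share kex and
p_minor across methyl probes and report τex = 1/kex.

**EXSY** — auto/cross peak intensities follow the two-site longitudinal
exchange solution with eigenvalues
λ1,2 = [(xl+xo) ± √((xl−xo)² + 4 k_lo k_ol)]/2, xl = R1l + k_lo,
xo = R1o + k_ol; all curves are fitted simultaneously.

**Diffusion** — ln I is linear in g² with slope −D·γH²·δeff²·(Δ − δeff/3
− τ/2) (bipolar pairs, δeff = 2d); D values are normalised across
temperature via Stokes-Einstein with bundled D2O/H2O viscosity tables and
mapped to oligomer size through a log-log MW calibration.

**Two-state transition** — p_open(T) = K/(1+K) with
K = exp(−(ΔH − TΔS)/RT); probe intensities are baseline + amplitude ×
p_open(T), fitted globally with shared (ΔH, T_m) and ΔS = ΔH/T_m.

## Worked example

Generate a synthetic magnetization-exchange dataset for a probe hopping
between a locked and an open conformation at 0.33 s⁻¹ (2 % intensity
noise), then fit it:

```python
from nmrdyn import exsy, synthesize as syn
from nmrdyn.series import MonteCarloSpec

dataset, manifest = syn.generate(
    syn.GeneratorSpec("exsy", seed=42, noise=0.02))
fit = exsy.fit_exsy(dataset, MonteCarloSpec(seed=1, replicates=200))
print(f"k_ol = {fit.k_ol:.3f} +/- {fit.k_ol_err:.3f} 1/s")
print(f"k_ex = {fit.k_ex:.3f} +/- {fit.k_ex_err:.3f} 1/s")
```

prints

```
k_ol = 0.336 +/- 0.040 1/s
k_ex = 0.667 +/- 0.080 1/s
```

— the open→locked rate is recovered within its Monte-Carlo error
(generated at 0.33 s⁻¹), and kex = k_lo + k_ol is reported alongside the
directional rates. The same pattern works for every experiment kind; for
example a two-probe thermal melt generated at ΔH = 241.7 kJ mol⁻¹ with a
36.8 °C midpoint fits to `dH = 240.0 +/- 3.5 kJ/mol, Tm = 36.9 C`.

The same functionality is exposed on the command line:

```sh
nmrdyn synth --kind exsy --seed 42 --out /tmp/exsy
nmrdyn exsy --input /tmp/exsy.tsv
nmrdyn run --out bundle.json        # full synthetic round trip
```

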