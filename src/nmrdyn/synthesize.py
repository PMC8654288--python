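"""Synthetic-data generation with controlled ground truth.

Every input type consumed by the analysis modules can be generated from
its forward model at stated ground-truth parameters, with a seeded noise
model standing in for spectral noise: per-point Gaussian with

    σ_i = noise · sqrt(I_i² + (0.1·I_max)²)

i.e. proportional noise with an additive floor so weak peaks are not
noise-free.  CPMG profiles are the exception — there the noise is applied
directly to R2,eff (proportional), matching how dispersion uncertainties
are quoted.  Each generator returns the data object expected by the
corresponding fit function plus a manifest recording the generating
parameters, so recovery can be scored.

Default grids and parameters mirror the study conditions: η-ratio delays
2-24 ms (8 values), CT period 30 ms with νCPMG 67-1000 Hz, EXSY mixing
times 50-1000 ms, BPP-LED timings d = 3.2 ms / Δ = 400 ms / τ = 0.1 ms,
a 20-55 °C thermal grid in 2.5 °C steps (denser than a typical measured
set, which under-determines the two-state fit), and a 2-fold BLI dilution
series from 1 to 64 µM.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np
import pandas as pd

from nmrdyn import methyl as _methyl
from nmrdyn.binding import Sensorgram, model_sensorgram
from nmrdyn.diffusion import GradientSeries, stejskal_tanner_b
from nmrdyn.errors import ValidationError
from nmrdyn.exsy import ExsyDataset, exsy_model
from nmrdyn.peaks import AcquisitionContext, PeakRecord, PeakTable
from nmrdyn.series import IntensitySeries
from nmrdyn.thermo import two_state_population

KINDS = ("relaxation_decay", "eta_ratio", "cpmg", "exsy", "gradient",
         "thermal", "sensorgram", "isotherm", "peak_table_pair")


@dataclass
class GeneratorSpec:
    """Ground truth, noise level and grid for one synthetic experiment."""

    kind: str
    seed: int
    noise: float = 0.02
    params: dict[str, Any] = dc_field(default_factory=dict)
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(
                f"unknown experiment kind '{self.kind}'; one of {KINDS}")
        if self.noise < 0:
            raise ValidationError("noise must be >= 0")


def _noisy(values: np.ndarray, noise: float,
           rng: np.random.Generator) -> np.ndarray:
    if noise == 0.0:
        return values.copy()
    floor = 0.1 * np.max(np.abs(values))
    sigma = noise * np.sqrt(values ** 2 + floor ** 2)
    return values + rng.normal(0.0, sigma)


def _sigmas(values: np.ndarray, noise: float) -> np.ndarray:
    floor = 0.1 * np.max(np.abs(values))
    return noise * np.sqrt(values ** 2 + floor ** 2)


def generate(spec: GeneratorSpec) -> tuple[Any, dict]:
    """Generate the input data for ``spec.kind`` plus a ground-truth manifest.

    Deterministic for a given seed; with ``noise=0`` the output lies
    exactly on the forward model.
    """
    rng = np.random.default_rng(spec.seed)
    maker = {
        "relaxation_decay": _gen_relaxation_decay,
        "eta_ratio": _gen_eta_ratio,
        "cpmg": _gen_cpmg,
        "exsy": _gen_exsy,
        "gradient": _gen_gradient,
        "thermal": _gen_thermal,
        "sensorgram": _gen_sensorgram,
        "isotherm": _gen_isotherm,
        "peak_table_pair": _gen_peak_table_pair,
    }[spec.kind]
    data, truth = maker(spec, rng)
    manifest = {"kind": spec.kind, "seed": spec.seed, "noise": spec.noise,
                "truth": truth}
    return data, manifest


# ---------------------------------------------------------------------------
# Per-kind generators
# ---------------------------------------------------------------------------

def _gen_relaxation_decay(spec, rng):
    p = {"rate": 1.82, "i0": 1.0, **spec.params}
    t = spec.grid if spec.grid is not None else np.linspace(0.02, 1.2, 8)
    clean = p["i0"] * np.exp(-p["rate"] * np.asarray(t, dtype=float))
    noisy = _noisy(clean, spec.noise, rng)
    series = IntensitySeries("decay", t, noisy,
                             _sigmas(clean, spec.noise) if spec.noise else
                             np.zeros_like(clean), x_label="delay_s")
    return series, p


def _gen_eta_ratio(spec, rng):
    p = {"s2_tauc_ns": 3.0, "delta": 1.0, **spec.params}
    eta = p.get("eta", _methyl.eta_from_s2tauc(p["s2_tauc_ns"]))
    p["eta"] = eta
    t = spec.grid if spec.grid is not None else _methyl.DEFAULT_ETA_DELAYS
    clean = _methyl.eta_ratio_model(eta, p["delta"], t)
    noisy = _noisy(clean, spec.noise, rng)
    series = IntensitySeries("methyl", t, noisy,
                             _sigmas(clean, spec.noise) if spec.noise else
                             np.zeros_like(clean), x_label="delay_s")
    return series, p


def _default_nu_grid(ct_period: float) -> np.ndarray:
    # attainable frequencies n/(2T) spanning 67-1000 Hz for T = 30 ms
    counts = np.array([4, 6, 8, 10, 14, 18, 24, 30, 40, 50, 60])
    return counts / (2.0 * ct_period)


def _gen_cpmg(spec, rng):
    p = {"tau_ex_ms": 2.0, "p_minor": 0.05, "r2_0": 15.0,
         "field_1h_mhz": 800.0, "ct_period": _methyl.DEFAULT_CT_PERIOD,
         "n_probes": 5, "dw_c_range_ppm": (0.5, 2.0), **spec.params}
    kex = 1000.0 / p["tau_ex_ms"]
    nu = spec.grid if spec.grid is not None \
        else _default_nu_grid(p["ct_period"])
    dws = np.linspace(*p["dw_c_range_ppm"], p["n_probes"])
    profiles = []
    for i, dw in enumerate(dws):
        pars = _methyl.TwoSiteExchangeParams(
            p_minor=p["p_minor"], k_ex=kex, dw_c_ppm=float(dw),
            r2_0=p["r2_0"])
        clean = _methyl.mq_dispersion_forward(pars, nu, p["field_1h_mhz"],
                                              p["ct_period"])
        sigma = spec.noise * np.abs(clean)
        noisy = clean + rng.normal(0.0, sigma) if spec.noise else clean
        profiles.append(_methyl.DispersionProfile(
            methyl_id=f"methyl_{i + 1}", nu_cpmg=nu, r2eff=noisy,
            error=sigma if spec.noise else None,
            ct_period=p["ct_period"], field_1h_mhz=p["field_1h_mhz"]))
    p["k_ex"] = kex
    p["dw_c_ppm"] = [float(d) for d in dws]
    return profiles, p


def _gen_exsy(spec, rng):
    p = {"k_lo": 0.33, "k_ol": 0.33, "r1_l": 1.5, "r1_o": 1.5,
         "i_l0": 1.0, "i_o0": 1.0, **spec.params}
    t = spec.grid if spec.grid is not None else np.linspace(0.05, 1.0, 8)
    i_ll, i_oo, i_lo, _ = exsy_model(p["k_lo"], p["k_ol"], p["r1_l"],
                                     p["r1_o"], p["i_l0"], p["i_o0"], t)
    scale = max(float(np.max(i_ll)), float(np.max(i_oo)))
    sigma = spec.noise * scale
    dataset = ExsyDataset(
        mixing_times=t,
        i_ll=i_ll + rng.normal(0, sigma, len(t)) if spec.noise else i_ll,
        i_oo=i_oo + rng.normal(0, sigma, len(t)) if spec.noise else i_oo,
        i_lo=i_lo + rng.normal(0, sigma, len(t)) if spec.noise else i_lo,
        error=sigma if spec.noise else None,
    )
    p["k_ex"] = p["k_lo"] + p["k_ol"]
    return dataset, p


def _gen_gradient(spec, rng):
    p = {"d_cm2_s": 3.4e-7, "i0": 1.0, "gradient_duration_ms": 3.2,
         "diffusion_delay_ms": 400.0, "tau_ms": 0.1,
         "temperature": 298.15, **spec.params}
    g = spec.grid if spec.grid is not None else np.linspace(2.0, 32.0, 12)
    series = GradientSeries(
        gradients=np.asarray(g, dtype=float),
        intensity=np.ones_like(np.asarray(g, dtype=float)),
        gradient_duration_ms=p["gradient_duration_ms"],
        diffusion_delay_ms=p["diffusion_delay_ms"], tau_ms=p["tau_ms"],
        temperature=p["temperature"])
    clean = p["i0"] * np.exp(-stejskal_tanner_b(series) * p["d_cm2_s"])
    series.intensity = _noisy(clean, spec.noise, rng)
    return series, p


def _gen_thermal(spec, rng):
    p = {"delta_h_kj": 241.7, "tm_c": 36.8,
         "probes": {"I310d1": (1.0, 0.0), "I408d1": (0.9, 0.05)},
         **spec.params}
    tm_k = p["tm_c"] + 273.15
    ds = p["delta_h_kj"] / tm_k
    t_c = spec.grid if spec.grid is not None else np.arange(20.0, 55.1, 2.5)
    t_k = np.asarray(t_c, dtype=float) + 273.15
    p_open = two_state_population(t_k, p["delta_h_kj"], ds)
    out = []
    for probe, (amp, base) in p["probes"].items():
        clean = base + amp * p_open
        out.append(IntensitySeries(
            probe, t_k, _noisy(clean, spec.noise, rng),
            _sigmas(clean, spec.noise) if spec.noise else
            np.zeros_like(clean), x_label="temperature_K"))
    p["delta_s_kj_per_k"] = ds
    p["tm_k"] = tm_k
    return out, p


_DEFAULT_CONCS = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0])


def _gen_sensorgram(spec, rng):
    p = {"k_on": 0.1, "k_off": 0.78, "r_max": 1.0, "assoc_end": 30.0,
         "dissoc_end": 40.0, "dt": 0.1, **spec.params}
    concs = spec.grid if spec.grid is not None else _DEFAULT_CONCS
    t = np.arange(0.0, p["dissoc_end"] + p["dt"] / 2, p["dt"])[1:]
    out = []
    for c in np.asarray(concs, dtype=float):
        clean = model_sensorgram(p["k_on"], p["k_off"], p["r_max"], c, t,
                                 p["assoc_end"])
        noisy = clean + rng.normal(0, spec.noise * p["r_max"], len(t)) \
            if spec.noise else clean
        out.append(Sensorgram(c, t, noisy, p["assoc_end"],
                              p["dissoc_end"]))
    p["k_d"] = p["k_off"] / p["k_on"]
    return out, p


def _gen_isotherm(spec, rng):
    p = {"k_d": 7.8, "r_max": 1.0, **spec.params}
    concs = np.asarray(spec.grid if spec.grid is not None
                       else _DEFAULT_CONCS, dtype=float)
    clean = p["r_max"] * concs / (p["k_d"] + concs)
    noisy = clean + rng.normal(0, spec.noise * np.abs(clean)) \
        if spec.noise else clean
    return (concs, noisy), p


def _gen_peak_table_pair(spec, rng):
    p = {"n_residues": 10, "perturbed": {3: (0.08, 0.3), 7: (0.02, 0.5)},
         **spec.params}
    ctx = AcquisitionContext(temperature=298.15, scans=4,
                             pulse90_length=9.0)
    ref_records, new_records = [], []
    for i in range(1, p["n_residues"] + 1):
        h = 8.0 + rng.uniform(-1.0, 1.0)
        n = 115.0 + rng.uniform(-10.0, 10.0)
        ref_records.append(PeakRecord(i, "A", "HN", {"1H": h, "15N": n},
                                      1.0, 0.01))
        dh, dn = p["perturbed"].get(i, (0.0, 0.0))
        new_records.append(PeakRecord(i, "A", "HN",
                                      {"1H": h + dh, "15N": n + dn},
                                      1.0, 0.01))
    return (PeakTable(ref_records, ctx), PeakTable(new_records, ctx)), p


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def recovery_report(truth: dict[str, float],
                    estimates: list[dict[str, tuple[float, float]]]
                    ) -> pd.DataFrame:
    """Per-parameter bias, RMSE and 1σ error-bar coverage over replicates.

    ``estimates`` holds one dict per replicate mapping parameter name to
    (value, error).  Coverage is the fraction of replicates whose 1σ
    interval contains the truth.
    """
    if not estimates:
        raise ValidationError("empty estimate set")
    rows = []
    for name, true_val in truth.items():
        vals, errs = [], []
        for est in estimates:
            if name not in est:
                raise ValidationError(f"estimate missing parameter '{name}'")
            v, e = est[name]
            vals.append(v)
            errs.append(e)
        vals = np.asarray(vals, dtype=float)
        errs = np.asarray(errs, dtype=float)
        bias = float(np.mean(vals) - true_val)
        rmse = float(np.sqrt(np.mean((vals - true_val) ** 2)))
        covered = np.abs(vals - true_val) <= errs
        rows.append({"parameter": name, "truth": true_val,
                     "mean": float(np.mean(vals)), "bias": bias,
                     "rmse": rmse, "coverage": float(np.mean(covered)),
                     "n": len(vals)})
    return pd.DataFrame(rows).set_index("parameter")
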