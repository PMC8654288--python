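"""Methyl side-chain dynamics: order parameters and MQ-CPMG dispersion.

Fast-timescale amplitudes
-------------------------
The intra-methyl ¹H-¹H cross-correlated relaxation rate η is extracted
from the build-up of single/triple-quantum intensity ratios

    |Ia/Ib| = (3/4)·η·tanh(√(η²+δ²)·T) / (√(η²+δ²) − δ·tanh(√(η²+δ²)·T))

where T is the relaxation delay and δ absorbs coupling to external
protons.  η is proportional to the product of the squared order parameter
of the methyl three-fold axis and the overall tumbling time:

    η ≈ (9/10)·(μ0/4π)²·[P2(cos Θaxis,HH)]²·S²axis·γH⁴·ħ²·τc / rHH⁶

with rHH = 1.813 Å and Θaxis,HH = 90°, so S²axis·τc = η / k_methyl with a
constant computed from CODATA values.

Millisecond exchange
--------------------
Multiple-quantum CPMG relaxation dispersion is modelled by numerical
propagation of the DQ/ZQ coherences of a two-site exchanging system
through the CPMG pulse train (2×2 complex Bloch-McConnell generators per
coherence order, closed-form matrix exponentials), with

    R2,eff = −(1/T)·ln(I/I0),    νCPMG = 1/(2δ)

for a constant-time relaxation period T (default 30 ms).  Global fits
share the exchange rate kex and minor population across methyl probes and
report the exchange time constant τex = 1/kex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from nmrdyn import constants as k
from nmrdyn.errors import FitError, ValidationError
from nmrdyn.series import IntensitySeries, MonteCarloSpec

#: γ(13C)/γ(1H) ratio used to convert the spectrometer 1H frequency.
GAMMA_C_OVER_H = 0.251449530

#: Default constant-time relaxation period of the MQ-CPMG experiment [s].
DEFAULT_CT_PERIOD = 0.030

#: Default delay grid of the SQ/TQ ratio experiment [s] (eight values, 2-24 ms).
DEFAULT_ETA_DELAYS = np.linspace(0.002, 0.024, 8)


def methyl_eta_constant() -> float:
    """k_methyl [s⁻²] with η = k_methyl · (S²axis·τc); CODATA constants."""
    p2hh = k.p2(math.cos(math.radians(k.THETA_AXIS_HH_DEG)))
    return (0.9 * k.MU0_OVER_4PI ** 2 * p2hh ** 2 * k.GAMMA_H ** 4
            * k.HBAR ** 2 / k.R_HH_METHYL ** 6)


# ---------------------------------------------------------------------------
# SQ/TQ ratio model and fitting
# ---------------------------------------------------------------------------

def eta_ratio_model(eta: float, delta: float, t_delay) -> np.ndarray:
    """Intensity ratio |Ia/Ib| of the cross-correlation build-up at delay T."""
    if np.any(np.asarray(eta) < 0):
        raise ValidationError("eta must be >= 0")
    t = np.asarray(t_delay, dtype=float)
    root = math.sqrt(eta * eta + delta * delta)
    if root == 0.0:
        return np.zeros_like(t)
    th = np.tanh(root * t)
    return 0.75 * eta * th / (root - delta * th)


@dataclass
class MethylEtaFit:
    """Fitted cross-correlated rate and derived order-parameter product."""

    methyl_id: str
    eta: float
    eta_err: float
    delta: float
    delta_err: float
    s2_tauc_ns: float
    s2_tauc_ns_err: float
    s2_axis: float | None = None
    identifiable: bool = True


def fit_eta(series: IntensitySeries, mc: MonteCarloSpec | None = None,
            tauc_ns: float | None = None) -> MethylEtaFit:
    """Fit (η, δ) to an intensity-ratio build-up and derive S²axis·τc.

    Requires at least four delay points.  When the ratios never rise above
    noise the fit is flagged unidentifiable.  ``tauc_ns`` additionally
    converts the product to S²axis.
    """
    if len(series) < 4:
        raise FitError("eta fit requires >= 4 relaxation delays")
    t, r = series.x, series.intensity
    noise_floor = (np.max(series.error) if series.error is not None
                   and series.error.size else 0.0)
    identifiable = bool(np.max(np.abs(r)) > max(3.0 * noise_floor, 1e-3))

    def model(tt, eta, delta):
        return eta_ratio_model(eta, delta, tt)

    p0 = (max(np.max(r), 0.01) / 0.75 / max(np.max(t), 1e-3), 1.0)
    popt, _ = curve_fit(model, t, r, p0=p0,
                        bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000)
    eta_hat, delta_hat = map(float, popt)

    eta_err = delta_err = 0.0
    if mc is not None:
        rng = mc.rng()
        fitted = model(t, *popt)
        sigma = (series.error if series.error is not None
                 and np.any(series.error > 0)
                 else np.full(len(t), float(np.std(r - fitted)) or 1e-4))
        etas = np.empty(mc.replicates)
        deltas = np.empty(mc.replicates)
        for i in range(mc.replicates):
            rep = fitted + rng.normal(0.0, sigma)
            try:
                p_rep, _ = curve_fit(model, t, np.clip(rep, 0, None), p0=popt,
                                     bounds=([0, 0], [np.inf, np.inf]),
                                     maxfev=20000)
                etas[i], deltas[i] = p_rep
            except RuntimeError:
                etas[i] = deltas[i] = np.nan
        eta_err = float(np.nanstd(etas, ddof=1))
        delta_err = float(np.nanstd(deltas, ddof=1))

    s2tauc, s2tauc_err = s2tauc_from_eta(eta_hat, eta_err)
    s2 = None
    if tauc_ns is not None:
        if tauc_ns <= 0:
            raise ValidationError("tauc must be > 0")
        s2 = s2tauc / tauc_ns
    return MethylEtaFit(series.probe_id, eta_hat, eta_err, delta_hat,
                        delta_err, s2tauc, s2tauc_err, s2, identifiable)


def s2tauc_from_eta(eta: float, eta_err: float = 0.0) -> tuple[float, float]:
    """Convert η (s⁻¹) to the order-parameter product S²axis·τc in ns."""
    if eta < 0:
        raise ValidationError("eta must be >= 0")
    k_methyl = methyl_eta_constant()
    return eta / k_methyl * 1e9, eta_err / k_methyl * 1e9


def eta_from_s2tauc(s2_tauc_ns: float) -> float:
    """Inverse of :func:`s2tauc_from_eta` (forward model for generators)."""
    return s2_tauc_ns * 1e-9 * methyl_eta_constant()


# ---------------------------------------------------------------------------
# MQ-CPMG dispersion
# ---------------------------------------------------------------------------

def r2eff_from_intensities(intensity, intensity_ref, ct_period: float
                           = DEFAULT_CT_PERIOD) -> np.ndarray:
    """R2,eff = −(1/T)·ln(I/I0) for a constant-time period T."""
    i = np.asarray(intensity, dtype=float)
    i0 = np.asarray(intensity_ref, dtype=float)
    if ct_period <= 0:
        raise ValidationError("constant-time period must be > 0")
    if np.any(i <= 0) or np.any(i0 <= 0):
        raise ValidationError("intensities must be positive")
    return -np.log(i / i0) / ct_period


@dataclass(frozen=True)
class TwoSiteExchangeParams:
    """Two-site exchange parameters of one dispersion profile.

    kex = k_forward + k_backward is the total exchange rate; p_minor the
    population of the sparsely populated state; Δω the chemical-shift
    differences between states.
    """

    p_minor: float
    k_ex: float
    dw_c_ppm: float
    dw_h_ppm: float = 0.0
    r2_0: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_minor < 0.5):
            raise ValidationError("p_minor must be in [0, 0.5)")
        if self.k_ex <= 0:
            raise ValidationError("k_ex must be > 0")

    @property
    def tau_ex_ms(self) -> float:
        return 1000.0 / self.k_ex


@dataclass
class DispersionProfile:
    """Measured or simulated R2,eff dispersion profile of one methyl."""

    methyl_id: str
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    error: np.ndarray | None = None
    temperature: float = 310.15
    ct_period: float = DEFAULT_CT_PERIOD
    field_1h_mhz: float = 800.0

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        if self.nu_cpmg.shape != self.r2eff.shape:
            raise ValidationError("nu grid and R2eff must match in length")
        if not np.all(np.isfinite(self.r2eff)):
            raise ValidationError("R2eff values must be finite")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)


def _expm2(m: np.ndarray) -> np.ndarray:
    """Closed-form exponential of a 2×2 complex matrix (Putzer form)."""
    tr = m[0, 0] + m[1, 1]
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    disc = np.sqrt(tr * tr - 4.0 * det + 0j)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    e1, e2 = np.exp(l1), np.exp(l2)
    eye = np.eye(2, dtype=complex)
    if abs(l1 - l2) < 1e-12 * max(abs(l1), 1.0):
        return e1 * (eye + (m - l1 * eye))
    return e1 * eye + (e2 - e1) / (l2 - l1) * (m - l1 * eye)


def mq_dispersion_forward(params: TwoSiteExchangeParams, nu_grid,
                          field_1h_mhz: float = 800.0,
                          ct_period: float = DEFAULT_CT_PERIOD) -> np.ndarray:
    """R2,eff(νCPMG) for two-site exchange of a multiple-quantum coherence.

    The coherence starts as DQ at the major-site equilibrium, alternates
    DQ↔ZQ at every ¹³C 180° pulse, and the sign of the ¹H shift difference
    flips at the mid-point ¹H refocusing pulse.  The number of pulses per
    CT period is the nearest integer to 2·T·ν, so the returned profile
    corresponds to the experimentally attainable frequency grid.
    """
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(nu <= 0):
        raise ValidationError("CPMG frequencies must be > 0")
    pb = params.p_minor
    pa = 1.0 - pb
    if pb == 0.0 or (params.dw_c_ppm == 0.0 and params.dw_h_ppm == 0.0):
        return np.full(nu.shape, params.r2_0)

    kab = params.k_ex * pb
    kba = params.k_ex * pa
    dw_c = 2.0 * math.pi * field_1h_mhz * GAMMA_C_OVER_H * params.dw_c_ppm
    dw_h = 2.0 * math.pi * field_1h_mhz * params.dw_h_ppm
    kmat = np.array([[-kab, kba], [kab, -kba]], dtype=complex)
    r2 = params.r2_0 * np.eye(2, dtype=complex)

    def generator(h_sign: float, c_sign: float) -> np.ndarray:
        shift = np.zeros((2, 2), dtype=complex)
        shift[1, 1] = 1j * (h_sign * dw_h + c_sign * dw_c)
        return kmat - r2 + shift

    v0 = np.array([pa, pb], dtype=complex)
    out = np.empty(nu.shape)
    for idx, nu_i in enumerate(nu):
        n = max(1, round(2.0 * ct_period * nu_i))
        tau = ct_period / n  # inter-pulse spacing; actual nu = n/(2T)
        # interval exponentials, keyed by (h_sign, c_sign, full/half)
        cache: dict[tuple[float, float, bool], np.ndarray] = {}

        def propagate(v, dur, h_sign, c_sign):
            full = abs(dur - tau) < 1e-15
            key = (h_sign, c_sign, full)
            mat = cache.get(key)
            if mat is None or not (full or abs(dur - 0.5 * tau) < 1e-15):
                mat = _expm2(generator(h_sign, c_sign) * dur)
                if full or abs(dur - 0.5 * tau) < 1e-15:
                    cache[key] = mat
            return mat @ v

        v = v0.copy()
        t_cursor = 0.0
        c_sign = 1.0  # DQ first
        # n pulses => n+1 intervals: tau/2, tau, ..., tau, tau/2
        durations = [0.5 * tau] + [tau] * (n - 1) + [0.5 * tau]
        for dur in durations:
            t_end = t_cursor + dur
            if dw_h != 0.0 and t_cursor < 0.5 * ct_period < t_end:
                first = 0.5 * ct_period - t_cursor
                v = propagate(v, first, 1.0, c_sign)
                v = propagate(v, dur - first, -1.0, c_sign)
            else:
                h_sign = 1.0 if t_end <= 0.5 * ct_period + 1e-15 else -1.0
                v = propagate(v, dur, h_sign, c_sign)
            t_cursor = t_end
            c_sign = -c_sign  # 13C 180° pulse: DQ <-> ZQ
        intensity = v[0].real
        if intensity <= 0:
            intensity = 1e-16
        out[idx] = -math.log(intensity / pa) / ct_period
    return out


def luz_meiboom_r2eff(params: TwoSiteExchangeParams, nu_grid,
                      field_1h_mhz: float = 800.0) -> np.ndarray:
    """Fast-exchange closed form (single effective shift difference).

    R2eff = R2_0 + pA·pB·Δω²/kex · [1 − (4ν/kex)·tanh(kex/(4ν))], valid for
    kex ≫ Δω; used as an independent cross-check of the propagator.
    """
    nu = np.asarray(nu_grid, dtype=float)
    dw = 2.0 * math.pi * field_1h_mhz * (
        GAMMA_C_OVER_H * params.dw_c_ppm + params.dw_h_ppm)
    pa, pb = 1.0 - params.p_minor, params.p_minor
    kex = params.k_ex
    phi = pa * pb * dw * dw
    return params.r2_0 + phi / kex * (
        1.0 - (4.0 * nu / kex) * np.tanh(kex / (4.0 * nu)))


@dataclass
class DispersionGlobalFit:
    """Global two-site fit over a set of dispersion profiles."""

    k_ex: float
    k_ex_err: float
    p_minor: float
    p_minor_err: float
    dw_c_ppm: dict[str, float]
    r2_0: dict[str, float]
    tau_ex_ms: float
    tau_ex_ms_err: float
    chi2: float
    identifiable: bool = True


_GRID_KEX = (1e2, 1e3, 1e4)
_GRID_PMINOR = (0.01, 0.05, 0.15)


def fit_dispersion_global(profiles: list[DispersionProfile],
                          mc: MonteCarloSpec | None = None
                          ) -> DispersionGlobalFit:
    """Globally fit shared (kex, p_minor) with per-profile Δω_C and R2_0.

    Initialisation is a coarse grid over kex × p_minor followed by local
    refinement of the best start (lowest χ²).  Profiles whose dispersion
    amplitude never exceeds the noise are flagged unidentifiable.
    """
    if len(profiles) < 1:
        raise FitError("at least one dispersion profile required")
    amplitudes = [float(np.ptp(p.r2eff)) for p in profiles]
    noise = max(
        (float(np.median(p.error)) for p in profiles if p.error is not None
         and p.error.size), default=0.0,
    )
    identifiable = any(a > max(3.0 * noise, 0.5) for a in amplitudes)

    n_prof = len(profiles)

    def unpack(x):
        kex = 10.0 ** x[0]
        pmin = x[1]
        dws = x[2:2 + n_prof]
        r20s = x[2 + n_prof:]
        return kex, pmin, dws, r20s

    def residuals(x):
        kex, pmin, dws, r20s = unpack(x)
        res = []
        for p, dw, r20 in zip(profiles, dws, r20s):
            pars = TwoSiteExchangeParams(p_minor=pmin, k_ex=kex,
                                         dw_c_ppm=dw, r2_0=r20)
            model = mq_dispersion_forward(pars, p.nu_cpmg, p.field_1h_mhz,
                                          p.ct_period)
            w = p.error if p.error is not None and np.all(p.error > 0) \
                else np.ones_like(model)
            res.append((model - p.r2eff) / w)
        return np.concatenate(res)

    lb = [0.0, 1e-4] + [0.0] * n_prof + [0.0] * n_prof
    ub = [6.0, 0.499] + [20.0] * n_prof + [200.0] * n_prof

    best = None
    for kex0 in _GRID_KEX:
        for p0 in _GRID_PMINOR:
            x0 = ([math.log10(kex0), p0]
                  + [1.0] * n_prof
                  + [max(float(np.min(p.r2eff)), 0.1) for p in profiles])
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub),
                                    max_nfev=60)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitError("global dispersion fit failed from every start")
    sol = least_squares(residuals, best.x, bounds=(lb, ub), max_nfev=400)

    kex, pmin, dws, r20s = unpack(sol.x)
    chi2 = float(2.0 * sol.cost)

    kex_err = p_err = tau_err = 0.0
    if mc is not None:
        rng = mc.rng()
        kexs = np.empty(mc.replicates)
        pms = np.empty(mc.replicates)
        base_models = []
        for p, dw, r20 in zip(profiles, dws, r20s):
            pars = TwoSiteExchangeParams(pmin, kex, dw, 0.0, r20)
            base_models.append(mq_dispersion_forward(
                pars, p.nu_cpmg, p.field_1h_mhz, p.ct_period))
        originals = [p.r2eff for p in profiles]
        for i in range(mc.replicates):
            for p, model in zip(profiles, base_models):
                sigma = (p.error if p.error is not None
                         and np.all(p.error > 0)
                         else 0.02 * np.abs(model))
                p.r2eff = model + rng.normal(0.0, sigma)
            try:
                rep = least_squares(residuals, sol.x, bounds=(lb, ub),
                                    max_nfev=200)
                kexs[i] = 10.0 ** rep.x[0]
                pms[i] = rep.x[1]
            except Exception:
                kexs[i] = pms[i] = np.nan
        for p, orig in zip(profiles, originals):
            p.r2eff = orig
        kex_err = float(np.nanstd(kexs, ddof=1))
        p_err = float(np.nanstd(pms, ddof=1))
        tau_err = float(np.nanstd(1000.0 / kexs, ddof=1))

    return DispersionGlobalFit(
        k_ex=kex, k_ex_err=kex_err, p_minor=pmin, p_minor_err=p_err,
        dw_c_ppm={p.methyl_id: float(d) for p, d in zip(profiles, dws)},
        r2_0={p.methyl_id: float(r) for p, r in zip(profiles, r20s)},
        tau_ex_ms=1000.0 / kex, tau_ex_ms_err=tau_err, chi2=chi2,
        identifiable=identifiable,
    )
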