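"""Backbone ¹⁵N relaxation analysis.

Covers exponential fitting of R1/R1ρ decay series with Monte-Carlo errors,
the off-resonance correction turning R1ρ into R2, rotational correlation
times from TRACT (the difference between the slowly and rapidly relaxing
¹⁵N doublet components), steady-state hetNOE error propagation, and the
R1·R2β product used to separate exchange broadening from anisotropic
tumbling.

The off-resonance correction is

    R2 = R1ρ / sin²θ − R1 / tan²θ,   θ = arctan(ω / Ω)

with spin-lock field strength ω and resonance offset Ω (θ = 90° on
resonance).  A 2 kHz spin lock averages out exchange contributions slower
than 1/(2π·2000 Hz) ≈ 80 µs; :func:`spin_lock_timescale_ceiling` reports
that ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from nmrdyn import constants as k
from nmrdyn.errors import FitError, ValidationError
from nmrdyn.series import IntensitySeries, MonteCarloSpec


@dataclass(frozen=True)
class RotatingFrameParams:
    """Spin-lock field and offset defining the effective-field tilt angle."""

    spin_lock_hz: float
    offset_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.spin_lock_hz <= 0:
            raise ValidationError("spin-lock field strength must be > 0")

    @property
    def tilt_angle(self) -> float:
        """Tilt angle θ = arctan(ω/Ω) in radians, π/2 on resonance."""
        if self.offset_hz == 0.0:
            return math.pi / 2.0
        return math.atan2(self.spin_lock_hz, self.offset_hz)


@dataclass
class RelaxationRecord:
    """Per-residue backbone relaxation observables (all rates in s⁻¹)."""

    residue_number: int
    r1: float | None = None
    r1_err: float = 0.0
    r1rho: float | None = None
    r1rho_err: float = 0.0
    r2_from_r1rho: float | None = None
    r2_from_r1rho_err: float = 0.0
    r2_alpha: float | None = None
    r2_alpha_err: float = 0.0
    r2_beta: float | None = None
    r2_beta_err: float = 0.0
    hetnoe: float | None = None
    hetnoe_err: float = 0.0


# ---------------------------------------------------------------------------
# Exponential decay fitting
# ---------------------------------------------------------------------------

def _mono_exp(t, i0, rate):
    return i0 * np.exp(-rate * t)


def fit_exponential_decay(
    series: IntensitySeries,
    mc: MonteCarloSpec | None = None,
) -> tuple[float, float]:
    """Fit I(t) = I0·exp(−R·t) and return (R, Monte-Carlo error) in s⁻¹.

    Requires at least three delay points with positive intensities.  A
    non-monotonic trend beyond the noise level triggers a warning but the
    fit is still returned.
    """
    t = series.x
    y = series.intensity
    if len(t) < 3:
        raise FitError("exponential fit requires >= 3 delay points")
    if np.any(y <= 0):
        raise FitError("exponential fit requires positive intensities")

    noise = _point_sigma(series)
    order = np.argsort(t)
    increases = np.diff(y[order])
    if np.any(increases > 3.0 * max(noise.max(), 1e-12)):
        warnings.warn("intensity series is non-monotonic beyond noise; "
                      "fitted rate may be unreliable", stacklevel=2)

    p0 = _exp_initial_guess(t, y)
    popt, _ = curve_fit(_mono_exp, t, y, p0=p0, maxfev=10000)
    rate = float(popt[1])

    err = 0.0
    if mc is not None:
        rng = mc.rng()
        rates = np.empty(mc.replicates)
        model = _mono_exp(t, *popt)
        sigma = noise if noise.any() else _residual_sigma(y, model, 2)
        for i in range(mc.replicates):
            y_rep = model + rng.normal(0.0, sigma, size=len(t))
            y_rep = np.clip(y_rep, 1e-12, None)
            try:
                p_rep, _ = curve_fit(_mono_exp, t, y_rep, p0=popt,
                                     maxfev=10000)
                rates[i] = p_rep[1]
            except RuntimeError:
                rates[i] = np.nan
        err = float(np.nanstd(rates, ddof=1))
    return rate, err


def _exp_initial_guess(t, y):
    i0 = float(np.max(y))
    # log-linear slope as a robust starting rate
    with np.errstate(all="ignore"):
        slope = np.polyfit(t, np.log(y), 1)[0]
    rate0 = max(-float(slope), 0.0)
    return (i0, rate0)


def _point_sigma(series: IntensitySeries) -> np.ndarray:
    if series.error is not None and np.any(series.error > 0):
        return series.error.astype(float)
    return np.zeros(len(series))


def _residual_sigma(y, model, n_params):
    dof = max(len(y) - n_params, 1)
    return np.full(len(y), float(np.sqrt(np.sum((y - model) ** 2) / dof)))


# ---------------------------------------------------------------------------
# R2 from R1rho
# ---------------------------------------------------------------------------

MIN_TILT_RAD = math.radians(1.0)


def r2_from_r1rho(r1rho: float, r1: float,
                  params: RotatingFrameParams) -> float:
    """Off-resonance-corrected transverse rate R2 = R1ρ/sin²θ − R1/tan²θ."""
    theta = params.tilt_angle
    if not (MIN_TILT_RAD < theta <= math.pi / 2.0 + 1e-12):
        raise FitError(
            f"tilt angle {math.degrees(theta):.2f}° too small: offset "
            "dominates the spin lock and the correction is ill-conditioned"
        )
    s, t = math.sin(theta), math.tan(theta)
    return r1rho / (s * s) - r1 / (t * t)


def spin_lock_timescale_ceiling(spin_lock_hz: float = 2000.0) -> float:
    """Slowest exchange timescale (s) averaged out by the spin lock.

    Exchange processes slower than 1/(2π·ω) are levelled out; for the
    default 2 kHz field this is ≈ 80 µs.
    """
    if spin_lock_hz <= 0:
        raise ValidationError("spin-lock field strength must be > 0")
    return 1.0 / (2.0 * math.pi * spin_lock_hz)


# ---------------------------------------------------------------------------
# TRACT
# ---------------------------------------------------------------------------

def _j_rigid(omega: float, tauc: float) -> float:
    """Rigid-rotor spectral density J(ω) = (2/5)·τc/(1+(ωτc)²)."""
    return 0.4 * tauc / (1.0 + (omega * tauc) ** 2)


def etaxy_from_tauc(tauc_s: float, field_1h_mhz: float) -> float:
    """Forward ¹⁵N DD/CSA transverse cross-correlated rate ηxy(τc) in s⁻¹.

    ηxy = (1/8)·d·c·P2(cos β)·[4J(0) + 3J(ωN)] with dipolar coupling
    d = (μ0/4π)·γH·γN·ħ/r³, CSA coupling c = Δσ·ωN and β the angle between
    the CSA principal axis and the N–H bond.
    """
    b0 = 2.0 * math.pi * field_1h_mhz * 1e6 / k.GAMMA_H
    omega_n = abs(k.GAMMA_N) * b0
    d = k.MU0_OVER_4PI * k.GAMMA_H * abs(k.GAMMA_N) * k.HBAR / k.R_NH ** 3
    c = abs(k.CSA_N_PPM) * 1e-6 * omega_n
    p2b = k.p2(math.cos(math.radians(k.CSA_NH_ANGLE_DEG)))
    return 0.125 * d * c * p2b * (4.0 * _j_rigid(0.0, tauc_s)
                                  + 3.0 * _j_rigid(omega_n, tauc_s))


def tract_tauc(r2_alpha: float, r2_beta: float, field_1h_mhz: float = 700.0,
               temperature: float | None = None) -> float:
    """Rotational correlation time τc (ns) from TRACT doublet rates.

    The cross-correlated rate ηxy = (R2β − R2α)/2 is inverted to τc by
    bisection of the rigid-rotor spectral-density relation on
    [0.1, 200] ns.  ``temperature`` is accepted for bookkeeping only.
    """
    if r2_beta <= r2_alpha:
        raise FitError("R2β must exceed R2α (no TROSY effect observed)")
    eta = 0.5 * (r2_beta - r2_alpha)

    def objective(tauc_ns: float) -> float:
        return etaxy_from_tauc(tauc_ns * 1e-9, field_1h_mhz) - eta

    lo, hi = 0.1, 200.0
    if objective(lo) > 0 or objective(hi) < 0:
        raise FitError(f"ηxy = {eta:.3g} s⁻¹ outside invertible range "
                       "(τc in [0.1, 200] ns)")
    return brentq(objective, lo, hi, xtol=1e-6)


def tract_rates_from_tauc(tauc_ns: float, r2_avg: float,
                          field_1h_mhz: float = 700.0) -> tuple[float, float]:
    """Forward model: (R2α, R2β) for a given τc and mean transverse rate."""
    eta = etaxy_from_tauc(tauc_ns * 1e-9, field_1h_mhz)
    return r2_avg - eta, r2_avg + eta


# ---------------------------------------------------------------------------
# Derived products
# ---------------------------------------------------------------------------

def hetnoe_ratio(i_sat: float, i_ref: float, sigma_sat: float,
                 sigma_ref: float) -> tuple[float, float]:
    """hetNOE = Isat/Iref with spectral-noise ratio-error propagation."""
    if i_ref == 0:
        raise FitError("reference intensity is zero")
    noe = i_sat / i_ref
    err = abs(noe) * math.hypot(sigma_sat / i_sat if i_sat else 0.0,
                                sigma_ref / i_ref)
    return noe, err


def rate_products(records: list[RelaxationRecord]) -> dict[int, tuple[float, float]]:
    """Per-residue R1·R2β with first-order error propagation.

    Residues missing either rate are absent from the result (not zero).
    Relative errors add in quadrature.
    """
    out: dict[int, tuple[float, float]] = {}
    for rec in records:
        if rec.r1 is None or rec.r2_beta is None:
            continue
        prod = rec.r1 * rec.r2_beta
        rel = math.hypot(
            rec.r1_err / rec.r1 if rec.r1 else 0.0,
            rec.r2_beta_err / rec.r2_beta if rec.r2_beta else 0.0,
        )
        out[rec.residue_number] = (prod, abs(prod) * rel)
    return out
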