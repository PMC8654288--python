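"""Pulsed-field-gradient diffusion fitting and oligomer-size calibration.

A bipolar-gradient stimulated-echo (BPP-LED) experiment attenuates the
signal as

    ln I(g) = ln I(0) − D · γH² · g² · δeff² · (Δ − δeff/3 − τ/2)

with effective gradient duration δeff = 2·d for a bipolar pair of duration
d, diffusion delay Δ and gradient-recovery delay τ.  The translational
diffusion coefficient D follows from the slope of ln I versus g².  Values
measured at different temperatures are normalised through the
Stokes-Einstein relation, D_corr = D·(η(T_obs)/η(T_ref))·(T_ref/T_obs),
with bundled H2O/D2O viscosity tables.  A log-log calibration of D against
molecular weight converts diffusion coefficients to apparent oligomer size,
and the fast-exchange-averaged D interpolates linearly between two pure
oligomeric states to give population fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from nmrdyn import constants as k
from nmrdyn.errors import FitError, ValidationError

#: Calibrant molecular weights (kDa) of the literature calibration set:
#: GB1, lysozyme, interleukin-10, the α7 proteasome single ring, HsIV and
#: the α7α7 half proteasome.
CALIBRANT_MW_KDA: dict[str, float] = {
    "GB1": 6.2,
    "lysozyme": 14.1,
    "IL-10": 37.2,
    "alpha7": 180.0,
    "HslV": 230.0,
    "alpha7alpha7": 360.0,
}


@dataclass
class GradientSeries:
    """Signal intensity versus encoding gradient strength.

    Gradient strengths are in G/cm (or arbitrary units times a calibration
    factor); timings are in ms.  Defaults mirror a ¹³C-edited BPP-LED
    acquisition: gradient duration d = 3.2 ms, diffusion delay Δ = 400 ms,
    recovery delay τ = 0.1 ms.
    """

    gradients: np.ndarray
    intensity: np.ndarray
    gradient_duration_ms: float = 3.2
    diffusion_delay_ms: float = 400.0
    tau_ms: float = 0.1
    temperature: float = 298.15
    gradient_calibration: float = 1.0  # G/cm per instrument unit

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.gradients) < 4:
            raise ValidationError("need >= 4 gradient points")
        if np.any(np.diff(self.gradients) <= 0):
            raise ValidationError("gradient strengths must strictly increase")
        if self.gradients.shape != self.intensity.shape:
            raise ValidationError("gradient/intensity length mismatch")


@dataclass
class DiffusionResult:
    """Fitted translational diffusion coefficient (cm² s⁻¹)."""

    d_obs: float
    d_err: float
    r_squared: float
    d_corrected: float | None = None
    reference_temperature: float | None = None

    def __post_init__(self) -> None:
        if self.d_obs < 0:
            raise ValidationError("diffusion coefficient must be >= 0")


def stejskal_tanner_b(series: GradientSeries) -> np.ndarray:
    """Attenuation factors b(g) [s cm⁻²] such that I = I0·exp(−b·D)."""
    g = series.gradients * series.gradient_calibration  # G/cm
    delta_eff = 2.0 * series.gradient_duration_ms * 1e-3
    big_delta = series.diffusion_delay_ms * 1e-3
    tau = series.tau_ms * 1e-3
    corr = big_delta - delta_eff / 3.0 - tau / 2.0
    return (k.GAMMA_H_PER_GAUSS * delta_eff) ** 2 * corr * g ** 2


def fit_diffusion(series: GradientSeries) -> DiffusionResult:
    """Linear fit of ln I versus g² and conversion of the slope to D."""
    if np.any(series.intensity <= 0):
        raise FitError("diffusion fit requires positive intensities")
    g2 = (series.gradients * series.gradient_calibration) ** 2
    ln_i = np.log(series.intensity)
    res = stats.linregress(g2, ln_i)
    if res.slope > 0:
        raise FitError("positive ln(I) vs g² slope: non-physical "
                       "(intensities grow with gradient strength)")
    delta_eff = 2.0 * series.gradient_duration_ms * 1e-3
    big_delta = series.diffusion_delay_ms * 1e-3
    tau = series.tau_ms * 1e-3
    denom = (k.GAMMA_H_PER_GAUSS * delta_eff) ** 2 * (
        big_delta - delta_eff / 3.0 - tau / 2.0)
    d = -res.slope / denom
    d_err = res.stderr / denom if res.stderr is not None else 0.0
    return DiffusionResult(d_obs=float(d), d_err=float(d_err),
                           r_squared=float(res.rvalue ** 2))


# ---------------------------------------------------------------------------
# Viscosity/temperature normalisation
# ---------------------------------------------------------------------------

def _load_viscosity(solvent: str) -> pd.DataFrame:
    fname = {"h2o": "viscosity_h2o.tsv", "d2o": "viscosity_d2o.tsv"}.get(
        solvent.lower())
    if fname is None:
        raise ValidationError(f"unknown solvent '{solvent}' (h2o or d2o)")
    with resources.files("nmrdyn.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t")


def viscosity(temperature_k: float, solvent: str = "d2o") -> float:
    """Interpolated solvent viscosity (mPa·s) from the bundled table."""
    table = _load_viscosity(solvent)
    t_c = temperature_k - 273.15
    t_min, t_max = table.temperature_C.min(), table.temperature_C.max()
    if not (t_min <= t_c <= t_max):
        raise ValidationError(
            f"temperature {t_c:.1f} °C outside the bundled {solvent} "
            f"viscosity table ({t_min}-{t_max} °C)")
    return float(np.interp(t_c, table.temperature_C, table.viscosity_mPa_s))


def viscosity_correct(result: DiffusionResult, t_obs: float, t_ref: float,
                      solvent: str = "d2o") -> DiffusionResult:
    """Reference a diffusion coefficient to ``t_ref`` via Stokes-Einstein.

    D_corr = D_obs · (η(T_obs)/η(T_ref)) · (T_ref/T_obs); temperatures in K.
    """
    factor = (viscosity(t_obs, solvent) / viscosity(t_ref, solvent)) \
        * (t_ref / t_obs)
    return DiffusionResult(
        d_obs=result.d_obs, d_err=result.d_err, r_squared=result.r_squared,
        d_corrected=result.d_obs * factor, reference_temperature=t_ref)


# ---------------------------------------------------------------------------
# Molecular-weight calibration
# ---------------------------------------------------------------------------

@dataclass
class MwCalibration:
    """Log-log calibration of diffusion coefficient against MW."""

    slope: float
    intercept: float
    calibrants: dict[str, tuple[float, float]]  # name -> (MW kDa, D)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError("calibration slope must be negative")

    def predict_d(self, mw_kda: float) -> float:
        return 10.0 ** (self.intercept + self.slope * math.log10(mw_kda))

    def predict_mw(self, d_cm2_s: float) -> float:
        return 10.0 ** ((math.log10(d_cm2_s) - self.intercept) / self.slope)


def calibrate_mw(calibrants: dict[str, tuple[float, float]]) -> MwCalibration:
    """Least-squares fit of log10 D versus log10 MW over >= 3 calibrants."""
    if len(calibrants) < 3:
        raise FitError("MW calibration requires >= 3 calibrants")
    mw = np.log10([v[0] for v in calibrants.values()])
    d = np.log10([v[1] for v in calibrants.values()])
    res = stats.linregress(mw, d)
    return MwCalibration(slope=float(res.slope),
                         intercept=float(res.intercept),
                         calibrants=dict(calibrants))


def power_law_calibrants(anchor_mw_kda: float, anchor_d: float,
                         exponent: float = -1.0 / 3.0,
                         mw_kda: dict[str, float] | None = None
                         ) -> dict[str, tuple[float, float]]:
    """Synthetic calibrant set on D = A·MW^exponent through an anchor point."""
    mws = mw_kda or CALIBRANT_MW_KDA
    a = anchor_d / anchor_mw_kda ** exponent
    return {name: (m, a * m ** exponent) for name, m in mws.items()}


def oligomer_fraction(d_obs: float, d_low_state: float, d_high_state: float,
                      tolerance: float = 0.05) -> float:
    """Fraction of the fast (small) species from fast-exchange-averaged D.

    Linear interpolation between the slow-state (large oligomer, low D) and
    fast-state (small oligomer, high D) coefficients.  D_obs outside the
    bracket by more than ``tolerance`` of the span is an error; within the
    tolerance it is clamped to [0, 1].
    """
    if d_low_state >= d_high_state:
        raise ValidationError("d_low_state must be < d_high_state")
    span = d_high_state - d_low_state
    frac = (d_obs - d_low_state) / span
    if frac < -tolerance or frac > 1.0 + tolerance:
        raise ValidationError(
            f"D_obs = {d_obs:.3g} outside the [{d_low_state:.3g}, "
            f"{d_high_state:.3g}] state bracket beyond tolerance")
    return float(min(max(frac, 0.0), 1.0))
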