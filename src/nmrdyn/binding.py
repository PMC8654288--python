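"""1:1 binding analysis of biolayer-interferometry (BLI) data.

A 1:1 Langmuir interaction with association rate k_on (µM⁻¹ s⁻¹) and
dissociation rate k_off (s⁻¹) gives, for analyte concentration C in
pseudo-first-order excess,

    association:   R(t) = R_eq·(1 − exp(−(k_on·C + k_off)·t)),
                   R_eq = R_max·C/(K_d + C),  K_d = k_off/k_on
    dissociation:  R(t) = R(t_assoc)·exp(−k_off·(t − t_assoc))

Steady-state analysis fits the hyperbolic isotherm R_eq(C) for (K_d,
R_max); kinetic analysis globally fits sensorgrams at several
concentrations for (k_on, k_off, R_max).  Reference-sensor subtraction is
assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from nmrdyn.errors import FitError, ValidationError
from nmrdyn.series import MonteCarloSpec

DEFAULT_ASSOC_END_S = 30.0
DEFAULT_DISSOC_END_S = 40.0


@dataclass
class Sensorgram:
    """Response trace of one analyte concentration (µM) versus time (s)."""

    concentration: float
    time: np.ndarray
    response: np.ndarray
    assoc_end: float = DEFAULT_ASSOC_END_S
    dissoc_end: float = DEFAULT_DISSOC_END_S

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration <= 0:
            raise ValidationError("analyte concentration must be > 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if self.time.shape != self.response.shape:
            raise ValidationError("time/response length mismatch")


@dataclass
class BindingFit:
    """Binding parameters; K_d = k_off/k_on in kinetic mode."""

    k_d: float
    r_max: float
    k_on: float | None = None
    k_off: float | None = None
    k_d_err: float = 0.0
    r_max_err: float = 0.0
    mode: str = "steady_state"
    flags: list[str] | None = None

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValidationError("K_d must be > 0")


def model_sensorgram(k_on: float, k_off: float, r_max: float,
                     concentration: float, time,
                     assoc_end: float = DEFAULT_ASSOC_END_S) -> np.ndarray:
    """1:1 Langmuir sensorgram over association and dissociation phases."""
    if k_on < 0 or k_off < 0:
        raise ValidationError("rate constants must be >= 0")
    t = np.asarray(time, dtype=float)
    if concentration == 0:
        return np.zeros_like(t)
    k_d = k_off / k_on if k_on > 0 else np.inf
    r_eq = r_max * concentration / (k_d + concentration) \
        if np.isfinite(k_d) else 0.0
    k_obs = k_on * concentration + k_off
    assoc = r_eq * (1.0 - np.exp(-k_obs * np.minimum(t, assoc_end)))
    r_end = r_eq * (1.0 - np.exp(-k_obs * assoc_end))
    dissoc = r_end * np.exp(-k_off * np.clip(t - assoc_end, 0.0, None))
    return np.where(t <= assoc_end, assoc, dissoc)


def steady_state_response(sensorgram: Sensorgram,
                          plateau_fraction: float = 0.1
                          ) -> tuple[float, str]:
    """Equilibrium response from the tail of the association phase.

    Returns the mean of the final ``plateau_fraction`` of the association
    phase and a flag: 'plateau' when the curve has levelled (last-tenth
    slope small against the response), else 'extrapolated' with a
    mono-exponential extrapolation to t → ∞.
    """
    mask = sensorgram.time <= sensorgram.assoc_end
    t, r = sensorgram.time[mask], sensorgram.response[mask]
    n_tail = max(2, int(len(t) * plateau_fraction))
    tail_t, tail_r = t[-n_tail:], r[-n_tail:]
    slope = np.polyfit(tail_t, tail_r, 1)[0]
    mean_tail = float(np.mean(tail_r))
    if abs(slope) * (tail_t[-1] - tail_t[0]) < 0.02 * max(abs(mean_tail),
                                                          1e-9):
        return mean_tail, "plateau"

    def assoc(tt, r_eq, k_obs):
        return r_eq * (1.0 - np.exp(-k_obs * tt))

    popt, _ = curve_fit(assoc, t, r, p0=(max(r.max(), 1e-6), 0.1),
                        maxfev=10000)
    return float(popt[0]), "extrapolated"


def fit_steady_state(concentrations, responses,
                     mc: MonteCarloSpec | None = None) -> BindingFit:
    """Hyperbolic fit R_eq = R_max·C/(K_d + C) over >= 4 concentrations."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(c) < 4:
        raise FitError("steady-state fit requires >= 4 concentrations")

    def hyperbola(cc, r_max, k_d):
        return r_max * cc / (k_d + cc)

    p0 = (float(r.max()) * 1.2, float(np.median(c)))
    popt, _ = curve_fit(hyperbola, c, r, p0=p0,
                        bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=20000)
    r_max, k_d = map(float, popt)

    flags = []
    if k_d < c.min() / 10 or k_d > c.max() * 10:
        flags.append("kd_outside_concentration_range")

    k_d_err = r_max_err = 0.0
    if mc is not None:
        rng = mc.rng()
        model = hyperbola(c, *popt)
        sigma = np.maximum(0.02 * np.abs(model), 1e-6 * r_max)
        kds = np.empty(mc.replicates)
        rms = np.empty(mc.replicates)
        for i in range(mc.replicates):
            rep = model + rng.normal(0.0, sigma)
            try:
                p_rep, _ = curve_fit(hyperbola, c, rep, p0=popt,
                                     bounds=([0, 1e-9], [np.inf, np.inf]),
                                     maxfev=20000)
                rms[i], kds[i] = p_rep
            except RuntimeError:
                rms[i] = kds[i] = np.nan
        k_d_err = float(np.nanstd(kds, ddof=1))
        r_max_err = float(np.nanstd(rms, ddof=1))

    return BindingFit(k_d=k_d, r_max=r_max, k_d_err=k_d_err,
                      r_max_err=r_max_err, mode="steady_state",
                      flags=flags or None)


def fit_kinetic(sensorgrams: list[Sensorgram],
                mc: MonteCarloSpec | None = None) -> BindingFit:
    """Global 1:1 kinetic fit of (k_on, k_off, R_max) across concentrations."""
    if len(sensorgrams) < 3:
        raise FitError("kinetic fit requires >= 3 analyte concentrations")

    def residuals(x):
        k_on, k_off, r_max = x
        res = []
        for sg in sensorgrams:
            model = model_sensorgram(k_on, k_off, r_max, sg.concentration,
                                     sg.time, sg.assoc_end)
            res.append(model - sg.response)
        return np.concatenate(res)

    c_med = float(np.median([sg.concentration for sg in sensorgrams]))
    r_scale = max(float(np.max(np.abs(sg.response)))
                  for sg in sensorgrams) or 1.0
    x0 = [0.1, 0.5, r_scale * 1.5]
    sol = least_squares(residuals, x0,
                        bounds=([1e-9, 1e-9, 1e-9], [np.inf] * 3),
                        max_nfev=5000)
    k_on, k_off, r_max = map(float, sol.x)

    flags = []
    dissoc_span = min(sg.dissoc_end - sg.assoc_end for sg in sensorgrams)
    if k_off * dissoc_span < 0.1:
        flags.append("dissociation_too_short_for_koff")

    k_d_err = 0.0
    if mc is not None:
        rng = mc.rng()
        models = [model_sensorgram(k_on, k_off, r_max, sg.concentration,
                                   sg.time, sg.assoc_end)
                  for sg in sensorgrams]
        kds = np.empty(mc.replicates)
        originals = [sg.response for sg in sensorgrams]
        for i in range(mc.replicates):
            for sg, m in zip(sensorgrams, models):
                sg.response = m + rng.normal(0.0, 0.02 * r_scale,
                                             size=len(m))
            try:
                rep = least_squares(residuals, sol.x,
                                    bounds=([1e-9] * 3, [np.inf] * 3),
                                    max_nfev=2000)
                kds[i] = rep.x[1] / rep.x[0]
            except Exception:
                kds[i] = np.nan
        for sg, orig in zip(sensorgrams, originals):
            sg.response = orig
        k_d_err = float(np.nanstd(kds, ddof=1))

    return BindingFit(k_d=k_off / k_on, r_max=r_max, k_on=k_on,
                      k_off=k_off, k_d_err=k_d_err, mode="kinetic",
                      flags=flags or None)
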