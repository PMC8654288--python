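"""Two-state thermodynamic analysis of a thermal oligomer transition.

An equilibrium between a locked (e.g. hexameric) and an open (e.g.
trimeric) state with van't Hoff enthalpy ΔH and entropy ΔS has

    K_eq(T) = exp(−(ΔH − T·ΔS)/(R·T)),    p_open = K_eq/(1 + K_eq)

so the populations always sum to one and cross 0.5 at the midpoint
T_m = ΔH/ΔS.  Probe intensities are modelled as
I(T) = baseline + amplitude·p_open(T) and fitted globally over probes with
shared thermodynamics.  Internally the fit is parameterised as (ΔH, T_m),
which is unit-safe and numerically stable, and ΔS = ΔH/T_m is derived.

Note: the transition is fitted as an equilibrium two-state model; ΔH/ΔS
here are van't Hoff quantities of the locked↔open equilibrium, not
activation parameters of a rate process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from nmrdyn.constants import R_GAS_KJ
from nmrdyn.errors import FitError, ValidationError
from nmrdyn.series import IntensitySeries, MonteCarloSpec


def two_state_population(temperature_k, delta_h_kj: float,
                         delta_s_kj_per_k: float) -> np.ndarray:
    """Population of the open state at temperature(s) in K.

    ΔH in kJ mol⁻¹ and ΔS in kJ mol⁻¹ K⁻¹; p_open + p_locked = 1 exactly.
    """
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t <= 0):
        raise ValidationError("temperature must be > 0 K")
    dg = delta_h_kj - t * delta_s_kj_per_k
    # logistic form of Keq/(1+Keq), numerically safe for large |ΔG|
    x = -dg / (R_GAS_KJ * t)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class TwoStateThermoFit:
    """Global two-state fit over temperature-dependent probe intensities."""

    delta_h_kj: float
    delta_s_kj_per_k: float
    tm_k: float
    delta_h_err: float = 0.0
    tm_err: float = 0.0
    amplitudes: dict[str, float] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    identifiable: bool = True

    @property
    def tm_c(self) -> float:
        return self.tm_k - 273.15


def fit_two_state(series_list: list[IntensitySeries],
                  mc: MonteCarloSpec | None = None) -> TwoStateThermoFit:
    """Fit shared (ΔH, T_m) with per-probe amplitude and baseline.

    Each series holds normalised intensities versus temperature in K
    (>= 4 points).  Data with no resolvable transition inside the
    temperature range are flagged unidentifiable.
    """
    if not series_list:
        raise FitError("no thermal series supplied")
    for s in series_list:
        if len(s) < 4:
            raise FitError(f"probe {s.probe_id}: need >= 4 temperatures")
    t_all = np.concatenate([s.x for s in series_list])
    t_lo, t_hi = float(t_all.min()), float(t_all.max())

    spans = [float(np.ptp(s.intensity)) for s in series_list]
    noises = [float(np.max(s.error)) if s.error is not None else 0.0
              for s in series_list]
    identifiable = any(sp > max(3.0 * nz, 0.05) for sp, nz in
                       zip(spans, noises))

    n_probe = len(series_list)

    def unpack(x):
        dh, tm = x[0], x[1]
        amps = x[2:2 + n_probe]
        bases = x[2 + n_probe:]
        return dh, tm, amps, bases

    def residuals(x):
        dh, tm, amps, bases = unpack(x)
        ds = dh / tm
        res = []
        for s, a, b in zip(series_list, amps, bases):
            model = b + a * two_state_population(s.x, dh, ds)
            w = s.error if s.error is not None and np.all(s.error > 0) \
                else np.ones(len(s))
            res.append((model - s.intensity) / w)
        return np.concatenate(res)

    x0 = [250.0, 0.5 * (t_lo + t_hi)]
    lb = [1.0, t_lo - 50.0]
    ub = [5000.0, t_hi + 50.0]
    for s in series_list:
        rising = s.intensity[np.argmax(s.x)] >= s.intensity[np.argmin(s.x)]
        span = float(np.ptp(s.intensity)) or 1.0
        x0 += [span if rising else -span]
        lb += [-np.inf]
        ub += [np.inf]
    for s in series_list:
        x0 += [float(np.min(s.intensity))]
        lb += [-np.inf]
        ub += [np.inf]

    sol = least_squares(residuals, x0, bounds=(lb, ub), max_nfev=5000)
    dh, tm, amps, bases = unpack(sol.x)

    dh_err = tm_err = 0.0
    if mc is not None:
        rng = mc.rng()
        ds_hat = dh / tm
        models = [b + a * two_state_population(s.x, dh, ds_hat)
                  for s, a, b in zip(series_list, amps, bases)]
        dhs = np.empty(mc.replicates)
        tms = np.empty(mc.replicates)
        originals = [s.intensity for s in series_list]
        for i in range(mc.replicates):
            for s, m in zip(series_list, models):
                sigma = (s.error if s.error is not None
                         and np.all(s.error > 0) else 0.02 * np.abs(m))
                s.intensity = m + rng.normal(0.0, sigma)
            try:
                rep = least_squares(residuals, sol.x, bounds=(lb, ub),
                                    max_nfev=2000)
                dhs[i], tms[i] = rep.x[0], rep.x[1]
            except Exception:
                dhs[i] = tms[i] = np.nan
        for s, orig in zip(series_list, originals):
            s.intensity = orig
        dh_err = float(np.nanstd(dhs, ddof=1))
        tm_err = float(np.nanstd(tms, ddof=1))

    return TwoStateThermoFit(
        delta_h_kj=float(dh), delta_s_kj_per_k=float(dh / tm),
        tm_k=float(tm), delta_h_err=dh_err, tm_err=tm_err,
        amplitudes={s.probe_id: float(a)
                    for s, a in zip(series_list, amps)},
        baselines={s.probe_id: float(b)
                   for s, b in zip(series_list, bases)},
        identifiable=identifiable,
    )


def population_curve(fit: TwoStateThermoFit, temperatures_k
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(p_open, p_locked) on a temperature grid; sums to 1 exactly."""
    p_open = two_state_population(temperatures_k, fit.delta_h_kj,
                                  fit.delta_s_kj_per_k)
    return p_open, 1.0 - p_open
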