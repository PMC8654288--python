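"""Peak tables, acquisition corrections and chemical-shift perturbations.

The atom-level currency of the pipeline is the :class:`PeakRecord`: an
assigned resonance with per-nucleus chemical shifts (ppm) and an intensity
with error.  Tables of records are read from and written to delimited text
with a configurable column mapping, intensities are normalised across
acquisition conditions (scans, dilution, pulse length), and shift changes
between two states are condensed into weighted chemical-shift perturbations
(CSPs).

CSP conventions
---------------
Amide moiety:   Δδ(HN) = sqrt(Δδ¹H² + (Δδ¹⁵N/5)²)
Methyl groups:  Δδ(HC) = sqrt(Δδ¹H² + (Δδ¹³C/4)²)

A CSP is flagged significant when it reaches ``threshold`` (default
0.05 ppm).  Secondary chemical shifts combine Cα and Cβ deviations from
random coil and are smoothed with a 1-2-1 window over residues
(i−1)–i–(i+1); at chain termini and next to missing residues the available
weights are renormalised rather than zero-padded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nmrdyn.errors import FormatError, ValidationError

DEFAULT_CSP_THRESHOLD = 0.05  # ppm
AMIDE_N_WEIGHT = 5.0
METHYL_C_WEIGHT = 4.0

#: Default file column → field mapping for delimited peak tables.
DEFAULT_COLUMNS: dict[str, str] = {
    "residue_number": "residue",
    "residue_type": "residue_type",
    "atom_group": "atom_group",
    "shift_1H": "shift_1H",
    "shift_15N": "shift_15N",
    "shift_13C": "shift_13C",
    "intensity": "intensity",
    "intensity_error": "intensity_error",
}


@dataclass(frozen=True)
class AcquisitionContext:
    """Acquisition parameters entering intensity normalisation.

    Attributes
    ----------
    temperature : float
        Sample temperature in K.
    scans : int
        Number of scans accumulated.
    pulse90_length : float
        ¹H 90° pulse length in µs.
    dilution_factor : float
        Dilution of the sample relative to the stock (1.0 = undiluted).
    field_1H : float
        ¹H Larmor frequency in MHz.
    """

    temperature: float
    scans: int
    pulse90_length: float
    dilution_factor: float = 1.0
    field_1H: float = 700.0

    def __post_init__(self) -> None:
        for name in ("temperature", "scans", "pulse90_length",
                     "dilution_factor", "field_1H"):
            if getattr(self, name) <= 0:
                raise ValidationError(
                    f"AcquisitionContext.{name} must be strictly positive"
                )


@dataclass(frozen=True)
class PeakRecord:
    """One assigned resonance with chemical shifts and intensity."""

    residue_number: int
    residue_type: str
    atom_group: str
    shifts: Mapping[str, float]
    intensity: float = 0.0
    intensity_error: float = 0.0

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise ValidationError(
                f"residue_number must be >= 1, got {self.residue_number}"
            )
        if not self.shifts:
            raise ValidationError(
                f"residue {self.residue_number} {self.atom_group}: "
                "at least one nucleus shift required"
            )
        if self.intensity_error < 0:
            raise ValidationError("intensity_error must be >= 0")

    def shift(self, nucleus: str) -> float:
        try:
            return self.shifts[nucleus]
        except KeyError:
            raise ValidationError(
                f"residue {self.residue_number} {self.atom_group}: "
                f"missing {nucleus} shift"
            ) from None


@dataclass
class PeakTable:
    """Ordered collection of peak records under one acquisition condition."""

    records: list[PeakRecord]
    condition: AcquisitionContext | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str]] = set()
        for rec in self.records:
            key = (rec.residue_number, rec.atom_group)
            if key in seen:
                raise ValidationError(f"duplicate peak {key} in table")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, residue_number: int, atom_group: str) -> PeakRecord | None:
        for rec in self.records:
            if (rec.residue_number, rec.atom_group) == (residue_number,
                                                        atom_group):
                return rec
        return None


@dataclass(frozen=True)
class CSPRecord:
    """Chemical-shift perturbation for one residue/probe."""

    residue_number: int
    csp: float
    significant: bool

    def __post_init__(self) -> None:
        if self.csp < 0:
            raise ValidationError("csp must be >= 0")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NUCLEUS_COLUMNS = {"shift_1H": "1H", "shift_15N": "15N", "shift_13C": "13C"}


def read_peak_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
    condition: AcquisitionContext | None = None,
) -> PeakTable:
    """Read a delimited peak table into a :class:`PeakTable`.

    ``columns`` maps field names (keys of :data:`DEFAULT_COLUMNS`) to the
    header names used in the file.  Shift columns that are absent or empty
    for a row are simply omitted from that record's shifts.  Malformed rows
    raise :class:`FormatError` naming the offending line.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
    for mandatory in ("residue_number",):
        if colmap[mandatory] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column '{colmap[mandatory]}'"
            )
    records: list[PeakRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            shifts: dict[str, float] = {}
            for col_key, nucleus in _NUCLEUS_COLUMNS.items():
                col = colmap[col_key]
                if col in df.columns and not _is_blank(row[col]):
                    shifts[nucleus] = float(row[col])
            records.append(PeakRecord(
                residue_number=int(row[colmap["residue_number"]]),
                residue_type=_str_or(row, df, colmap["residue_type"], "X"),
                atom_group=_str_or(row, df, colmap["atom_group"], "HN"),
                shifts=shifts,
                intensity=_float_or(row, df, colmap["intensity"], 0.0),
                intensity_error=_float_or(row, df, colmap["intensity_error"],
                                          0.0),
            ))
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
    return PeakTable(records=records, condition=condition)


def write_peak_table(table: PeakTable, path: str | Path,
                     sep: str = "\t") -> None:
    """Write a peak table as delimited text (ppm with 6 decimals)."""
    rows = []
    for rec in table.records:
        rows.append({
            "residue": rec.residue_number,
            "residue_type": rec.residue_type,
            "atom_group": rec.atom_group,
            "shift_1H": _fmt(rec.shifts.get("1H")),
            "shift_15N": _fmt(rec.shifts.get("15N")),
            "shift_13C": _fmt(rec.shifts.get("13C")),
            "intensity": repr(rec.intensity),
            "intensity_error": repr(rec.intensity_error),
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_csp_json(records: Sequence[CSPRecord], path: str | Path) -> None:
    payload = [
        {"residue_number": r.residue_number,
         "csp": round(r.csp, 6),
         "significant": r.significant}
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.6f}"


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) \
        or (isinstance(value, str) and value.strip() == "")


def _str_or(row, df, col, default):
    if col in df.columns and not _is_blank(row[col]):
        return str(row[col])
    return default


def _float_or(row, df, col, default):
    if col in df.columns and not _is_blank(row[col]):
        return float(row[col])
    return default


# ---------------------------------------------------------------------------
# Intensity corrections
# ---------------------------------------------------------------------------

def correct_intensities(
    intensities: np.ndarray | Sequence[float],
    context_ref: AcquisitionContext,
    context_new: AcquisitionContext,
    extra_scale: float = 1.0,
) -> np.ndarray:
    """Rescale intensities acquired under ``context_new`` onto ``context_ref``.

    The correction divides by the scans ratio and the dilution ratio and
    multiplies by the pulse-length ratio (receiver-equivalence convention);
    ``extra_scale`` applies an additional global factor, e.g. to compensate
    temperature-dependent transverse-relaxation losses when comparing
    spectra across temperatures.
    """
    if context_new.scans <= 0 or context_new.dilution_factor <= 0:
        raise ValidationError("scans and dilution factor must be positive")
    arr = np.asarray(intensities, dtype=float)
    factor = (
        (context_ref.scans / context_new.scans)
        * (context_ref.dilution_factor / context_new.dilution_factor)
        * (context_new.pulse90_length / context_ref.pulse90_length)
        * extra_scale
    )
    return arr * factor


def correct_table(table: PeakTable, context_ref: AcquisitionContext,
                  extra_scale: float = 1.0) -> PeakTable:
    """Apply :func:`correct_intensities` to every record of a table."""
    if table.condition is None:
        raise ValidationError("table has no acquisition context")
    raw = np.array([r.intensity for r in table.records])
    errs = np.array([r.intensity_error for r in table.records])
    corr = correct_intensities(raw, context_ref, table.condition, extra_scale)
    corr_err = correct_intensities(errs, context_ref, table.condition,
                                   extra_scale)
    new_records = [
        replace(rec, intensity=i, intensity_error=e)
        for rec, i, e in zip(table.records, corr, corr_err)
    ]
    return PeakTable(records=new_records, condition=context_ref)


# ---------------------------------------------------------------------------
# Chemical-shift perturbations
# ---------------------------------------------------------------------------

def amide_csp(ref: PeakRecord, new: PeakRecord,
              threshold: float = DEFAULT_CSP_THRESHOLD) -> CSPRecord:
    """Weighted amide CSP: sqrt(Δδ¹H² + (Δδ¹⁵N/5)²)."""
    d_h = new.shift("1H") - ref.shift("1H")
    d_n = new.shift("15N") - ref.shift("15N")
    csp = math.hypot(d_h, d_n / AMIDE_N_WEIGHT)
    return CSPRecord(ref.residue_number, csp, csp >= threshold)


def methyl_csp(ref: PeakRecord, new: PeakRecord,
               threshold: float = DEFAULT_CSP_THRESHOLD) -> CSPRecord:
    """Weighted methyl CSP: sqrt(Δδ¹H² + (Δδ¹³C/4)²)."""
    d_h = new.shift("1H") - ref.shift("1H")
    d_c = new.shift("13C") - ref.shift("13C")
    csp = math.hypot(d_h, d_c / METHYL_C_WEIGHT)
    return CSPRecord(ref.residue_number, csp, csp >= threshold)


def csp_table(ref: PeakTable, new: PeakTable, kind: str = "amide",
              threshold: float = DEFAULT_CSP_THRESHOLD) -> list[CSPRecord]:
    """CSPs for all peaks present in both tables (matched on residue/atom)."""
    func = amide_csp if kind == "amide" else methyl_csp
    out = []
    for rec in ref.records:
        other = new.get(rec.residue_number, rec.atom_group)
        if other is not None:
            out.append(func(rec, other, threshold))
    return out


# ---------------------------------------------------------------------------
# Secondary chemical shifts
# ---------------------------------------------------------------------------

def secondary_shifts(
    observed_ca: Sequence[float],
    observed_cb: Sequence[float],
    random_coil_ca: Sequence[float],
    random_coil_cb: Sequence[float],
    mode: str = "difference",
) -> np.ndarray:
    """Combined, 1-2-1 smoothed secondary chemical shifts.

    Raw secondary shifts Δδ = observed − random coil are combined per
    residue as Δδ(Cα) − Δδ(Cβ) (``mode='difference'``, default; positive for
    helix, negative for strand) or Δδ(Cα) + Δδ(Cβ) (``mode='sum'``), then
    smoothed with weights 1-2-1 over (i−1)–i–(i+1).  Missing residues
    (NaN in any input) stay NaN and are skipped in neighbouring windows by
    renormalising the remaining weights; the same renormalisation handles
    the chain termini.
    """
    arrays = [np.asarray(a, dtype=float) for a in
              (observed_ca, observed_cb, random_coil_ca, random_coil_cb)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValidationError("secondary_shifts: input length mismatch")
    oca, ocb, rca, rcb = arrays
    dca = oca - rca
    dcb = ocb - rcb
    combined = dca - dcb if mode == "difference" else dca + dcb
    return smooth_121(combined)


def smooth_121(values: Sequence[float]) -> np.ndarray:
    """1-2-1 running average with renormalised weights at gaps/termini."""
    v = np.asarray(values, dtype=float)
    out = np.full_like(v, np.nan)
    n = len(v)
    for i in range(n):
        if np.isnan(v[i]):
            continue
        wsum, acc = 0.0, 0.0
        for j, w in ((i - 1, 1.0), (i, 2.0), (i + 1, 1.0)):
            if 0 <= j < n and not np.isnan(v[j]):
                acc += w * v[j]
                wsum += w
        out[i] = acc / wsum
    return out
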