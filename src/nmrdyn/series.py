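"""Shared containers for one-dimensional intensity series and Monte-Carlo
error specification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nmrdyn.errors import ValidationError


@dataclass
class IntensitySeries:
    """Intensities of one probe versus one experimental control variable.

    The control variable ``x`` may be a relaxation delay (s), a CPMG
    frequency (Hz), a mixing time (s), a gradient strength, a temperature
    (K) or an analyte concentration (µM), depending on the experiment.
    """

    probe_id: str
    x: np.ndarray
    intensity: np.ndarray
    error: np.ndarray | None = None
    x_label: str = "x"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.x.shape != self.intensity.shape:
            raise ValidationError("x and intensity must have equal length")
        if self.error is not None:
            self.error = np.asarray(self.error, dtype=float)
            if self.error.shape != self.x.shape:
                raise ValidationError("error must match x length")
            if np.any(self.error < 0):
                raise ValidationError("errors must be >= 0")

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        data = {"probe": self.probe_id, self.x_label: self.x,
                "intensity": self.intensity}
        if self.error is not None:
            data["error"] = self.error
        return pd.DataFrame(data)


@dataclass(frozen=True)
class MonteCarloSpec:
    """Monte-Carlo error-propagation settings.

    Replicate datasets are drawn with per-point Gaussian noise (σ taken
    from the series errors, or from fit residuals when absent) and refit;
    the reported error is the standard deviation of the replicate
    estimates.  The seed is mandatory so errors are reproducible.
    """

    seed: int
    replicates: int = 500

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValidationError("Monte-Carlo replicates must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
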