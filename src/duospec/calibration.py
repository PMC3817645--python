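"""Beer's-law calibration: OLS line fit, molar absorptivity, and LOQ.

A calibration line is the ordinary least-squares fit (with intercept) of
absorbance A on concentration C over a standard series:

    A = a + s·C

With a 1 cm path length the slope s is the molar absorptivity ε in
mmol⁻¹·L·cm⁻¹. The limit of quantitation is

    LOQ = (a + 10·|Δa|) / s

where Δa is the standard error of the intercept. With the coefficients of
the published HMF/266 nm line (a=−0.0055, Δa=0.021, s=12.38) this gives
0.017 mmol/L, and 4.68 mmol/L for the LA/284 nm line (a=0.0075, Δa=0.0058,
s=0.014).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from scipy import stats

from .spectra import CalibrationTable

__all__ = [
    "CalibrationLine",
    "DegenerateDesignError",
    "InsufficientPointsError",
    "InvalidLineError",
    "fit_line",
    "loq",
    "molar_absorptivity",
]


class DegenerateDesignError(ValueError):
    """All standard concentrations equal; the slope is not identifiable."""


class InsufficientPointsError(ValueError):
    """Fewer than three calibration points."""


class InvalidLineError(ValueError):
    """Calibration line unusable for the requested computation (slope <= 0)."""


@dataclass
class CalibrationLine:
    """A fitted Beer's-law line for one analyte at one wavelength.

    ``slope`` is in AU·L/mmol (≡ ε for a 1 cm path), ``intercept`` in AU.
    ``intercept_uncertainty`` (Δa) and ``slope_uncertainty`` are the OLS
    standard errors of the respective coefficients.
    """

    analyte: str
    wavelength: float
    slope: float
    intercept: float
    intercept_uncertainty: float
    slope_uncertainty: float
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.intercept_uncertainty < 0 or self.slope_uncertainty < 0:
            raise ValueError("uncertainties must be >= 0")
        # allow r² marginally outside [0,1] from rounding, then clip
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = min(max(self.r_squared, 0.0), 1.0)
        if self.n < 3:
            raise InsufficientPointsError("a calibration line needs n >= 3")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationLine":
        return cls(**json.loads(Path(path).read_text()))


def fit_line(table: CalibrationTable) -> CalibrationLine:
    """Fit absorbance on concentration by OLS with intercept.

    Returns the slope and intercept together with their standard errors and
    the coefficient of determination r². Raises
    :class:`InsufficientPointsError` for n < 3 and
    :class:`DegenerateDesignError` when every concentration is identical.
    """
    conc = table.concentrations
    absb = table.absorbances
    if len(conc) < 3:
        raise InsufficientPointsError(f"need >= 3 points, got {len(conc)}")
    if conc.max() == conc.min():
        raise DegenerateDesignError("all concentrations equal; cannot fit a slope")

    res = stats.linregress(conc, absb)
    return CalibrationLine(
        analyte=table.analyte,
        wavelength=table.wavelength,
        slope=float(res.slope),
        intercept=float(res.intercept),
        intercept_uncertainty=float(res.intercept_stderr),
        slope_uncertainty=float(res.stderr),
        r_squared=float(res.rvalue) ** 2,
        n=len(conc),
    )


def loq(line: CalibrationLine) -> float:
    """Limit of quantitation, (a + 10·|Δa|) / s, in mmol/L.

    Uses the signed intercept a exactly as the defining formula is written.
    Requires a positive slope.
    """
    if line.slope <= 0:
        raise InvalidLineError("LOQ requires a positive slope")
    return (line.intercept + 10.0 * abs(line.intercept_uncertainty)) / line.slope


def molar_absorptivity(line: CalibrationLine, path_length: float = 1.0) -> float:
    """Molar absorptivity ε = slope / path_length, in mmol⁻¹·L·cm⁻¹."""
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    return line.slope / path_length
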