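"""Dual-wavelength quantification: charcoal correction, 2×2 Beer's-law
deconvolution, and hydrolysate content computation.

The mixture absorbance of the charcoal-treated sample at the two analytical
wavelengths is a classical-least-squares (CLS) superposition of the two
analytes:

    A_λ = l · (ε_HMF^λ · C_HMF + ε_LA^λ · C_LA),   λ ∈ {266, 284} nm

(The published rendering of this system scrambles some sub/superscripts —
pairing an LA absorptivity with C_HMF — which contradicts Beer's law; the
form above is the physically consistent reading and reproduces the intended
method.) The 2×2 system is solved exactly. Charcoal treatment removes the
colored byproducts but also adsorbs part of each analyte; the correction
coefficient

    K = A_before / A_after

(measured on pure standards at each analyte's peak wavelength) compensates
for that loss. The content in the original hydrolysate is then

    W = C · M · K · R   [mg/L]

with M the molecular weight (g/mol) and R the dilution factor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectra import Spectrum, absorbance_at

__all__ = [
    "AbsorptivityMatrix",
    "CorrectionCoefficients",
    "QuantResult",
    "SingularSystemError",
    "PUBLISHED_EPSILON",
    "PUBLISHED_K",
    "PUBLISHED_LOQ",
    "MOLECULAR_WEIGHTS",
    "correction_coefficient",
    "solve_two_component",
    "contents",
    "quantify_sample",
]

# Published molar absorptivities (mmol⁻¹·L·cm⁻¹) at the analytical wavelengths.
PUBLISHED_EPSILON: dict[str, dict[float, float]] = {
    "HMF": {266.0: 12.38, 284.0: 22.7},
    "LA": {266.0: 0.023, 284.0: 0.014},
}
# Published charcoal correction coefficients (dimensionless).
PUBLISHED_K: dict[str, float] = {"HMF": 69.3, "LA": 1.62}
# Published limits of quantitation (mmol/L): HMF at 266 nm, LA at 284 nm.
PUBLISHED_LOQ: dict[str, float] = {"HMF": 0.017, "LA": 4.68}
# Standard molecular weights, g/mol.
MOLECULAR_WEIGHTS: dict[str, float] = {"HMF": 126.11, "LA": 116.12}


class SingularSystemError(ValueError):
    """The absorptivity matrix is (numerically) singular."""


class NonPositiveAbsorbanceError(ValueError):
    """Post-treatment absorbance is <= 0; the K ratio is undefined."""


@dataclass
class AbsorptivityMatrix:
    """The 2×2 molar-absorptivity table ε[analyte][wavelength].

    Rows of :meth:`as_array` are wavelengths, columns are analytes, so that
    ``A = l · E @ C`` for the concentration vector C ordered like
    ``analytes``.
    """

    entries: Mapping[str, Mapping[float, float]] = field(
        default_factory=lambda: {a: dict(w) for a, w in PUBLISHED_EPSILON.items()}
    )
    wavelengths: tuple[float, float] = (266.0, 284.0)
    analytes: tuple[str, str] = ("HMF", "LA")

    def __post_init__(self) -> None:
        for analyte in self.analytes:
            for wl in self.wavelengths:
                eps = self.entries[analyte][wl]
                if eps < 0:
                    raise ValueError(f"epsilon[{analyte}][{wl}] must be >= 0")
        arr = self.as_array()
        det = arr[0, 0] * arr[1, 1] - arr[0, 1] * arr[1, 0]
        scale = max(abs(arr[0, 0] * arr[1, 1]), abs(arr[0, 1] * arr[1, 0]), 1e-300)
        if abs(det) <= 1e-12 * scale:
            raise SingularSystemError(
                "absorptivity matrix is singular; the two-component system is unsolvable"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.entries[a][wl] for a in self.analytes] for wl in self.wavelengths]
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "wavelengths": list(self.wavelengths),
            "analytes": list(self.analytes),
            "entries": {
                a: {str(wl): self.entries[a][wl] for wl in self.wavelengths}
                for a in self.analytes
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "AbsorptivityMatrix":
        payload = json.loads(Path(path).read_text())
        wavelengths = tuple(float(w) for w in payload["wavelengths"])
        analytes = tuple(payload["analytes"])
        entries = {
            a: {float(w): float(v) for w, v in payload["entries"][a].items()}
            for a in analytes
        }
        return cls(entries=entries, wavelengths=wavelengths, analytes=analytes)


@dataclass
class CorrectionCoefficients:
    """Per-analyte charcoal correction coefficients K = A_before / A_after.

    K ≥ 1: adsorption can only remove analyte, never add it.
    """

    K: dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_K))

    def __post_init__(self) -> None:
        for analyte, k in self.K.items():
            if k < 1:
                raise ValueError(f"K[{analyte}] = {k} < 1; charcoal cannot add analyte")

    def __getitem__(self, analyte: str) -> float:
        return self.K[analyte]


@dataclass
class QuantResult:
    """Solved concentrations and corrected hydrolysate contents.

    ``concentrations`` are mmol/L in the charcoal-treated, diluted solution;
    ``contents_mg_L`` are mg/L in the original hydrolysate (W = C·M·K·R).
    ``flags`` holds strings of the form ``"below_loq:HMF"``,
    ``"negative_clamped:LA"`` or ``"singular_system"``.
    """

    concentrations: dict[str, float]
    contents_mg_L: dict[str, float]
    flags: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "concentrations_mmol_L": self.concentrations,
            "contents_mg_L": self.contents_mg_L,
            "flags": sorted(self.flags),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def correction_coefficient(
    before: Spectrum, after: Spectrum, wavelength: float
) -> float:
    """Charcoal correction coefficient K = A_before(λ) / A_after(λ).

    Measured on a pure standard at the analyte's characteristic wavelength
    (284 nm for HMF, 266 nm for LA). Raises
    :class:`NonPositiveAbsorbanceError` when the post-treatment absorbance
    is <= 0; warns when K < 1 (treatment apparently added absorbance).
    """
    a_before = absorbance_at(before, wavelength)
    a_after = absorbance_at(after, wavelength)
    if a_after <= 0:
        raise NonPositiveAbsorbanceError(
            f"post-treatment absorbance {a_after} AU at {wavelength} nm is not positive"
        )
    k = a_before / a_after
    if k < 1:
        warnings.warn(
            f"K = {k:.4g} < 1 at {wavelength} nm: treated spectrum absorbs more "
            "than the untreated one",
            stacklevel=2,
        )
    return k


def solve_two_component(
    a266: float,
    a284: float,
    matrix: AbsorptivityMatrix | None = None,
    path_length: float = 1.0,
) -> tuple[float, float]:
    """Solve the two-wavelength Beer's-law system for (C_HMF, C_LA), mmol/L.

    Solves ``A = l · E @ C`` exactly for the 2×2 absorptivity matrix E.
    Negative components are returned unclamped; callers decide whether to
    clamp (see :func:`quantify_sample`).
    """
    if matrix is None:
        matrix = AbsorptivityMatrix()
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    m = path_length * matrix.as_array()
    try:
        c = np.linalg.solve(m, np.array([a266, a284], dtype=float))
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(str(exc)) from exc
    return float(c[0]), float(c[1])


def contents(c: float, m: float, k: float, r: float) -> float:
    """Hydrolysate content W = C · M · K · R, mg/L.

    mmol/L × g/mol = mg/L, scaled by the charcoal correction K and the
    dilution factor R.
    """
    if min(c, m, k, r) < 0:
        raise ValueError("all inputs must be >= 0")
    return c * m * k * r


def quantify_sample(
    treated: Spectrum,
    matrix: AbsorptivityMatrix | None = None,
    correction: CorrectionCoefficients | Mapping[str, float] | None = None,
    molecular_weights: Mapping[str, float] | None = None,
    loqs: Mapping[str, float] | None = None,
) -> QuantResult:
    """Quantify HMF and LA from a charcoal-treated spectrum.

    Reads A266 and A284 off the spectrum, solves the two-component system,
    clamps small negative concentrations to zero (flag ``negative_clamped``),
    flags concentrations below the per-analyte LOQ, and converts to
    hydrolysate contents with W = C·M·K·R using the spectrum's dilution
    factor R.
    """
    if matrix is None:
        matrix = AbsorptivityMatrix()
    if correction is None:
        correction = CorrectionCoefficients()
    k_map = correction.K if isinstance(correction, CorrectionCoefficients) else correction
    m_map = dict(MOLECULAR_WEIGHTS if molecular_weights is None else molecular_weights)

    a266 = absorbance_at(treated, matrix.wavelengths[0])
    a284 = absorbance_at(treated, matrix.wavelengths[1])
    solved = solve_two_component(a266, a284, matrix, path_length=treated.path_length)

    flags: set[str] = set()
    conc: dict[str, float] = {}
    for analyte, c in zip(matrix.analytes, solved):
        if c < 0:
            flags.add(f"negative_clamped:{analyte}")
            c = 0.0
        if loqs is not None and analyte in loqs and c < loqs[analyte]:
            flags.add(f"below_loq:{analyte}")
        conc[analyte] = c

    w = {
        analyte: contents(conc[analyte], m_map[analyte], k_map[analyte],
                          treated.dilution_factor)
        for analyte in matrix.analytes
    }
    return QuantResult(concentrations=conc, contents_mg_L=w, flags=flags)
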