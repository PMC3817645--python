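"""Synthetic UV spectra: forward Beer's-law model, byproduct interferent,
charcoal treatment, calibration sets, and hydrolysate kinetics.

No instrument data accompany the method, so this module is the testbed for
everything else: it renders absorbance curves from known concentrations so
the inverse problem (calibration, deconvolution, correction) can be checked
against ground truth.

Band model
----------
Each analyte's absorption band is a Gaussian in wavelength,

    ε(λ) = ε_peak · exp(−(λ − center)² / (2σ²)),

the minimal smooth two-parameter shape fixed by the two published
absorptivity constraints per analyte. HMF peaks at 284 nm with
ε_peak = 22.7; its width solves ε(266)/ε(284) = 12.38/22.7, giving
σ ≈ 16.35 nm. LA peaks at 266 nm with ε_peak = 0.023 and
ε(284)/ε(266) = 0.014/0.023, giving σ ≈ 18.06 nm. The hydrolysis
byproducts are modeled as one broad Gaussian band centered at 400 nm
(σ = 30 nm) covering the 350–450 nm interference window.

Charcoal model
--------------
At dosage d (g charcoal per mL sample) the byproduct band is scaled by
max(0, 1 − d/0.1) — complete removal at and above 0.1 g/mL — while each
analyte band is attenuated linearly in dosage from factor 1 at d = 0 down
to 1/K at d ≥ 0.1 g/mL, where K is that analyte's correction coefficient.

Kinetics
--------
``simulate_hydrolysate_series`` drives demo workflows with the closed-form
consecutive first-order scheme glucose → HMF → LA. It goes beyond what the
method itself established (no rate constants were measured); it exists only
for demonstrations and stress tests, never as an assertion target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import PUBLISHED_EPSILON, PUBLISHED_K
from .spectra import CalibrationTable, Spectrum

__all__ = [
    "BandModel",
    "SyntheticConfig",
    "HMF_BAND",
    "LA_BAND",
    "DEFAULT_CALIBRATION_CONCENTRATIONS",
    "render_spectrum",
    "charcoal_treat",
    "make_calibration_set",
    "simulate_hydrolysate_series",
    "hmf_peak_time",
]

# Dosage (g/mL) at which charcoal removes the byproduct band completely.
FULL_TREATMENT_DOSAGE = 0.1

# Standard-series concentrations (mmol/L) used for the published calibrations.
DEFAULT_CALIBRATION_CONCENTRATIONS: dict[str, tuple[float, ...]] = {
    "HMF": (0.019, 0.037, 0.056, 0.075, 0.093),
    "LA": (20.25, 29.80, 39.00, 47.86, 64.66),
}


@dataclass(frozen=True)
class BandModel:
    """A Gaussian absorption band: ε(λ) = peak · exp(−(λ−center)²/(2σ²))."""

    analyte: str
    center: float  # nm
    sigma: float  # nm
    peak_absorptivity: float  # mmol⁻¹·L·cm⁻¹

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.peak_absorptivity <= 0:
            raise ValueError("sigma and peak_absorptivity must be positive")

    def absorptivity(self, wavelengths: np.ndarray | float) -> np.ndarray | float:
        lam = np.asarray(wavelengths, dtype=float)
        eps = self.peak_absorptivity * np.exp(
            -((lam - self.center) ** 2) / (2.0 * self.sigma**2)
        )
        return float(eps) if np.isscalar(wavelengths) else eps


def _sigma_from_two_points(offset_nm: float, eps_off: float, eps_peak: float) -> float:
    """Width σ such that a Gaussian band drops from eps_peak to eps_off over
    ``offset_nm`` nanometers from its center."""
    return offset_nm / math.sqrt(2.0 * math.log(eps_peak / eps_off))


# The two analytical wavelengths sit 18 nm apart; each band's width is fixed
# by the published on-peak and off-peak absorptivities.
HMF_BAND = BandModel(
    "HMF", 284.0,
    _sigma_from_two_points(18.0, PUBLISHED_EPSILON["HMF"][266.0], PUBLISHED_EPSILON["HMF"][284.0]),
    PUBLISHED_EPSILON["HMF"][284.0],
)
LA_BAND = BandModel(
    "LA", 266.0,
    _sigma_from_two_points(18.0, PUBLISHED_EPSILON["LA"][284.0], PUBLISHED_EPSILON["LA"][266.0]),
    PUBLISHED_EPSILON["LA"][266.0],
)

BYPRODUCT = "byproduct"
NOISE = "noise"


@dataclass
class SyntheticConfig:
    """All knobs of the forward model; every random draw flows from ``seed``.

    Defaults reproduce the published absorptivities at 266/284 nm, the
    published correction coefficients, and the instrument's operating
    conditions (1 cm path, full charcoal dosage 0.1 g/mL). ``noise_sd`` is
    additive Gaussian absorbance noise (AU), truncated so total absorbance
    stays nonnegative. Kinetics rates place the HMF maximum near 24 min for
    a 3 g / 50 mL glucose charge (G0 ≈ 333 mmol/L).
    """

    bands: dict[str, BandModel] = field(
        default_factory=lambda: {"HMF": HMF_BAND, "LA": LA_BAND}
    )
    byproduct_center: float = 400.0  # nm
    byproduct_sigma: float = 30.0  # nm
    byproduct_amplitude: float = 0.5  # AU
    noise_sd: float = 0.005  # AU
    charcoal_dosage: float = FULL_TREATMENT_DOSAGE  # g/mL
    k_values: dict[str, float] = field(default_factory=lambda: dict(PUBLISHED_K))
    k1: float = 0.10  # 1/min, glucose → HMF
    k2: float = 0.012  # 1/min, HMF → LA
    g0: float = 333.0  # mmol/L initial glucose
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.charcoal_dosage < 0:
            raise ValueError("noise_sd and charcoal_dosage must be >= 0")
        if self.byproduct_sigma <= 0:
            raise ValueError("byproduct_sigma must be positive")
        for analyte, k in self.k_values.items():
            if k < 1:
                raise ValueError(f"K[{analyte}] must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_grid(start: float = 200.0, stop: float = 600.0, step: float = 1.0) -> np.ndarray:
    return np.arange(start, stop + 0.5 * step, step)


def render_spectrum(
    concentrations: Mapping[str, float],
    config: SyntheticConfig | None = None,
    grid: np.ndarray | Sequence[float] | None = None,
    *,
    path_length: float = 1.0,
    dilution_factor: float = 1.0,
    include_byproduct: bool = True,
    rng: np.random.Generator | None = None,
    label: str = "synthetic",
) -> Spectrum:
    """Render A(λ) = Σ ε_analyte(λ)·C_analyte·l + byproduct(λ) + noise.

    The returned :class:`Spectrum` carries its noiseless per-species
    contributions in ``components`` (keys: analyte names and ``"byproduct"``)
    so downstream treatment can act species-wise. Total absorbance is
    truncated at zero from below.
    """
    if config is None:
        config = SyntheticConfig()
    lam = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if lam.size == 0:
        raise ValueError("empty wavelength grid")
    if rng is None:
        rng = config.rng()

    components: dict[str, np.ndarray] = {}
    for analyte, c in concentrations.items():
        if c < 0:
            raise ValueError(f"concentration of {analyte} must be >= 0")
        band = config.bands[analyte]
        components[analyte] = band.absorptivity(lam) * c * path_length
    if include_byproduct and config.byproduct_amplitude > 0:
        components[BYPRODUCT] = config.byproduct_amplitude * np.exp(
            -((lam - config.byproduct_center) ** 2) / (2.0 * config.byproduct_sigma**2)
        )

    total = sum(components.values(), np.zeros_like(lam))
    if config.noise_sd > 0:
        total = total + rng.normal(0.0, config.noise_sd, size=lam.shape)
    total = np.maximum(total, 0.0)
    return Spectrum(
        lam, total,
        path_length=path_length,
        dilution_factor=dilution_factor,
        label=label,
        components=components,
    )


def _byproduct_factor(dosage: float) -> float:
    return max(0.0, 1.0 - dosage / FULL_TREATMENT_DOSAGE)


def _analyte_factor(dosage: float, k: float) -> float:
    # linear in dosage from 1 (untreated) to 1/K (full treatment and beyond)
    frac = min(dosage / FULL_TREATMENT_DOSAGE, 1.0)
    return 1.0 + (1.0 / k - 1.0) * frac


def charcoal_treat(
    spectrum: Spectrum,
    config: SyntheticConfig | None = None,
    dosage: float | None = None,
) -> Spectrum:
    """Apply the charcoal adsorption model to a rendered spectrum.

    The byproduct component is scaled by max(0, 1 − d/0.1) and each analyte
    component by the linear interpolation between 1 (d = 0) and 1/K
    (d ≥ 0.1 g/mL). Measurement noise (the residual between the stored
    total and the component sum) passes through unchanged, so dosage 0 is
    an exact identity. Requires a spectrum with ``components`` (i.e. one
    produced by :func:`render_spectrum`).
    """
    if config is None:
        config = SyntheticConfig()
    d = config.charcoal_dosage if dosage is None else dosage
    if d < 0:
        raise ValueError("charcoal dosage must be >= 0")
    if spectrum.components is None:
        raise ValueError(
            "charcoal_treat needs the per-species decomposition; "
            "use a spectrum produced by render_spectrum"
        )

    clean_total = sum(spectrum.components.values(), np.zeros_like(spectrum.wavelengths))
    residual = spectrum.absorbances - np.maximum(clean_total, 0.0)

    treated: dict[str, np.ndarray] = {}
    for species, contribution in spectrum.components.items():
        if species == BYPRODUCT:
            factor = _byproduct_factor(d)
        else:
            factor = _analyte_factor(d, config.k_values[species])
        treated[species] = contribution * factor

    total = sum(treated.values(), np.zeros_like(spectrum.wavelengths)) + residual
    return Spectrum(
        spectrum.wavelengths.copy(),
        np.maximum(total, 0.0),
        path_length=spectrum.path_length,
        dilution_factor=spectrum.dilution_factor,
        label=f"{spectrum.label}+charcoal({d:g} g/mL)",
        components=treated,
    )


def make_calibration_set(
    analyte: str,
    slope: float,
    intercept: float = 0.0,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength: float | None = None,
) -> CalibrationTable:
    """Generate a standard series: A_i = intercept + slope·C_i + noise.

    Defaults to the published standard concentrations for the analyte and
    to its characteristic wavelength (284 nm HMF, 266 nm LA). Reproducible
    under ``seed``.
    """
    if concentrations is None:
        concentrations = DEFAULT_CALIBRATION_CONCENTRATIONS[analyte]
    if wavelength is None:
        wavelength = {"HMF": 284.0, "LA": 266.0}.get(analyte, 284.0)
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    absb = intercept + slope * conc
    if noise_sd > 0:
        absb = absb + rng.normal(0.0, noise_sd, size=conc.shape)
    return CalibrationTable(
        analyte=analyte,
        points=list(zip(conc.tolist(), absb.tolist())),
        wavelength=wavelength,
    )


def simulate_hydrolysate_series(
    config: SyntheticConfig | None = None,
    times: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Closed-form consecutive first-order kinetics glucose → HMF → LA.

    glucose(t) = G0·e^(−k1·t);
    HMF(t) = G0·k1/(k2−k1)·(e^(−k1·t) − e^(−k2·t))  (k1 ≠ k2),
             G0·k1·t·e^(−k1·t)                        (k1 = k2);
    LA(t) = G0 − glucose(t) − HMF(t), so mass is conserved exactly.

    Returns a DataFrame with columns time_min, glucose, HMF, LA (mmol/L).
    """
    if config is None:
        config = SyntheticConfig()
    if config.k1 <= 0 or config.k2 <= 0:
        raise ValueError("rate constants k1, k2 must be positive")
    t = np.asarray(
        np.linspace(0.0, 120.0, 121) if times is None else times, dtype=float
    )
    if np.any(t < 0):
        raise ValueError("times must be >= 0")

    k1, k2, g0 = config.k1, config.k2, config.g0
    glucose = g0 * np.exp(-k1 * t)
    if k1 == k2:
        hmf = g0 * k1 * t * np.exp(-k1 * t)
    else:
        hmf = g0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    la = g0 - glucose - hmf
    return pd.DataFrame({"time_min": t, "glucose": glucose, "HMF": hmf, "LA": la})


def hmf_peak_time(k1: float, k2: float) -> float:
    """Time of the intermediate's unique maximum: ln(k1/k2)/(k1−k2), or 1/k1
    in the equal-rates limit."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if k1 == k2:
        return 1.0 / k1
    return math.log(k1 / k2) / (k1 - k2)
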