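"""Absorbance spectra and calibration tables: data model and file I/O.

A :class:`Spectrum` is a sampled UV-Vis absorbance curve A(λ) on a strictly
increasing wavelength grid, together with the cuvette path length (cm) and
the dilution factor R of the measured solution relative to the original
sample. Single-wavelength readings (e.g. A266, A284 for the dual-wavelength
method) are taken with :func:`absorbance_at`, which interpolates linearly
between grid points and never extrapolates.

File formats:

* CSV with the fixed header ``wavelength_nm,absorbance`` (comma separator,
  '.' decimal, UTF-8) — read/write, bit-identical round trip.
* A minimal read-only JCAMP-DX subset: single-block files whose numeric
  table is ``XYDATA=(X++(Y..Y))`` in plain (AFFN) form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "CalibrationTable",
    "SpectrumParseError",
    "SpectrumValidationError",
    "WavelengthRangeError",
    "read_spectrum",
    "write_spectrum",
    "absorbance_at",
    "read_calibration_table",
    "write_calibration_table",
]

CSV_HEADER = ("wavelength_nm", "absorbance")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed (message names the line)."""


class SpectrumValidationError(ValueError):
    """Parsed data violates a Spectrum invariant (e.g. duplicate wavelengths)."""


class WavelengthRangeError(ValueError):
    """Requested wavelength lies outside the sampled grid."""


@dataclass
class Spectrum:
    """A sampled absorbance curve with measurement metadata.

    Parameters
    ----------
    wavelengths : array-like of float
        Wavelength grid in nm, strictly increasing, length ≥ 2.
    absorbances : array-like of float
        Absorbance in AU, same length as ``wavelengths``.
    path_length : float, default 1.0
        Optical path length in cm (the instrument here uses a 1 cm flow cell).
    dilution_factor : float, default 1.0
        Dilution factor R ≥ 1 of the measured solution vs the original sample.
    label : str
        Free-text identifier.
    components : mapping or None
        Optional per-species decomposition of the curve (noiseless additive
        contributions, AU). Populated by the synthetic renderer; ``None`` for
        measured spectra.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    path_length: float = 1.0
    dilution_factor: float = 1.0
    label: str = ""
    components: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavelengths.ndim != 1 or self.absorbances.ndim != 1:
            raise SpectrumValidationError("wavelengths and absorbances must be 1-D")
        if len(self.wavelengths) != len(self.absorbances):
            raise SpectrumValidationError(
                f"length mismatch: {len(self.wavelengths)} wavelengths vs "
                f"{len(self.absorbances)} absorbances"
            )
        if len(self.wavelengths) < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise SpectrumValidationError("wavelength grid must be strictly increasing")
        if not self.path_length > 0:
            raise SpectrumValidationError("path_length must be positive")
        if not self.dilution_factor >= 1:
            raise SpectrumValidationError("dilution_factor R must be >= 1")

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class CalibrationTable:
    """Standard-series data for one analyte at one wavelength.

    ``points`` is a sequence of (concentration mmol/L, absorbance AU) pairs;
    at least three points with non-identical concentrations are required for
    a calibration fit.
    """

    analyte: str
    points: list[tuple[float, float]]
    wavelength: float

    def __post_init__(self) -> None:
        self.points = [(float(c), float(a)) for c, a in self.points]
        if len(self.points) < 3:
            raise SpectrumValidationError("a calibration table needs >= 3 points")
        if any(c < 0 for c, _ in self.points):
            raise SpectrumValidationError("concentrations must be >= 0")
        concs = [c for c, _ in self.points]
        if max(concs) == min(concs):
            raise SpectrumValidationError("concentrations must not all be equal")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points])

    @property
    def absorbances(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


# ---------------------------------------------------------------------------
# Spectrum I/O
# ---------------------------------------------------------------------------

def read_spectrum(
    path: str | Path,
    format: str = "csv",
    *,
    path_length: float = 1.0,
    dilution_factor: float = 1.0,
    label: str | None = None,
) -> Spectrum:
    """Read a spectrum from ``path``.

    ``format`` is ``"csv"`` (header ``wavelength_nm,absorbance``) or
    ``"jcampdx"``. Rows are sorted by wavelength on load; duplicate
    wavelengths raise :class:`SpectrumValidationError`, malformed rows raise
    :class:`SpectrumParseError` naming the line number.
    """
    path = Path(path)
    if format == "csv":
        wl, ab = _read_csv_pairs(path)
    elif format == "jcampdx":
        wl, ab = _read_jcampdx(path)
    else:
        raise ValueError(f"unknown spectrum format: {format!r}")

    order = np.argsort(wl, kind="stable")
    wl, ab = wl[order], ab[order]
    if np.any(np.diff(wl) <= 0):
        raise SpectrumValidationError(
            f"{path.name}: duplicate wavelengths in grid (non strictly increasing)"
        )
    return Spectrum(
        wl, ab,
        path_length=path_length,
        dilution_factor=dilution_factor,
        label=path.stem if label is None else label,
    )


def _read_csv_pairs(path: Path) -> tuple[np.ndarray, np.ndarray]:
    wavelengths: list[float] = []
    absorbances: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectrumParseError(f"{path.name}: empty file") from None
        if tuple(h.strip() for h in header) != CSV_HEADER:
            raise SpectrumParseError(
                f"{path.name}, line 1: expected header "
                f"'{','.join(CSV_HEADER)}', got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if len(row) != 2:
                raise SpectrumParseError(
                    f"{path.name}, line {lineno}: expected 2 fields, got {len(row)}"
                )
            try:
                wavelengths.append(float(row[0]))
                absorbances.append(float(row[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path.name}, line {lineno}: non-numeric value in {row!r}"
                ) from None
    return np.array(wavelengths), np.array(absorbances)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as CSV; values use shortest exact float repr, so a
    read → write → read cycle is bit-identical."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for wl, ab in zip(spectrum.wavelengths, spectrum.absorbances):
            writer.writerow([repr(float(wl)), repr(float(ab))])


def _read_jcampdx(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: single block, ``XYDATA=(X++(Y..Y))``, plain
    AFFN numbers (no SQZ/DIF compression)."""
    labels: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    in_data = False
    with open(path, encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$", 1)[0].strip()  # strip comments
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XYDATA":
                    if value.replace(" ", "") != "(X++(Y..Y))":
                        raise SpectrumParseError(
                            f"{path.name}, line {lineno}: unsupported XYDATA form {value!r}"
                        )
                    in_data = True
                elif key == "END":
                    in_data = False
                else:
                    labels[key] = value
            elif in_data:
                data_lines.append((lineno, line))
    if not data_lines:
        raise SpectrumParseError(f"{path.name}: no XYDATA=(X++(Y..Y)) block found")

    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))
    wavelengths: list[float] = []
    absorbances: list[float] = []
    deltax = None
    if "DELTAX" in labels:
        deltax = float(labels["DELTAX"])
    elif {"FIRSTX", "LASTX", "NPOINTS"} <= labels.keys():
        npoints = int(labels["NPOINTS"])
        if npoints > 1:
            deltax = (float(labels["LASTX"]) - float(labels["FIRSTX"])) / (npoints - 1)
    for lineno, line in data_lines:
        fields = line.replace(",", " ").split()
        try:
            numbers = [float(f) for f in fields]
        except ValueError:
            raise SpectrumParseError(
                f"{path.name}, line {lineno}: non-numeric value in data table"
            ) from None
        if len(numbers) < 2:
            raise SpectrumParseError(
                f"{path.name}, line {lineno}: data line needs an X value and >= 1 Y value"
            )
        x0, ys = numbers[0], numbers[1:]
        if deltax is None and len(ys) > 1:
            raise SpectrumParseError(
                f"{path.name}: multiple Y per line requires DELTAX or "
                "FIRSTX/LASTX/NPOINTS headers"
            )
        step = deltax if deltax is not None else 0.0
        for i, y in enumerate(ys):
            wavelengths.append((x0 + i * step) * xfactor)
            absorbances.append(y * yfactor)
    return np.array(wavelengths), np.array(absorbances)


# ---------------------------------------------------------------------------
# Reading single wavelengths off a sampled curve
# ---------------------------------------------------------------------------

def absorbance_at(spectrum: Spectrum, wavelength: float) -> float:
    """Absorbance at ``wavelength`` (nm) by linear interpolation.

    Exact grid hits return the stored value; wavelengths outside the grid
    raise :class:`WavelengthRangeError` (no extrapolation).
    """
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise WavelengthRangeError(
            f"{wavelength} nm outside sampled range [{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spectrum.absorbances))


# ---------------------------------------------------------------------------
# Calibration table I/O (CSV: concentration_mmol_L,absorbance)
# ---------------------------------------------------------------------------

CALIBRATION_CSV_HEADER = ("concentration_mmol_L", "absorbance")


def read_calibration_table(
    path: str | Path, analyte: str, wavelength: float
) -> CalibrationTable:
    """Read a calibration CSV with header ``concentration_mmol_L,absorbance``."""
    path = Path(path)
    points: list[tuple[float, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SpectrumParseError(f"{path.name}: empty file") from None
        if tuple(h.strip() for h in header) != CALIBRATION_CSV_HEADER:
            raise SpectrumParseError(
                f"{path.name}, line 1: expected header "
                f"'{','.join(CALIBRATION_CSV_HEADER)}'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                points.append((float(row[0]), float(row[1])))
            except (ValueError, IndexError):
                raise SpectrumParseError(
                    f"{path.name}, line {lineno}: malformed row {row!r}"
                ) from None
    return CalibrationTable(analyte=analyte, points=points, wavelength=wavelength)


def write_calibration_table(table: CalibrationTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALIBRATION_CSV_HEADER)
        for c, a in table.points:
            writer.writerow([repr(c), repr(a)])
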