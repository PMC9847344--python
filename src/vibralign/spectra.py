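"""Core domain types and file I/O for vibrational spectra.

A *line spectrum* is the stick output of a harmonic frequency calculation:
discrete (wavenumber, intensity) pairs per conformer and modality.  A
*continuous spectrum* is a broadened or measured spectrum on a uniform
wavenumber grid.  Peaks extracted by deconvolution are *pseudo-Voigt bands*
carrying position, height, bandwidth (FWHM) and mixing parameter.

All spectra are stored with ascending wavenumbers in cm^-1; display order is
a presentation concern.  VCD intensities stay signed end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "LineSpectrum",
    "ContinuousSpectrum",
    "PeakBand",
    "PeakList",
    "ConformerEnsemble",
    "SpectrumParseError",
    "read_continuous_spectrum",
    "write_continuous_spectrum",
    "read_line_spectra",
    "write_line_spectra",
    "read_peak_list",
    "write_peak_list",
    "write_alignment_report",
    "read_alignment_report",
]


class Modality(str, Enum):
    """Spectroscopic source of a spectrum or peak (the source index of a peak)."""

    IR = "IR"
    RAMAN = "RAMAN"
    VCD = "VCD"


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass(frozen=True)
class LineSpectrum:
    """Stick spectrum of one conformer for one modality.

    Wavenumbers must be strictly increasing and positive.  IR and Raman
    intensities are non-negative; VCD intensities may carry either sign.
    """

    modality: Modality
    wavenumbers: np.ndarray
    intensities: np.ndarray
    conformer_id: str = "conf0"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wn.shape != inten.shape or wn.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if wn.size and (np.any(wn <= 0) or np.any(np.diff(wn) <= 0)):
            raise ValueError("wavenumbers must be positive and strictly increasing")
        if self.modality is not Modality.VCD and np.any(inten < 0):
            raise ValueError(f"{self.modality.value} line intensities must be >= 0")
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass(frozen=True)
class ContinuousSpectrum:
    """Spectrum sampled on a uniform, ascending wavenumber grid."""

    modality: Modality
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.shape != values.shape:
            raise ValueError("grid and values must be 1-D and equal length")
        if grid.size >= 2:
            steps = np.diff(grid)
            if np.any(steps <= 0):
                raise ValueError("grid must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValueError("grid must be uniformly spaced")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def spacing(self) -> float:
        if self.grid.size < 2:
            raise ValueError("spacing undefined for spectra with fewer than 2 points")
        return float(self.grid[1] - self.grid[0])

    def __len__(self) -> int:
        return self.grid.size


@dataclass(frozen=True)
class PeakBand:
    """One pseudo-Voigt band: position x0, height I, FWHM w, mixing eta.

    ``eta`` interpolates between a Gaussian (0) and a Lorentzian (1) of the
    same height and FWHM.  ``origin`` records whether the band was fitted to
    an experimental or a theoretical spectrum; height is signed only for VCD.
    """

    x0: float
    I: float
    w: float
    eta: float
    source: Modality
    origin: str = "experimental"  # or "theoretical"
    flagged: bool = False  # set by the fitter for collapsed/degenerate bands

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("bandwidth w must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.origin not in ("experimental", "theoretical"):
            raise ValueError("origin must be 'experimental' or 'theoretical'")
        if self.source is not Modality.VCD and self.I <= 0:
            raise ValueError("IR/Raman band heights must be > 0")


@dataclass(frozen=True)
class PeakList:
    """Ordered list of bands, all sharing one origin.

    The constructor validates ordering (non-decreasing x0) and raises on
    violation rather than silently reordering.
    """

    peaks: tuple[PeakBand, ...]

    def __init__(self, peaks: Iterable[PeakBand]):
        peaks = tuple(peaks)
        xs = [p.x0 for p in peaks]
        if any(b < a for a, b in zip(xs, xs[1:])):
            raise ValueError("peaks must be ordered by non-decreasing x0")
        if len({p.origin for p in peaks}) > 1:
            raise ValueError("all peaks in a list must share one origin")
        object.__setattr__(self, "peaks", peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.x0 for p in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([p.I for p in self.peaks])

    def sorted(self) -> "PeakList":
        """Return a copy sorted by x0 (stable)."""
        return PeakList(sorted(self.peaks, key=lambda p: p.x0))


@dataclass(frozen=True)
class ConformerEnsemble:
    """Conformers of one isomer with relative free energies (kcal/mol).

    Each conformer supplies one line spectrum per modality; all conformers
    must provide the same modality set.  Energies are shifted so the minimum
    is zero.
    """

    isomer_id: str
    conformers: tuple[tuple[Mapping[Modality, LineSpectrum], float], ...]
    temperature: float = 298.15

    def __init__(
        self,
        isomer_id: str,
        conformers: Sequence[tuple[Mapping[Modality, LineSpectrum], float]],
        temperature: float = 298.15,
    ):
        if not conformers:
            raise ValueError("ensemble needs at least one conformer")
        mod_sets = [frozenset(spectra.keys()) for spectra, _ in conformers]
        if len(set(mod_sets)) != 1:
            raise ValueError("all conformers must provide the same modality set")
        emin = min(e for _, e in conformers)
        shifted = tuple((dict(spectra), float(e - emin)) for spectra, e in conformers)
        object.__setattr__(self, "isomer_id", isomer_id)
        object.__setattr__(self, "conformers", shifted)
        object.__setattr__(self, "temperature", float(temperature))

    @property
    def modalities(self) -> frozenset[Modality]:
        return frozenset(self.conformers[0][0].keys())

    @property
    def relative_energies(self) -> np.ndarray:
        return np.array([e for _, e in self.conformers])


# ---------------------------------------------------------------------------
# Continuous spectrum I/O
# ---------------------------------------------------------------------------

def read_continuous_spectrum(path: str | Path, modality: Modality) -> ContinuousSpectrum:
    """Read a two-column (wavenumber, intensity) text file.

    Whitespace- or comma-delimited; lines starting with '#' are comments.
    Data are sorted ascending; a non-uniform grid is resampled by linear
    interpolation at the median input spacing.
    """
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                x, y = float(parts[0]), float(parts[1])
            except (ValueError, IndexError) as exc:
                raise SpectrumParseError(
                    f"{path}: non-numeric or malformed data at line {lineno}: {raw!r}"
                ) from exc
            rows.append((x, y))
    if len(rows) < 4:
        # allow tiny files only when they are already uniform; the spec's
        # minimal example uses 3 rows on a uniform grid
        if len(rows) < 3:
            raise SpectrumParseError(f"{path}: insufficient data ({len(rows)} rows, need >= 3)")
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    x, y = arr[order, 0], arr[order, 1]
    if np.any(np.diff(x) == 0):
        raise SpectrumParseError(f"{path}: duplicate wavenumbers")
    steps = np.diff(x)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        h = float(np.median(steps))
        n = int(round((x[-1] - x[0]) / h)) + 1
        grid = x[0] + h * np.arange(n)
        grid = grid[grid <= x[-1] + 1e-9]
        y = np.interp(grid, x, y)
        x = grid
    return ContinuousSpectrum(modality=modality, grid=x, values=y)


def write_continuous_spectrum(spectrum: ContinuousSpectrum, path: str | Path) -> None:
    header = f"# modality: {spectrum.modality.value}\n# wavenumber_cm-1  intensity"
    np.savetxt(path, np.column_stack([spectrum.grid, spectrum.values]),
               fmt="%.8g", header=header, comments="")


# ---------------------------------------------------------------------------
# Ensemble (line spectra) I/O — JSON
# ---------------------------------------------------------------------------

def write_line_spectra(ensemble: ConformerEnsemble, path: str | Path) -> None:
    doc = {
        "isomer_id": ensemble.isomer_id,
        "temperature_K": ensemble.temperature,
        "conformers": [
            {
                "id": next(iter(spectra.values())).conformer_id,
                "dG_kcal_mol": energy,
                "modalities": {
                    mod.value: np.column_stack(
                        [spec.wavenumbers, spec.intensities]
                    ).tolist()
                    for mod, spec in sorted(spectra.items(), key=lambda kv: kv[0].value)
                },
            }
            for spectra, energy in ensemble.conformers
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_line_spectra(path: str | Path) -> ConformerEnsemble:
    """Read a conformer ensemble from the JSON format of :func:`write_line_spectra`.

    Missing ``dG_kcal_mol`` defaults to 0; energies are min-shifted on load.
    """
    doc = json.loads(Path(path).read_text())
    conformers = []
    for i, conf in enumerate(doc["conformers"]):
        cid = str(conf.get("id", f"conf{i}"))
        energy = float(conf.get("dG_kcal_mol", 0.0))
        spectra: dict[Modality, LineSpectrum] = {}
        for mod_name, table in conf["modalities"].items():
            arr = np.array(table, dtype=float).reshape(-1, 2)
            spectra[Modality(mod_name)] = LineSpectrum(
                modality=Modality(mod_name),
                wavenumbers=arr[:, 0],
                intensities=arr[:, 1],
                conformer_id=cid,
            )
        conformers.append((spectra, energy))
    return ConformerEnsemble(
        isomer_id=str(doc.get("isomer_id", Path(path).stem)),
        conformers=conformers,
        temperature=float(doc.get("temperature_K", 298.15)),
    )


# ---------------------------------------------------------------------------
# Peak list I/O — CSV with header x0,I,w,eta,modality,origin
# ---------------------------------------------------------------------------

def write_peak_list(peaks: PeakList, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "x0": [p.x0 for p in peaks],
            "I": [p.I for p in peaks],
            "w": [p.w for p in peaks],
            "eta": [p.eta for p in peaks],
            "modality": [p.source.value for p in peaks],
            "origin": [p.origin for p in peaks],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_peak_list(path: str | Path) -> PeakList:
    df = pd.read_csv(path)
    required = {"x0", "I", "w", "eta", "modality", "origin"}
    if not required.issubset(df.columns):
        raise SpectrumParseError(f"{path}: peak CSV must have columns {sorted(required)}")
    return PeakList(
        PeakBand(
            x0=float(r.x0), I=float(r.I), w=float(r.w), eta=float(r.eta),
            source=Modality(r.modality), origin=str(r.origin),
        )
        for r in df.itertuples()
    )


# ---------------------------------------------------------------------------
# Assessment report I/O — JSON
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_alignment_report(assessments: Sequence, path: str | Path) -> dict:
    """Write a JSON report of per-isomer, per-mu metrics plus a ranked summary.

    ``assessments`` are :class:`vibralign.metrics.IsomerAssessment` objects.
    Returns the document written (floats rounded to 6 significant digits so
    identical runs produce byte-identical files).
    """
    from .metrics import rank_isomers  # local import: avoid cycle

    if not assessments:
        raise ValueError("assessments must be non-empty")
    ranking = rank_isomers(list(assessments))
    doc = {
        "isomers": {a.isomer_id: a.to_dict() for a in assessments},
        "ranking": ranking.to_dict(),
    }
    doc = _round_floats(doc)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc


def read_alignment_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
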