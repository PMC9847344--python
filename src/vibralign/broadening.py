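"""Band shapes, Boltzmann weighting, and broadening of line spectra.

Both the Lorentzian L and the Gaussian G are *height*-parameterized with a
shared full width at half maximum w, so the pair (I, w) means the same thing
for every shape and mixing parameter:

    L(x0) = G(x0) = I,    L(x0 +/- w/2) = G(x0 +/- w/2) = I/2

The pseudo-Voigt profile is the convex mix V = eta*L + (1-eta)*G, hence
V(x0) = I for any eta.  Area-normalized forms would entangle the height with
w and eta, which the deconvolution treats as independent band attributes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import ConformerEnsemble, ContinuousSpectrum, LineSpectrum, Modality, PeakBand

__all__ = [
    "GAS_CONSTANT_KCAL",
    "BandShapeParams",
    "boltzmann_weights",
    "band_value",
    "broaden",
    "ensemble_spectrum",
    "default_grid",
]

#: molar gas constant in kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.987204258640832e-3

_FOUR_LN2 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class BandShapeParams:
    """Broadening band shape: lorentzian, gaussian, or pseudo_voigt.

    ``fwhm`` is the full width at half maximum in cm^-1 (default 12, the
    conventional Lorentzian bandwidth for broadening harmonic line spectra);
    ``eta`` is the Lorentzian fraction, used only for pseudo_voigt.
    """

    shape: str = "lorentzian"
    fwhm: float = 12.0
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.shape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")

    @property
    def effective_eta(self) -> float:
        return {"lorentzian": 1.0, "gaussian": 0.0, "pseudo_voigt": self.eta}[self.shape]


def boltzmann_weights(
    relative_free_energies: Sequence[float], temperature: float = 298.15
) -> np.ndarray:
    """Population weights w_i = exp(-dG_i/RT) / sum_j exp(-dG_j/RT).

    Energies in kcal/mol, temperature in K.  Computed with the max-shift
    trick so large energy gaps cannot overflow; weights sum to 1.
    """
    energies = np.asarray(relative_free_energies, dtype=float)
    if energies.size == 0:
        raise ValueError("need at least one energy")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    beta = 1.0 / (GAS_CONSTANT_KCAL * temperature)
    z = -beta * energies
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def _profile(x: np.ndarray, x0: float, w: float, eta: float) -> np.ndarray:
    """Unit-height pseudo-Voigt profile with FWHM w centred at x0."""
    u = (np.asarray(x, dtype=float) - x0) / w
    lor = 1.0 / (1.0 + 4.0 * u * u)
    gau = np.exp(-_FOUR_LN2 * u * u)
    return eta * lor + (1.0 - eta) * gau


def band_value(x, peak: PeakBand, shape: BandShapeParams | None = None):
    """Evaluate one band at x (scalar or array).

    If ``shape`` is given, its shape/eta/fwhm override the band's own eta and
    width (used when broadening stick lines, whose bands carry no fitted
    shape).  Otherwise the band's own (w, eta) are used.
    """
    if shape is not None:
        if shape.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        return peak.I * _profile(x, peak.x0, shape.fwhm, shape.effective_eta)
    return peak.I * _profile(x, peak.x0, peak.w, peak.eta)


def default_grid(lo: float, hi: float, fwhm: float = 12.0, step: float = 1.0) -> np.ndarray:
    """Analysis window padded by 3*FWHM each side, sampled at ``step`` cm^-1."""
    pad = 3.0 * fwhm
    return np.arange(lo - pad, hi + pad + 0.5 * step, step)


def broaden(
    line: LineSpectrum, shape: BandShapeParams, grid: np.ndarray
) -> ContinuousSpectrum:
    """Convolve a stick spectrum with the band shape on the given grid.

    Linear in the line list: broadening the union of two stick spectra equals
    the pointwise sum of broadening each.  An empty stick spectrum yields an
    all-zero spectrum.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    eta = shape.effective_eta
    for x0, inten in zip(line.wavenumbers, line.intensities):
        values += inten * _profile(grid, x0, shape.fwhm, eta)
    return ContinuousSpectrum(modality=line.modality, grid=grid, values=values)


def ensemble_spectrum(
    ensemble: ConformerEnsemble,
    modality: Modality,
    shape: BandShapeParams,
    grid: np.ndarray,
) -> ContinuousSpectrum:
    """Boltzmann-weighted sum of per-conformer broadened spectra."""
    if modality not in ensemble.modalities:
        raise ValueError(f"ensemble {ensemble.isomer_id} lacks modality {modality.value}")
    weights = boltzmann_weights(ensemble.relative_energies, ensemble.temperature)
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for (spectra, _), w in zip(ensemble.conformers, weights):
        total += w * broaden(spectra[modality], shape, grid).values
    return ContinuousSpectrum(modality=modality, grid=grid, values=total)
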