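"""Peak detection and simultaneous pseudo-Voigt deconvolution.

A measured (or broadened theoretical) spectrum is decomposed into as many
pseudo-Voigt bands as there are detected peaks, fitted simultaneously by
bounded least squares.  Strongly overlapping bands sum to an apparent
maximum above either underlying height; the fit recovers the underlying
heights, which is what the alignment scoring should see instead of the
inflated effective intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .broadening import _profile
from .spectra import ContinuousSpectrum, Modality, PeakBand, PeakList

__all__ = [
    "PeakDetectionConfig",
    "DeconvolutionResult",
    "detect_peaks",
    "fit_pseudo_voigts",
    "reconvolute",
]


@dataclass(frozen=True)
class PeakDetectionConfig:
    """Automatic peak-detection settings.

    ``min_prominence`` is a fraction of the spectrum maximum (of |values|,
    so negative VCD lobes are found too); ``min_separation`` is the minimum
    distance between accepted peaks in cm^-1.  ``manual_positions`` overrides
    detection entirely for noisy spectra where automation fails.
    """

    min_prominence: float = 0.02
    min_separation: float = 4.0
    manual_positions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.min_prominence < 1.0:
            raise ValueError("min_prominence must be in (0, 1)")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class DeconvolutionResult:
    bands: PeakList
    residual_rms: float
    converged: bool


def detect_peaks(
    spectrum: ContinuousSpectrum, cfg: PeakDetectionConfig = PeakDetectionConfig()
) -> list[float]:
    """Positions of local maxima of |values| with sufficient prominence.

    Returns wavenumbers; empty list when nothing clears the prominence
    threshold.  Manual positions, if configured, are returned sorted and
    verbatim after a range check.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    if cfg.manual_positions is not None:
        lo, hi = spectrum.grid[0], spectrum.grid[-1]
        for x in cfg.manual_positions:
            if not lo <= x <= hi:
                raise ValueError(f"manual position {x} outside grid [{lo}, {hi}]")
        return sorted(cfg.manual_positions)
    mag = np.abs(spectrum.values)
    vmax = mag.max()
    if vmax == 0:
        return []
    distance = max(1, int(round(cfg.min_separation / spectrum.spacing)))
    idx, _ = find_peaks(mag, prominence=cfg.min_prominence * vmax, distance=distance)
    return [float(spectrum.grid[i]) for i in idx]


def _model(params: np.ndarray, grid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(grid)
    for x0, height, w, eta in params.reshape(-1, 4):
        out += height * _profile(grid, x0, w, eta)
    return out


def _initial_width(spectrum: ContinuousSpectrum, x0: float, fallback: float = 12.0) -> float:
    """Half-maximum crossing distance around x0, or the fallback FWHM."""
    grid, values = spectrum.grid, np.abs(spectrum.values)
    i0 = int(np.argmin(np.abs(grid - x0)))
    half = values[i0] / 2.0
    if half <= 0:
        return fallback
    right = left = None
    for i in range(i0, len(grid)):
        if values[i] < half:
            right = grid[i] - x0
            break
    for i in range(i0, -1, -1):
        if values[i] < half:
            left = x0 - grid[i]
            break
    if right is None and left is None:
        return fallback
    if right is None:
        return 2.0 * left
    if left is None:
        return 2.0 * right
    return float(left + right)


def fit_pseudo_voigts(
    spectrum: ContinuousSpectrum,
    initial_positions: Sequence[float],
    *,
    origin: str = "experimental",
    max_nfev: int = 400,
    fit_offset: bool = False,
) -> DeconvolutionResult:
    """Fit one pseudo-Voigt band per initial position, simultaneously.

    Bounded least squares over all bands' (x0, I, w, eta): eta in [0, 1],
    w in [2*grid spacing, window/2], x0 within +/- 2*initial width of its
    starting point; heights are sign-free for VCD and non-negative otherwise.
    Spectra are assumed baseline-corrected; ``fit_offset`` adds a constant
    baseline term (off by default).

    Returns the bands sorted by position together with the RMS residual.
    Non-convergence still returns a result, with ``converged=False``.
    """
    positions = sorted(float(x) for x in initial_positions)
    if not positions:
        raise ValueError("need at least one initial position")
    grid, values = spectrum.grid, spectrum.values
    lo, hi = grid[0], grid[-1]
    for x in positions:
        if not lo <= x <= hi:
            raise ValueError(f"initial position {x} outside grid")
    spacing = spectrum.spacing
    w_min, w_max = 2.0 * spacing, (hi - lo) / 2.0
    signed = spectrum.modality is Modality.VCD
    scale = float(np.max(np.abs(values))) or 1.0

    p0, lb, ub = [], [], []
    for k, x0 in enumerate(positions):
        i0 = int(np.argmin(np.abs(grid - x0)))
        height = values[i0] if signed else max(values[i0], 1e-6 * scale)
        w0 = _initial_width(spectrum, x0)
        # in a fused cluster the half-maximum crossing spans several bands and
        # over-wide starts fall into smeared local minima: cap by the nearest
        # neighbouring start position
        gaps = [abs(positions[j] - x0) for j in (k - 1, k + 1) if 0 <= j < len(positions)]
        if gaps:
            w0 = min(w0, min(gaps))
        w0 = float(np.clip(w0, w_min, w_max))
        max_shift = 2.0 * w0
        p0 += [x0, height, w0, 0.5]
        lb += [x0 - max_shift, -10.0 * scale if signed else 0.0, w_min, 0.0]
        ub += [x0 + max_shift, 10.0 * scale, w_max, 1.0]
    if fit_offset:
        p0.append(0.0)
        lb.append(-scale)
        ub.append(scale)

    def residuals(p: np.ndarray) -> np.ndarray:
        if fit_offset:
            return _model(p[:-1], grid) + p[-1] - values
        return _model(p, grid) - values

    p0 = np.clip(np.asarray(p0, float), lb, ub)
    sol = least_squares(residuals, p0, bounds=(np.asarray(lb), np.asarray(ub)),
                        max_nfev=max_nfev, method="trf")
    params = sol.x[:-1] if fit_offset else sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    noise_floor = 1e-3 * scale
    bands = []
    for x0, height, w, eta in params.reshape(-1, 4):
        if not signed:
            height = max(height, 1e-12 * scale)  # keep constructor invariant
        collapsed = (np.isclose(w, w_min) or np.isclose(w, w_max)) and abs(height) < noise_floor
        bands.append(
            PeakBand(
                x0=float(x0), I=float(height), w=float(w),
                eta=float(np.clip(eta, 0.0, 1.0)),
                source=spectrum.modality, origin=origin,
                flagged=bool(collapsed),
            )
        )
    bands.sort(key=lambda b: b.x0)
    return DeconvolutionResult(
        bands=PeakList(bands), residual_rms=rms, converged=bool(sol.status > 0)
    )


def reconvolute(bands: PeakList, grid: np.ndarray, modality: Modality | None = None) -> ContinuousSpectrum:
    """Pointwise sum of all pseudo-Voigt bands on the grid.

    Uses each band's own (w, eta).  An empty band list gives a zero spectrum;
    then ``modality`` must be supplied.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.zeros_like(grid)
    for b in bands:
        values += b.I * _profile(grid, b.x0, b.w, b.eta)
    if modality is None:
        if len(bands) == 0:
            raise ValueError("modality required for an empty band list")
        modality = bands[0].source
    return ContinuousSpectrum(modality=modality, grid=grid, values=values)
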