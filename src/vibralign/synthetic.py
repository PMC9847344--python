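"""Synthetic paired experimental/theoretical fixtures.

Emulates the error structure the alignment is designed for: harmonic
frequency calculations carry a *systematic* error (removable with a constant
scaling factor, here the reciprocal of ``systematic_scale``) plus a
*stochastic* per-mode error (Gaussian jitter) that no global factor can fix.
Experimental bands are pseudo-Voigt with variable width and mixing, while
theoretical sticks are later broadened with a fixed pure Lorentzian, so the
generated pairs also reproduce the band-shape mismatch the deconvolution
must absorb.

Everything is deterministic under ``SyntheticConfig.seed``; the individual
operations draw from independent, tagged substreams of that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import AnalysisWindow
from .deconvolution import reconvolute
from .spectra import ContinuousSpectrum, LineSpectrum, Modality, PeakBand, PeakList

__all__ = [
    "SyntheticConfig",
    "make_truth",
    "derive_theoretical",
    "render_experimental",
    "make_isomer_decoys",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic fixtures.

    systematic_scale  -- true 1/mu: theoretical frequencies are the ground
                         truth divided by this factor (0.975, the typical
                         best scaling factor for hybrid-DFT harmonic spectra
                         in the fingerprint region).
    jitter_sd         -- per-peak stochastic frequency error, cm^-1.
    intensity_noise_sd-- relative intensity noise on theoretical sticks.
    exp_fwhm_range    -- experimental bandwidth range, cm^-1.
    theo_fwhm         -- Lorentzian bandwidth used to broaden theory, cm^-1.
    eta_range         -- experimental pseudo-Voigt mixing range.
    baseline_noise_sd -- additive baseline noise, fraction of the rendered max.
    min_separation    -- minimum truth-peak separation; defaults to half the
                         mean experimental FWHM so the overlap regime is
                         present but identifiable.
    overlap_pair      -- force one pair of bands closer than one FWHM, the
                         strongly overlapping case.
    """

    n_peaks: int = 8
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    systematic_scale: float = 0.975
    jitter_sd: float = 3.0
    intensity_noise_sd: float = 0.10
    exp_fwhm_range: tuple[float, float] = (10.0, 18.0)
    theo_fwhm: float = 12.0
    eta_range: tuple[float, float] = (0.3, 0.9)
    baseline_noise_sd: float = 0.005
    min_separation: float | None = None
    overlap_pair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        for name in ("jitter_sd", "intensity_noise_sd", "baseline_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.systematic_scale <= 0:
            raise ValueError("systematic_scale must be > 0")

    @property
    def separation(self) -> float:
        if self.min_separation is not None:
            return self.min_separation
        return 0.5 * (self.exp_fwhm_range[0] + self.exp_fwhm_range[1]) / 2.0


def _rng(cfg: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def make_truth(cfg: SyntheticConfig, modality: Modality = Modality.IR) -> PeakList:
    """Ground-truth experimental band set; correspondence is positional.

    Positions are uniform in the window with the minimum separation enforced
    (sorted-uniform construction on the gap-shrunk window), heights uniform
    in (0.2, 1.0], widths and mixing uniform in their configured ranges.
    VCD truths get random signs on the heights.
    """
    rng = _rng(cfg, 0)
    lo, hi = cfg.window.lo, cfg.window.hi
    sep = cfg.separation
    usable = (hi - lo) - (cfg.n_peaks - 1) * sep
    if usable <= 0:
        raise ValueError(
            f"window too small for {cfg.n_peaks} peaks at separation {sep}"
        )
    y = np.sort(rng.uniform(lo, lo + usable, cfg.n_peaks))
    positions = y + sep * np.arange(cfg.n_peaks)
    if cfg.overlap_pair and cfg.n_peaks >= 2:
        # squeeze the central pair to below one experimental FWHM
        mid = cfg.n_peaks // 2
        gap = 0.6 * cfg.exp_fwhm_range[0]
        positions[mid] = positions[mid - 1] + gap
        positions = np.sort(positions)
    heights = rng.uniform(0.2, 1.0, cfg.n_peaks)
    widths = rng.uniform(*cfg.exp_fwhm_range, cfg.n_peaks)
    etas = rng.uniform(*cfg.eta_range, cfg.n_peaks)
    if modality is Modality.VCD:
        heights = heights * rng.choice([-1.0, 1.0], cfg.n_peaks)
    return PeakList(
        PeakBand(
            x0=float(x), I=float(h), w=float(w), eta=float(e),
            source=modality, origin="experimental",
        )
        for x, h, w, e in zip(positions, heights, widths, etas)
    )


def derive_theoretical(truth: PeakList, cfg: SyntheticConfig) -> LineSpectrum:
    """Stick spectrum a harmonic calculation would give for the truth.

    Frequencies: x0 / systematic_scale + N(0, jitter_sd); intensities:
    I * (1 + N(0, intensity_noise_sd)), clipped positive for IR/Raman.
    """
    rng = _rng(cfg, 1)
    modality = truth[0].source if len(truth) else Modality.IR
    freqs = np.array([p.x0 for p in truth]) / cfg.systematic_scale
    freqs = freqs + rng.normal(0.0, cfg.jitter_sd, len(truth))
    inten = np.array([p.I for p in truth]) * (
        1.0 + rng.normal(0.0, cfg.intensity_noise_sd, len(truth))
    )
    if modality is not Modality.VCD:
        inten = np.clip(inten, 1e-6, None)
    order = np.argsort(freqs)
    return LineSpectrum(
        modality=modality,
        wavenumbers=freqs[order],
        intensities=inten[order],
        conformer_id="synthetic",
    )


def render_experimental(
    truth: PeakList, cfg: SyntheticConfig, grid: np.ndarray
) -> ContinuousSpectrum:
    """Reconvolute the truth bands and add baseline noise on the grid."""
    clean = reconvolute(truth, np.asarray(grid, dtype=float))
    if cfg.baseline_noise_sd == 0:
        return clean
    rng = _rng(cfg, 2)
    sd = cfg.baseline_noise_sd * float(np.max(np.abs(clean.values)))
    noisy = clean.values + rng.normal(0.0, sd, clean.grid.size)
    return ContinuousSpectrum(modality=clean.modality, grid=clean.grid, values=noisy)


def _derangement(rng: np.random.Generator, indices: np.ndarray) -> np.ndarray:
    """Random permutation of ``indices`` with no fixed point (rejection sampled)."""
    while True:
        perm = rng.permutation(indices)
        if not np.any(perm == indices):
            return perm


def make_isomer_decoys(
    truth: PeakList, k: int, severity: float, cfg: SyntheticConfig
) -> list[LineSpectrum]:
    """Stick spectra of k wrong isomers.

    Each decoy reuses the truth's systematic scale and jitter but perturbs a
    random subset (at least 30% of the peaks, minimum two) of peaks:
    frequency shifts drawn from N(0, severity * jitter_sd) and a derangement
    of the subset's intensities (a permutation without fixed points, so every
    perturbed peak's height really changes) — wrong diastereomers differ in
    both peak positions and intensity patterns.  severity = 0 degenerates to
    an ordinary theoretical spectrum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    modality = truth[0].source if len(truth) else Modality.IR
    n = len(truth)
    decoys = []
    for d in range(k):
        rng = _rng(cfg, 10 + d)
        freqs = np.array([p.x0 for p in truth]) / cfg.systematic_scale
        freqs = freqs + rng.normal(0.0, cfg.jitter_sd, n)
        inten = np.array([p.I for p in truth]) * (
            1.0 + rng.normal(0.0, cfg.intensity_noise_sd, n)
        )
        if severity > 0:
            n_pert = min(n, max(2, int(np.ceil(0.3 * n)))) if n >= 2 else 1
            subset = rng.choice(n, size=n_pert, replace=False)
            freqs[subset] += rng.normal(0.0, severity * cfg.jitter_sd, n_pert)
            if n_pert >= 2:
                inten[subset] = inten[_derangement(rng, subset)]
        if modality is not Modality.VCD:
            inten = np.clip(inten, 1e-6, None)
        order = np.argsort(freqs)
        decoys.append(
            LineSpectrum(
                modality=modality,
                wavenumbers=freqs[order],
                intensities=inten[order],
                conformer_id=f"decoy{d}",
            )
        )
    return decoys
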