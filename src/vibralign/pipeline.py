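"""End-to-end workflows: deconvolute, align, screen, and rank isomers.

These helpers glue the stages together the way a full run proceeds:
theoretical stick spectra are Boltzmann-weighted and broadened, both sides
are deconvoluted into pseudo-Voigt bands, the bands are aligned over a grid
of frequency scaling factors, and the isomers are ranked by the combined
score.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .alignment import ScoringConfig
from .broadening import BandShapeParams, ensemble_spectrum
from .deconvolution import (
    DeconvolutionResult,
    PeakDetectionConfig,
    detect_peaks,
    fit_pseudo_voigts,
)
from .metrics import (
    DEFAULT_MU_GRID,
    AnalysisWindow,
    IsomerAssessment,
    Ranking,
    rank_isomers,
    screen_mu,
)
from .spectra import ConformerEnsemble, ContinuousSpectrum, LineSpectrum, Modality
from .synthetic import (
    SyntheticConfig,
    derive_theoretical,
    make_isomer_decoys,
    make_truth,
    render_experimental,
)

__all__ = [
    "deconvolute_spectrum",
    "theoretical_bands",
    "assess_isomers",
    "ranking_experiment",
]


def deconvolute_spectrum(
    spectrum: ContinuousSpectrum,
    detection: PeakDetectionConfig = PeakDetectionConfig(),
    origin: str = "experimental",
) -> DeconvolutionResult:
    """Detect peaks and fit one pseudo-Voigt band per detected peak."""
    positions = detect_peaks(spectrum, detection)
    if not positions:
        raise ValueError("no peaks detected; lower min_prominence or supply manual positions")
    return fit_pseudo_voigts(spectrum, positions, origin=origin)


def theoretical_bands(
    ensemble: ConformerEnsemble,
    modality: Modality,
    window: AnalysisWindow,
    shape: BandShapeParams = BandShapeParams(),
    detection: PeakDetectionConfig = PeakDetectionConfig(),
) -> DeconvolutionResult:
    """Boltzmann-weight, broaden, and deconvolute one isomer's line spectra."""
    pad = 3.0 * shape.fwhm
    grid = np.arange(window.lo - pad, window.hi + pad + 0.5 * window.step, window.step)
    spec = ensemble_spectrum(ensemble, modality, shape, grid)
    return deconvolute_spectrum(spec, detection, origin="theoretical")


def assess_isomers(
    exp_spectra: Mapping[Modality, ContinuousSpectrum],
    ensembles: Sequence[ConformerEnsemble],
    window: AnalysisWindow = AnalysisWindow(),
    shape: BandShapeParams = BandShapeParams(),
    detection: PeakDetectionConfig = PeakDetectionConfig(),
    scoring: ScoringConfig = ScoringConfig(),
    mu_grid: Sequence[float] = DEFAULT_MU_GRID,
) -> tuple[list[IsomerAssessment], Ranking]:
    """Screen every isomer over the mu grid and rank by best combined score."""
    mods = sorted(exp_spectra, key=lambda m: m.value)
    exp_bands = {m: deconvolute_spectrum(exp_spectra[m], detection).bands for m in mods}
    assessments = []
    for ens in ensembles:
        theo_bands = {
            m: theoretical_bands(ens, m, window, shape, detection).bands for m in mods
        }
        assessments.append(
            screen_mu(
                exp_spectra, exp_bands, theo_bands,
                window=window, cfg=scoring, mu_grid=mu_grid, isomer_id=ens.isomer_id,
            )
        )
    return assessments, rank_isomers(assessments)


def ranking_experiment(
    n_seeds: int = 100,
    k_decoys: int = 3,
    severity: float = 5.0,
    base_seed: int = 0,
    cfg: SyntheticConfig | None = None,
    mu_grid: Sequence[float] = DEFAULT_MU_GRID,
) -> int:
    """Seeded replicates of the decoy experiment; returns the success count.

    Each replicate builds a ground-truth band set, renders a noisy
    experimental spectrum, derives the matching theoretical stick spectrum
    plus ``k_decoys`` perturbed wrong-isomer spectra, runs the full pipeline
    (broaden, deconvolute, align over the mu grid), and counts a success when
    the generating spectrum ranks first by s_comb.
    """
    template = cfg or SyntheticConfig()
    window = template.window
    shape = BandShapeParams(shape="lorentzian", fwhm=template.theo_fwhm)
    successes = 0
    for r in range(n_seeds):
        rcfg = dataclasses.replace(template, seed=int(base_seed) + r)
        truth = make_truth(rcfg)
        pad = 3.0 * max(rcfg.exp_fwhm_range[1], rcfg.theo_fwhm)
        grid = np.arange(window.lo - pad, window.hi + pad + 0.5 * window.step, window.step)
        exp_spec = render_experimental(truth, rcfg, grid)
        lines = {"true": derive_theoretical(truth, rcfg)}
        for d, decoy in enumerate(make_isomer_decoys(truth, k_decoys, severity, rcfg)):
            lines[f"decoy{d}"] = decoy
        ensembles = [
            ConformerEnsemble(isomer_id=name, conformers=[({Modality.IR: ls}, 0.0)])
            for name, ls in lines.items()
        ]
        _, ranking = assess_isomers(
            {Modality.IR: exp_spec}, ensembles, window=window, shape=shape, mu_grid=mu_grid
        )
        if ranking.order[0] == "true":
            successes += 1
    return successes
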