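"""Quantitative assessment of aligned spectra and isomer ranking.

After alignment, both the experimental spectrum and the shifted-and-
reconvoluted theoretical spectrum are resampled on a common fingerprint
window (cubic splines, 1 cm^-1 steps) and compared with the Pearson
correlation r_P (overlap), the Spearman correlation r_S (shape/derivative
information), and the alignment score s (work performed by the alignment).
The combined score

    s_comb = s * prod over modalities of (r_P * r_S)

is the ranking quantity: its absolute value carries no meaning, but the best
matching isomer should attain the highest value.  Because the harmonic
frequency-scaling factor is method- and compound-dependent, s_comb is
screened over a grid of scaling factors mu and the per-isomer maximum is
compared; the s_comb(mu) curve is typically bell-shaped.

For VCD the correlations are signed: a mirror-image (wrong) enantiomer
produces anti-correlated VCD spectra while IR metrics are unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import pearsonr, spearmanr

from .alignment import (
    Alignment,
    ScoringConfig,
    align_multisource,
    align_peaks,
    normalize_intensities,
    shift_theoretical,
)
from .deconvolution import reconvolute
from .spectra import ContinuousSpectrum, Modality, PeakList

__all__ = [
    "AnalysisWindow",
    "MuRecord",
    "IsomerAssessment",
    "Ranking",
    "DEFAULT_MU_GRID",
    "resample",
    "pearson",
    "spearman",
    "combined_score",
    "screen_mu",
    "rank_isomers",
    "enantiomer_sign",
    "assessment_table",
]

#: default screening grid for the frequency scaling factor: 0.94..1.02 step 0.005
DEFAULT_MU_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.94, 1.0201, 0.005), 4))


@dataclass(frozen=True)
class AnalysisWindow:
    """Wavenumber window used for resampling and correlation (default step 1).

    The fingerprint region 1000-1500 cm^-1 is the usual choice; 1150-1500 for
    DMSO-d6 spectra, whose solvent bands obscure the lower range.
    """

    lo: float = 1000.0
    hi: float = 1500.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError("lo must be < hi")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 0.5 * self.step, self.step)


@dataclass(frozen=True)
class MuRecord:
    """Metrics at one scaling factor."""

    mu: float
    s: float
    r_pearson: Mapping[Modality, float]
    r_spearman: Mapping[Modality, float]
    s_comb: float

    def to_dict(self) -> dict:
        d: dict = {"mu": self.mu, "s": self.s, "s_comb": self.s_comb}
        for mod in sorted(self.r_pearson, key=lambda m: m.value):
            d[f"rP_{mod.value}"] = self.r_pearson[mod]
            d[f"rS_{mod.value}"] = self.r_spearman[mod]
        return d


@dataclass(frozen=True)
class IsomerAssessment:
    """Full mu-screening record for one isomer."""

    isomer_id: str
    records: tuple[MuRecord, ...]
    pairs_at_best: Mapping[Modality, tuple[tuple[float, float, float], ...]] = None  # type: ignore[assignment]

    @property
    def best_record(self) -> MuRecord:
        return max(self.records, key=lambda r: (r.s_comb, -abs(r.mu - 1.0)))

    @property
    def best_mu(self) -> float:
        return self.best_record.mu

    @property
    def best_s_comb(self) -> float:
        return self.best_record.s_comb

    def to_dict(self) -> dict:
        d = {
            "isomer_id": self.isomer_id,
            "best_mu": self.best_mu,
            "best_s_comb": self.best_s_comb,
            "records": [r.to_dict() for r in self.records],
        }
        if self.pairs_at_best:
            d["matched_pairs_at_best"] = {
                mod.value: [list(t) for t in pairs]
                for mod, pairs in self.pairs_at_best.items()
            }
        return d


@dataclass(frozen=True)
class Ranking:
    """Isomers sorted by best combined score, with the best/second-best ratio."""

    order: tuple[str, ...]
    best_s_comb: Mapping[str, float]
    ratio: float | None

    def to_dict(self) -> dict:
        return {
            "order": list(self.order),
            "best_s_comb": dict(self.best_s_comb),
            "ratio": self.ratio,
        }


def resample(spectrum: ContinuousSpectrum, window: AnalysisWindow) -> ContinuousSpectrum:
    """Natural cubic-spline interpolation of the spectrum onto the window grid."""
    if window.lo < spectrum.grid[0] - 1e-9 or window.hi > spectrum.grid[-1] + 1e-9:
        raise ValueError(
            f"window [{window.lo}, {window.hi}] outside spectrum grid "
            f"[{spectrum.grid[0]}, {spectrum.grid[-1]}]"
        )
    spline = CubicSpline(spectrum.grid, spectrum.values, bc_type="natural")
    grid = window.grid
    return ContinuousSpectrum(modality=spectrum.modality, grid=grid, values=spline(grid))


def _check_comparable(a: ContinuousSpectrum, b: ContinuousSpectrum) -> None:
    if a.grid.shape != b.grid.shape or not np.allclose(a.grid, b.grid):
        raise ValueError("spectra must share an identical grid")
    for v, name in ((a.values, "first"), (b.values, "second")):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} spectrum is constant; correlation undefined")


def pearson(a: ContinuousSpectrum, b: ContinuousSpectrum) -> float:
    """Product-moment correlation of two spectra on identical grids."""
    _check_comparable(a, b)
    return float(pearsonr(a.values, b.values).statistic)


def spearman(a: ContinuousSpectrum, b: ContinuousSpectrum) -> float:
    """Rank correlation (ties by average rank) of two spectra on identical grids."""
    _check_comparable(a, b)
    return float(spearmanr(a.values, b.values).statistic)


def combined_score(s: float, correlations: Mapping[Modality, tuple[float, float]]) -> float:
    """s times the product of every modality's (r_P, r_S); signed."""
    out = s
    for r_p, r_s in correlations.values():
        out *= r_p * r_s
    return out


def screen_mu(
    exp_spectra: Mapping[Modality, ContinuousSpectrum],
    exp_peaks: Mapping[Modality, PeakList],
    theo_peaks: Mapping[Modality, PeakList],
    window: AnalysisWindow = AnalysisWindow(),
    cfg: ScoringConfig = ScoringConfig(),
    mu_grid: Sequence[float] = DEFAULT_MU_GRID,
    isomer_id: str = "isomer0",
) -> IsomerAssessment:
    """Evaluate all metrics for one isomer over a grid of scaling factors.

    For each mu: align the (normalized) theoretical peaks to the experimental
    ones (multi-source when several modalities are supplied), shift the
    theoretical bands onto their matched positions, reconvolute, resample
    both spectra on the window grid, and compute r_P/r_S per modality, the
    alignment score s, and s_comb.  A mu where the alignment finds no match
    records s_comb = 0.
    """
    if not mu_grid:
        raise ValueError("mu grid must be non-empty")
    mods = sorted(exp_spectra, key=lambda m: m.value)
    if set(exp_peaks) != set(mods) or set(theo_peaks) != set(mods):
        raise ValueError("exp_spectra, exp_peaks, theo_peaks must share one modality set")
    exp_norm = {m: normalize_intensities(exp_peaks[m]) for m in mods}
    theo_norm = {m: normalize_intensities(theo_peaks[m]) for m in mods}
    exp_resampled = {m: resample(exp_spectra[m], window) for m in mods}
    pad = 3.0 * max(max(p.w for p in theo_norm[m]) for m in mods)
    recon_grid = np.arange(window.lo - pad, window.hi + pad + 0.5 * window.step, window.step)

    records = []
    best_pairs: Mapping[Modality, tuple] | None = None
    best_s_comb = -np.inf
    for mu in mu_grid:
        mu_cfg = replace(cfg, mu=float(mu))
        if len(mods) == 1:
            mod = mods[0]
            aln = align_peaks(exp_norm[mod], theo_norm[mod], mu_cfg)
            per_source = {mod: aln}
            s = aln.total_score
        else:
            multi = align_multisource(exp_norm, theo_norm, mu_cfg)
            per_source = dict(multi.by_source)
            s = multi.total_score
        r_p: dict[Modality, float] = {}
        r_s: dict[Modality, float] = {}
        for mod in mods:
            shifted = shift_theoretical(theo_norm[mod], per_source[mod], exp_norm[mod])
            theo_spec = reconvolute(shifted, recon_grid, modality=mod)
            theo_win = resample(theo_spec, window)
            try:
                r_p[mod] = pearson(exp_resampled[mod], theo_win)
                r_s[mod] = spearman(exp_resampled[mod], theo_win)
            except ValueError:  # constant spectrum: no usable correlation
                r_p[mod] = 0.0
                r_s[mod] = 0.0
        s_comb = combined_score(s, {m: (r_p[m], r_s[m]) for m in mods})
        records.append(MuRecord(mu=float(mu), s=s, r_pearson=r_p, r_spearman=r_s, s_comb=s_comb))
        if s_comb > best_s_comb:
            best_s_comb = s_comb
            best_pairs = {
                m: tuple(
                    (exp_norm[m][i].x0, theo_norm[m][j].x0, sc)
                    for i, j, sc in per_source[m].pairs
                )
                for m in mods
            }
    return IsomerAssessment(
        isomer_id=isomer_id, records=tuple(records), pairs_at_best=best_pairs
    )


def rank_isomers(assessments: Sequence[IsomerAssessment]) -> Ranking:
    """Sort isomers by best s_comb (descending, stable by isomer_id on ties).

    The ratio of the best to the second-best s_comb is a descriptive
    confidence indicator: values close to 1 mean both candidates describe the
    experiment similarly well.  Reported unrounded; absent for one isomer.
    """
    if not assessments:
        raise ValueError("need at least one assessment")
    ordered = sorted(assessments, key=lambda a: (-a.best_s_comb, a.isomer_id))
    scores = {a.isomer_id: a.best_s_comb for a in ordered}
    ratio = None
    if len(ordered) > 1 and ordered[1].best_s_comb != 0:
        ratio = ordered[0].best_s_comb / ordered[1].best_s_comb
    return Ranking(order=tuple(a.isomer_id for a in ordered), best_s_comb=scores, ratio=ratio)


def enantiomer_sign(
    vcd_r_p: float, vcd_r_s: float, threshold: float = 0.05
) -> str:
    """Classify the VCD correlation signs.

    Both correlations positive: the computed enantiomer matches experiment;
    both negative: the mirror image was computed; mixed signs or magnitudes
    below the threshold: no call.
    """
    for r in (vcd_r_p, vcd_r_s):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must be in [-1, 1]")
    if abs(vcd_r_p) < threshold or abs(vcd_r_s) < threshold:
        return "ambiguous"
    if vcd_r_p > 0 and vcd_r_s > 0:
        return "correct_enantiomer"
    if vcd_r_p < 0 and vcd_r_s < 0:
        return "mirror_enantiomer"
    return "ambiguous"


def assessment_table(assessments: Sequence[IsomerAssessment]) -> pd.DataFrame:
    """One row per isomer x mu with fixed columns.

    Columns: isomer, mu, s, rP_IR, rS_IR, rP_X, rS_X, s_comb where X is the
    run's non-IR modality (Raman or VCD); the X columns are NaN for runs with
    only one modality.
    """
    rows = []
    for a in assessments:
        for rec in a.records:
            other = [m for m in rec.r_pearson if m is not Modality.IR]
            row = {
                "isomer": a.isomer_id,
                "mu": rec.mu,
                "s": rec.s,
                "rP_IR": rec.r_pearson.get(Modality.IR, np.nan),
                "rS_IR": rec.r_spearman.get(Modality.IR, np.nan),
                "rP_X": rec.r_pearson[other[0]] if other else np.nan,
                "rS_X": rec.r_spearman[other[0]] if other else np.nan,
                "s_comb": rec.s_comb,
            }
            rows.append(row)
    return pd.DataFrame(rows, columns=["isomer", "mu", "s", "rP_IR", "rS_IR", "rP_X", "rS_X", "s_comb"])
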