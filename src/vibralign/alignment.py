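"""Optimal monotone matching of theoretical to experimental peak lists.

Peaks are treated like letters in strings and aligned globally by dynamic
programming (Needleman-Wunsch style): each peak is either matched to a peak
of the other list or to a gap, and the order of peaks is strictly preserved.
The pairwise score is a product of three compactly supported mollifier
kernels in frequency, intensity, and bandwidth, so two peaks that differ too
much in any one attribute cannot be matched at all.  Every peak contributes
equally to the total score regardless of its intensity, which makes the
alignment score complementary to overlap metrics such as Pearson/Spearman
correlation.

The theoretical frequency axis is multiplied once by a constant scaling
factor mu before scoring, to correct the systematic error of the harmonic
approximation; the alignment itself absorbs the residual stochastic error
peak by peak.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .spectra import Modality, PeakBand, PeakList

__all__ = [
    "ScoringConfig",
    "LegacyScoringConfig",
    "Alignment",
    "MultiSourceAlignment",
    "normalize_intensities",
    "mollifier",
    "pair_score",
    "legacy_pair_score",
    "align_peaks",
    "shift_theoretical",
    "align_multisource",
    "alignment_to_json",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Cutoff-based product scoring.

    mu     -- frequency scaling factor applied (once) to theoretical positions.
    C_nu   -- cutoff for the frequency difference, cm^-1; roughly the scale of
              the stochastic harmonic error.
    C_I    -- cutoff for the intensity difference, in max-normalized units.
    C_w    -- cutoff for the bandwidth difference, cm^-1.
    gap_score -- contribution of an unmatched peak (0: gaps are free but
              unrewarded; the cutoffs already forbid bad matches).
    normalize_score -- divide the raw optimum by max(n_exp, n_theo) so the
              total score is comparable across isomers and lies in [0, 1].
    """

    mu: float = 1.0
    C_nu: float = 30.0
    C_I: float = 0.5
    C_w: float = 20.0
    gap_score: float = 0.0
    normalize_score: bool = True

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if min(self.C_nu, self.C_I, self.C_w) <= 0:
            raise ValueError("all cutoffs must be > 0")


@dataclass(frozen=True)
class LegacyScoringConfig:
    """Spread parameters of the earlier two-term (intensity + frequency) score."""

    sigma1: float
    sigma2: float
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("sigma1 and sigma2 must be > 0")


@dataclass(frozen=True)
class Alignment:
    """Monotone matching between an experimental and a theoretical peak list.

    ``pairs`` holds (exp index, theo index, pair score) with both index
    sequences strictly increasing; ``exp_gaps``/``theo_gaps`` list the
    unmatched indices.  ``total_score`` is the (optionally normalized) DP
    optimum; ``raw_score`` the plain sum of pair scores plus gap scores.
    """

    pairs: tuple[tuple[int, int, float], ...]
    exp_gaps: tuple[int, ...]
    theo_gaps: tuple[int, ...]
    total_score: float
    raw_score: float
    config: ScoringConfig


@dataclass(frozen=True)
class MultiSourceAlignment:
    """Per-modality alignments from one combined multi-source run."""

    by_source: Mapping[Modality, Alignment]
    total_score: float
    raw_score: float
    config: ScoringConfig


def normalize_intensities(peaks: PeakList) -> PeakList:
    """Scale heights so max |I| = 1 within the list; signs are preserved.

    Needed because measured absorbance and computed intensities live on
    unrelated scales.  Idempotent; raises when every height is zero.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    scale = max(abs(p.I) for p in peaks)
    if scale == 0:
        raise ValueError("cannot normalize an all-zero peak list")
    return PeakList(replace(p, I=p.I / scale) for p in peaks)


def mollifier(delta: float, cutoff: float) -> float:
    """Smooth bump kernel: 1 at delta=0, exactly 0 for |delta| >= cutoff.

    exp(1 - 1/(1 - (delta/cutoff)^2)) inside the support; infinitely
    differentiable and strictly decreasing in |delta| on (0, cutoff).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    t = delta / cutoff
    t2 = t * t
    if t2 >= 1.0:
        return 0.0
    return math.exp(1.0 - 1.0 / (1.0 - t2))


def pair_score(exp: PeakBand, theo: PeakBand, cfg: ScoringConfig) -> float:
    """Product of frequency, intensity, and bandwidth mollifier components.

    The theoretical position is scaled by cfg.mu; intensities are compared on
    magnitudes (the score is insensitive to the VCD sign, which enters only
    through the correlation metrics).  Zero whenever any component is zero,
    so a high-intensity peak can never be matched to a low-intensity one even
    at identical frequency.
    """
    s_freq = mollifier(exp.x0 - cfg.mu * theo.x0, cfg.C_nu)
    if s_freq == 0.0:
        return 0.0
    s_inten = mollifier(abs(exp.I) - abs(theo.I), cfg.C_I)
    if s_inten == 0.0:
        return 0.0
    s_width = mollifier(exp.w - theo.w, cfg.C_w)
    return s_inten * s_width * s_freq


def legacy_pair_score(exp: PeakBand, theo: PeakBand, cfg: LegacyScoringConfig) -> float:
    """Earlier two-term score: an intensity term plus a frequency term.

    Both terms are Gaussian, so the score decays smoothly and reaches zero
    only at infinite separation — the behaviour the cutoff scoring replaces.
    Provided for backward comparison only.
    """
    d_i = abs(exp.I) - abs(theo.I)
    d_nu = exp.x0 - cfg.mu * theo.x0
    return math.exp(-(d_i**2) / (2.0 * cfg.sigma1**2)) + math.exp(
        -(d_nu**2) / (2.0 * cfg.sigma2**2)
    )


def _dp_align(
    exp_peaks: Sequence[PeakBand],
    theo_peaks: Sequence[PeakBand],
    cfg: ScoringConfig,
    allowed: np.ndarray | None = None,
) -> tuple[list[tuple[int, int, float]], float]:
    """Global DP over monotone matchings; returns matched pairs and raw optimum.

    ``allowed`` optionally masks forbidden pairs (multi-source cross matches).
    Zero-score matches are never taken as pairs (they are gaps).  Traceback
    ties are broken deterministically: match > theoretical gap > experimental
    gap.
    """
    n, m = len(exp_peaks), len(theo_peaks)
    score = np.zeros((n, m))
    for i, pe in enumerate(exp_peaks):
        for j, pt in enumerate(theo_peaks):
            if allowed is not None and not allowed[i, j]:
                continue
            score[i, j] = pair_score(pe, pt, cfg)
    gap = cfg.gap_score
    S = np.zeros((n + 1, m + 1))
    S[0, :] = gap * np.arange(m + 1)
    S[:, 0] = gap * np.arange(n + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = S[i, j - 1] + gap  # theoretical peak j-1 gapped
            up = S[i - 1, j] + gap  # experimental peak i-1 gapped
            if up > best:
                best = up
            if score[i - 1, j - 1] > 0.0:
                diag = S[i - 1, j - 1] + score[i - 1, j - 1]
                if diag >= best:
                    best = diag
            S[i, j] = best
    # traceback, tie preference: match, then theo gap, then exp gap
    pairs: list[tuple[int, int, float]] = []
    i, j = n, m
    eps = 1e-12
    while i > 0 and j > 0:
        sc = score[i - 1, j - 1]
        if sc > 0.0 and abs(S[i, j] - (S[i - 1, j - 1] + sc)) <= eps:
            pairs.append((i - 1, j - 1, float(sc)))
            i -= 1
            j -= 1
        elif abs(S[i, j] - (S[i, j - 1] + gap)) <= eps:
            j -= 1
        else:
            i -= 1
    pairs.reverse()
    return pairs, float(S[n, m])


def align_peaks(exp: PeakList, theo: PeakList, cfg: ScoringConfig) -> Alignment:
    """Optimal global alignment of two sorted, intensity-normalized peak lists.

    The total score is the DP optimum, divided by max(n_exp, n_theo) when
    cfg.normalize_score, so a perfect all-match of equal-length lists scores
    exactly 1.
    """
    if len(exp) == 0 or len(theo) == 0:
        raise ValueError("both peak lists must be non-empty")
    pairs, raw = _dp_align(list(exp), list(theo), cfg)
    matched_e = {i for i, _, _ in pairs}
    matched_t = {j for _, j, _ in pairs}
    total = raw / max(len(exp), len(theo)) if cfg.normalize_score else raw
    return Alignment(
        pairs=tuple(pairs),
        exp_gaps=tuple(i for i in range(len(exp)) if i not in matched_e),
        theo_gaps=tuple(j for j in range(len(theo)) if j not in matched_t),
        total_score=total,
        raw_score=raw,
        config=cfg,
    )


def shift_theoretical(theo: PeakList, alignment: Alignment, exp: PeakList) -> PeakList:
    """Move theoretical bands onto their matched experimental positions.

    Matched bands take the experimental position.  Unmatched bands are
    shifted by the same distance as the closest (by position; tie: the
    lower-frequency neighbour) matched theoretical band, so leftover peaks
    follow their neighbourhood instead of staying put.  Heights, widths, and
    mixing parameters are untouched; the result is re-sorted and feeds
    reconvolution to produce the aligned spectrum.

    With zero matches the identity shift is returned, every band flagged.
    """
    theo_peaks = list(theo)
    if not alignment.pairs:
        return PeakList(replace(p, flagged=True) for p in theo_peaks)
    shift_by_idx: dict[int, float] = {}
    for e_idx, t_idx, _ in alignment.pairs:
        shift_by_idx[t_idx] = exp[e_idx].x0 - theo_peaks[t_idx].x0
    matched = sorted(shift_by_idx)
    out = []
    for k, p in enumerate(theo_peaks):
        if k in shift_by_idx:
            delta = shift_by_idx[k]
        else:
            best = min(
                matched,
                key=lambda t: (abs(theo_peaks[t].x0 - p.x0), theo_peaks[t].x0),
            )
            delta = shift_by_idx[best]
        out.append(replace(p, x0=p.x0 + delta))
    out.sort(key=lambda b: b.x0)
    return PeakList(out)


def align_multisource(
    exp_by_source: Mapping[Modality, PeakList],
    theo_by_source: Mapping[Modality, PeakList],
    cfg: ScoringConfig,
) -> MultiSourceAlignment:
    """Simultaneous alignment of several spectroscopies on one frequency axis.

    Each side's per-source lists (already normalized independently) are
    concatenated, each peak keeping its source index, and sorted by
    frequency.  One DP runs over the combined strings with cross-source
    matches forbidden, so an IR peak can only ever match an IR peak; the
    source index then splits the result back into per-source alignments.
    The combined score is normalized by max of the total peak counts.
    """
    if set(exp_by_source) != set(theo_by_source):
        missing = set(exp_by_source) ^ set(theo_by_source)
        raise ValueError(f"modalities present on one side only: {sorted(m.value for m in missing)}")
    if not exp_by_source:
        raise ValueError("at least one modality required")
    source_order = sorted(exp_by_source, key=lambda m: m.value)

    def merge(by_source: Mapping[Modality, PeakList]):
        entries = []  # (band, source, within-source index)
        for mod in source_order:
            for k, p in enumerate(by_source[mod]):
                entries.append((p, mod, k))
        entries.sort(key=lambda e: (e[0].x0, e[1].value, e[2]))
        return entries

    exp_entries = merge(exp_by_source)
    theo_entries = merge(theo_by_source)
    allowed = np.array(
        [[e[1] is t[1] for t in theo_entries] for e in exp_entries], dtype=bool
    )
    pairs, raw = _dp_align(
        [e[0] for e in exp_entries], [t[0] for t in theo_entries], cfg, allowed=allowed
    )
    # split back by source index
    per_source_pairs: dict[Modality, list[tuple[int, int, float]]] = {m: [] for m in source_order}
    for ei, tj, sc in pairs:
        mod = exp_entries[ei][1]
        per_source_pairs[mod].append((exp_entries[ei][2], theo_entries[tj][2], sc))
    by_source = {}
    for mod in source_order:
        ps = sorted(per_source_pairs[mod])
        matched_e = {i for i, _, _ in ps}
        matched_t = {j for _, j, _ in ps}
        n_e, n_t = len(exp_by_source[mod]), len(theo_by_source[mod])
        raw_mod = sum(sc for _, _, sc in ps) + cfg.gap_score * (
            n_e - len(ps) + n_t - len(ps)
        )
        by_source[mod] = Alignment(
            pairs=tuple(ps),
            exp_gaps=tuple(i for i in range(n_e) if i not in matched_e),
            theo_gaps=tuple(j for j in range(n_t) if j not in matched_t),
            total_score=raw_mod / max(n_e, n_t) if cfg.normalize_score else raw_mod,
            raw_score=raw_mod,
            config=cfg,
        )
    n_exp = sum(len(v) for v in exp_by_source.values())
    n_theo = sum(len(v) for v in theo_by_source.values())
    total = raw / max(n_exp, n_theo) if cfg.normalize_score else raw
    return MultiSourceAlignment(
        by_source=by_source, total_score=total, raw_score=raw, config=cfg
    )


def alignment_to_json(
    alignment: Alignment, exp: PeakList, theo: PeakList, path: str | Path | None = None
) -> dict:
    """Serializable view of an alignment: matched (nu_e, nu_t, score), gaps, s."""
    doc = {
        "pairs": [
            {"nu_exp": exp[i].x0, "nu_theo": theo[j].x0, "score": sc}
            for i, j, sc in alignment.pairs
        ],
        "exp_gaps": list(alignment.exp_gaps),
        "theo_gaps": list(alignment.theo_gaps),
        "total_score": alignment.total_score,
        "raw_score": alignment.raw_score,
        "config": {
            "mu": alignment.config.mu,
            "C_nu": alignment.config.C_nu,
            "C_I": alignment.config.C_I,
            "C_w": alignment.config.C_w,
            "gap_score": alignment.config.gap_score,
            "normalize_score": alignment.config.normalize_score,
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc
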