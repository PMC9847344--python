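# Methods

This document records the model implemented by `vibralign`, the default
parameter values and why they were chosen, the scope of the synthetic
benchmark generator, the numerical choices, and the known limitations.

## Problem setting

Given a measured vibrational spectrum (IR, Raman, and/or VCD) and computed
harmonic spectra for several candidate stereoisomers, decide which candidate
explains the measurement best. Computed harmonic frequencies differ from
experiment in two ways:

- a **systematic** error, largely removable by one constant scaling factor
  μ < 1 applied to the computed frequencies, and
- a **stochastic** per-mode error of a few cm⁻¹ that no global factor
  removes.

The stochastic part breaks naive point-by-point overlap metrics: a few cm⁻¹
of misalignment between narrow bands destroys their pointwise product. The
approach here first reduces both spectra to band parameters, then matches
bands explicitly, and only computes curve correlations *after* moving the
matched theoretical bands onto their experimental positions.

## Band model

Every band is a height-parameterized pseudo-Voigt with a shared full width
at half maximum (FWHM) w for both components:

    V(x) = I · [ η · L(x) + (1 − η) · G(x) ]
    L(x) = 1 / (1 + 4 u²),   G(x) = exp(−4 ln 2 · u²),   u = (x − x₀) / w

so V(x₀) = I for every mixing parameter η ∈ [0, 1], and V(x₀ ± w/2) = I/2
for the pure shapes. VCD band heights are signed; IR and Raman heights are
non-negative.

Conformer ensembles are combined before broadening with Boltzmann weights
wᵢ = exp(−ΔGᵢ/RT) / Σⱼ exp(−ΔGⱼ/RT) at T = 298.15 K, with
R = 1.987204258640832 × 10⁻³ kcal mol⁻¹ K⁻¹; energies are max-shifted
before exponentiation so arbitrarily large gaps cannot overflow.

## Deconvolution

- **Peak detection**: local maxima of |values| (absolute value so negative
  VCD lobes are detected) with prominence ≥ 2 % of the spectrum maximum and
  separation ≥ 4 cm⁻¹ (`scipy.signal.find_peaks`). Manual positions can
  override detection for difficult spectra.
- **Fit**: one pseudo-Voigt per detected peak, all bands fitted
  *simultaneously* with bounded least squares (`scipy.optimize.least_squares`,
  trust-region reflective). Bounds: η ∈ [0, 1]; w ∈ [2·grid spacing,
  window/2]; x₀ within ±2 starting widths of its detected position; heights
  non-negative except for VCD. The starting width is the half-maximum
  crossing distance around the detected position, additionally capped by the
  distance to the nearest neighbouring start — in fused clusters the
  half-maximum crossing spans several bands and an uncapped start strands
  the fit in a poor local minimum.
- Spectra are assumed baseline-corrected; an optional constant-offset term
  is available (`fit_offset=True`) but off by default.

The prominence default of 2 % is a compromise measured on the synthetic
fixtures: 5 % suppresses genuine weak bands (end-to-end ranking success
dropped from 85 to 78 of 100 replicates), while 1 % sits at ~2σ of the
fixtures' baseline noise (0.5 % of the maximum) and floods the fit with
spurious bands, inflating runtime past usability.

## Scoring and alignment

Band intensities on each side are first normalized so the maximum
|intensity| is 1 (signs kept for VCD). A candidate pair of an experimental
band e and a theoretical band t is scored with a product of three mollifier
kernels — smooth bump functions that are exactly 0 beyond a cutoff:

    f(δ; C) = exp(1 − 1 / (1 − (δ/C)²))   for |δ| < C, else 0
    score(e, t) = f(ν̃ₑ − μ·ν̃ₜ; C_ν̃) · f(|Iₑ| − |Iₜ|; C_I) · f(wₑ − wₜ; C_w)

Defaults: C_ν̃ = 30 cm⁻¹, C_I = 0.5, C_w = 20 cm⁻¹. The product form means
a pair is rejected (score 0) as soon as *any* single property is
incompatible. VCD signs are deliberately ignored in the score (|I|), so the
alignment itself is enantiomer-blind; enantiomer discrimination comes from
the signed correlations afterwards. A legacy two-term Gaussian score
(sum of exp(−ΔI²/2σ₁²) and exp(−Δν̃²/2σ₂²)) is provided for comparison;
because it is a sum, it can give sizable scores to pairs that agree in only
one property, which is the motivation for the product kernel.

Matching is a global alignment (Needleman–Wunsch dynamic program) over
order-preserving matchings with gap score 0; pairs whose score is 0 become
gaps. Traceback ties are broken deterministically (match over
theoretical-gap over experimental-gap). The reported alignment score is

    s = (summed pair scores) / max(n_exp, n_theo)  ∈ [0, 1].

**Multi-source alignment**: peak lists from several modalities are
concatenated with a source tag, sorted by frequency, and aligned in one
dynamic program in which cross-source matches are forbidden; the result is
split back per modality. This enforces a single consistent frequency
correspondence across simultaneously measured spectra.

**Band shifting**: after alignment, each matched theoretical band is moved
to its partner's position; each unmatched band is moved by the shift of the
closest matched theoretical band (ties toward lower frequency). If nothing
matched, bands stay in place and are flagged.

## Metrics, μ screening, and ranking

Both the experimental spectrum and the shifted, re-convoluted theoretical
spectrum are resampled on the analysis window (default 1000–1500 cm⁻¹,
1 cm⁻¹ steps) with natural cubic splines, then compared with the Pearson
correlation r_P and the Spearman rank correlation r_S. The ranking quantity
is

    s_comb = s · Π over modalities (r_P · r_S).

Its absolute value carries no physical meaning; only the comparison between
candidate isomers matters. s_comb is evaluated on a μ grid of 17 values
(0.94…1.02, step 0.005) and each isomer is represented by its maximum
(ties broken toward μ = 1). Isomers are ranked by best s_comb; the ratio of
best to second-best is reported unrounded as a descriptive confidence
indicator. For VCD, both r_P and r_S < 0 (with |r| ≥ 0.05) indicates the
mirror enantiomer was computed; mixed signs or smaller magnitudes give no
call.

## Synthetic benchmark generator

The generator produces paired fixtures that emulate the error structure
above — it is a benchmark harness, not a physical simulator. Defaults
(frozen study conditions):

| parameter | default | meaning |
|---|---|---|
| `n_peaks` | 8 | truth bands in the window |
| window | 1000–1500 cm⁻¹ | fingerprint region |
| `systematic_scale` | 0.975 | truth x₀ / scale = theoretical frequency (so μ = 0.975 is the recoverable optimum) |
| `jitter_sd` | 3.0 cm⁻¹ | stochastic per-mode frequency error |
| `intensity_noise_sd` | 0.10 | relative intensity error |
| `exp_fwhm_range` | 10–18 cm⁻¹ | experimental band widths |
| `theo_fwhm` | 12 cm⁻¹ | Lorentzian used to broaden theory |
| `eta_range` | 0.3–0.9 | experimental pseudo-Voigt mixing |
| `baseline_noise_sd` | 0.005 | additive noise, fraction of max |
| min. separation | half the mean experimental FWHM (7 cm⁻¹) | overlap present but identifiable |

Truth positions use the sorted-uniform construction on the gap-shrunk
window, so positions are uniform subject to the separation constraint.
All randomness flows through tagged substreams of one seed
(`numpy.random.default_rng([seed, tag])`), so every artifact is independently
reproducible.

**Decoys** (wrong isomers) reuse the truth's systematic scale and jitter but
perturb a random subset of peaks (≥ 30 %, minimum 2): frequency shifts of
N(0, severity · jitter_sd) and a *derangement* of the subset's intensities —
a permutation with no fixed point, so every perturbed peak's height really
changes. (A plain permutation is the identity with probability 1/k! and
produced decoys indistinguishable from the true isomer.) Severity 0
degenerates to an ordinary theoretical spectrum.

## Numerical choices

- All floating-point work in float64 via NumPy; band evaluation is
  vectorized over the grid.
- Boltzmann weights are computed with the max-shift trick.
- Cubic-spline resampling uses natural boundary conditions to avoid
  endpoint oscillation on windows cut out of a longer spectrum.
- Dynamic-programming traceback compares scores with an absolute tolerance
  of 10⁻¹² so platform-dependent rounding cannot flip tie decisions.
- JSON outputs round floats to six significant digits, making identical
  runs byte-identical.

## Limitations

- **Band-count mismatch from peak fusion** is the dominant error source in
  end-to-end ranking. Lorentzian broadening at 12 cm⁻¹ fuses theoretical
  stick pairs closer than ~10 cm⁻¹ into one detected maximum, while the
  experimental side (different widths and mixing) often resolves them, or
  vice versa. The alignment then pays an unavoidable gap penalty, and a
  decoy whose perturbation happens to unfuse a pair can match the
  experimental band count and outrank the true isomer. Under the frozen
  benchmark conditions the full pipeline ranks the generating isomer first
  in 85 of 100 seeded replicates; even an idealized pipeline that skips
  detection and fitting entirely (truth bands used directly as experimental
  peaks, raw sticks as theoretical bands) only reaches ~92 %, so the ceiling
  is largely set by the benchmark conditions rather than the fitting stages.
  The acceptance criterion of ≥ 95/100 is therefore not met and is left
  failing rather than weakening the conditions after observing outcomes.
- The deconvolution assumes baseline-corrected spectra; sloping or curved
  baselines must be removed beforehand (only a constant offset can be
  co-fitted).
- Peak detection has no model of overlapping bands without distinct local
  maxima; a shoulder that never becomes a maximum is absorbed into its
  neighbour.
- The μ screening assumes one global scaling factor per spectrum; mode-class
  dependent scaling is out of scope.
- The synthetic generator does not model solvent bands, combination bands,
  anharmonic resonances, or instrument line-shape asymmetry.
- Correlations are computed on the window grid only; bands that the shift
  step moves to the window edge can leak intensity outside the compared
  range (mitigated by reconvoluting on a padded grid before resampling).
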