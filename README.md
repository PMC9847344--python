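# vibralign

Alignment-based comparison of experimental and computed vibrational spectra
(IR, Raman, VCD) for assigning stereoisomers.

## What it does

Assigning the relative or absolute configuration of a molecule from its
vibrational spectra means deciding which of several computed candidate
isomers best explains a measured spectrum. Plain point-by-point overlap
metrics are fragile here, because harmonic frequency calculations carry a
systematic error (removable with a constant scaling factor μ) *and* a
per-mode stochastic error that no global factor can fix. `vibralign` instead
compares spectra at the level of their underlying bands:

1. **Deconvolution** — the measured spectrum and the broadened theoretical
   spectrum are each decomposed into pseudo-Voigt bands
   V(x) = I·[η·L(x) + (1−η)·G(x)], all bands fitted simultaneously by
   bounded least squares. This recovers underlying band heights even where
   strong overlap inflates the apparent maximum of the summed curve.
2. **Peak alignment** — bands from both sides are matched by global
   sequence alignment (Needleman–Wunsch dynamic programming over monotone
   matchings, gap score 0). A candidate pair (e, t) is scored by a product
   of three compactly supported kernels,

       score(e, t) = f(ν̃ₑ − μ·ν̃ₜ; C_ν̃) · f(|Iₑ| − |Iₜ|; C_I) · f(wₑ − wₜ; C_w)
       f(δ; C)     = exp(1 − 1 / (1 − (δ/C)²))   for |δ| < C,  else 0

   with default cutoffs C_ν̃ = 30 cm⁻¹, C_I = 0.5 (after normalizing each
   side's maximum |intensity| to 1), and C_w = 20 cm⁻¹. The alignment score
   s is the summed pair score divided by the larger band count; identical
   band sets give s = 1.
3. **Metrics** — matched theoretical bands are shifted onto their
   experimental positions, re-convoluted, and compared on a common grid
   (natural cubic splines, 1 cm⁻¹ steps over the fingerprint window
   1000–1500 cm⁻¹) with Pearson (r_P) and Spearman (r_S) correlations. The
   ranking quantity is s_comb = s · Π over modalities of (r_P · r_S).
4. **μ screening & ranking** — s_comb is maximized over a grid of scaling
   factors (0.94…1.02, step 0.005) per isomer; isomers are ranked by their
   best s_comb and the best/second-best ratio is reported as a confidence
   indicator. For VCD, sign conventions make the wrong enantiomer show
   anti-correlated r_P and r_S while IR/Raman metrics are unchanged.

Multiple modalities (e.g. IR + Raman) are aligned jointly in one dynamic
program with cross-modality matches forbidden; conformer ensembles are
combined with Boltzmann weights exp(−ΔG/RT)/Σ at 298.15 K before
broadening.

See [docs/methods.md](docs/methods.md) for the full model description,
parameter rationale, and limitations.

## Worked example

Generate a synthetic benchmark case (a known "experimental" spectrum, the
matching theoretical stick spectrum `isomer0`, and two wrong-isomer decoys),
then screen all three candidates against the experiment:

```sh
vibralign synth --seed 3 --decoys 2 --out fixture
vibralign screen IR=fixture/experimental_IR.dat \
    --ensemble fixture/isomer0.json \
    --ensemble fixture/isomer1.json \
    --ensemble fixture/isomer2.json \
    --out run
cat run/ranking.json
```

Actual output of this run:

```json
{
 "best_s_comb": {
  "isomer0": 0.939517,
  "isomer1": 0.465796,
  "isomer2": 0.69069
 },
 "order": [
  "isomer0",
  "isomer2",
  "isomer1"
 ],
 "ratio": 1.36026
}
```

The generating isomer ranks first, and the screening also recovers the
systematic scale the generator used (fixtures are built with a frequency
scale of 1/0.975): `run/screening.json` reports `best_mu = 0.975` for
`isomer0`. The per-μ metric table is written to `run/screening.csv`:

```
isomer,mu,s,rP_IR,rS_IR,rP_X,rS_X,s_comb
isomer0,0.94,0.377026,0.255863,0.30026,,,0.0289652
isomer0,0.945,0.376283,0.255863,0.30026,,,0.0289081
...
```

The same computation from Python, at the level of a single band pair:

```python
>>> from vibralign import Modality, PeakBand, ScoringConfig, pair_score
>>> e = PeakBand(x0=1204.0, I=0.80, w=14.0, eta=0.5,
...              source=Modality.IR, origin="experimental")
>>> t = PeakBand(x0=1233.0, I=0.65, w=12.0, eta=0.5,
...              source=Modality.IR, origin="theoretical")
>>> round(pair_score(e, t, ScoringConfig()), 6)          # unscaled: 29 cm-1 apart
1e-06
>>> round(pair_score(e, t, ScoringConfig(mu=0.975)), 6)  # scaled: 1.8 cm-1 apart
0.893404
```

## Command-line interface

| command | purpose |
|---|---|
| `vibralign deconvolute IR=spec.dat` | fit pseudo-Voigt bands, write band CSV + reconvoluted spectrum |
| `vibralign align IR=spec.dat --ensemble iso.json --mu 0.975` | align isomers at a fixed scaling factor |
| `vibralign screen IR=spec.dat --ensemble iso.json ...` | full μ-grid screening and ranking |
| `vibralign synth --seed N` | generate synthetic benchmark fixtures |

Exit codes: 0 success, 1 computation failure, 2 bad input/configuration.
Identical inputs produce byte-identical JSON outputs (floats rounded to six
significant digits). `--config file.json|file.toml` supplies parameter
defaults; explicit flags take precedence.

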