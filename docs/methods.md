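# Methods

## Model and estimators

A single scale factor per quantum-chemical method maps computed harmonic
wavenumbers onto experimental fundamentals, s·ν_calc ≈ ν_exp. Two
least-squares variants are fitted, both instances of one-parameter
regression through the origin, y_i ≈ s·x_i:

| objective | x_i | y_i | minimised RMSD |
|---|---|---|---|
| absolute | ν_calc,i | ν_exp,i | aRMSD (cm⁻¹) |
| relative | ν_calc,i / ν_exp,i | 1 | rRMSD (dimensionless) |

The closed-form solution and its maximum-likelihood uncertainty are

    s = S_xy / S_xx,   σ₀² = (1/N)·Σ(s·x_i − y_i)²,   σ_s = σ₀ / √S_xx,

with S_xy = Σ x_i y_i and S_xx = Σ x_i². σ_s follows from the curvature of
the quadratic objective: writing s = s_min + δs, the summed-squares
function is N/2 + δs²/(2σ_s²), so δs is normally distributed with variance
σ₀²/S_xx. The fits are unweighted — the objectives contain no per-mode or
intensity weights — and each fit also reports the *other* metric evaluated
at its optimum (the cross-evaluated aRMSD of the relative factor is the
relevant accuracy figure when that factor is used to predict band
positions).

Assumptions worth keeping in mind:

- The absolute objective's error model is additive, frequency-independent
  scatter; the relative objective's is multiplicative scatter. Each
  estimator is calibrated only under its own error structure. Under purely
  additive noise the relative factor is pulled low by the large relative
  scatter of low-frequency modes; under multiplicative noise on ν_exp the
  relative factor carries a second-order errors-in-variables bias
  ≈ −2·s·σ_rel² (the noise sits in the denominator of x). Both effects are
  demonstrated in the test suite; neither is a defect of the closed form.
- σ_s assumes independent, homoscedastic residuals. Value-sorted pairing
  (below) violates independence mildly: when noise swaps neighbouring
  modes, sorting correlates residuals, and the empirical spread of fitted
  factors runs a few-to-15 percent above the reported σ in the recovery
  experiments. The reported σ is therefore a slightly optimistic but
  honest standard error under the stated assumptions.

## Dataset rules and pairing

A molecule contributes 3N−6 frequency pairs (one for a diatomic). Linear
molecules physically have 3N−5 modes; the lowest-energy vibration —
usually one component of a doubly degenerate bend — is disregarded, so
3N−6 entries are retained there too. Degenerate modes appear as repeated
entries and are each paired.

Pairing is strictly by sorted value: both lists ascending, zipped
index-wise. This is permutation-optimal for the summed squared deviation
(rearrangement inequality; verified exhaustively in the tests for mode
counts ≤ 6) but can mis-assign modes whose energy ordering differs between
calculation and experiment; no correction is attempted — the effect washes
out in large datasets and is visible only as the mild σ underestimate
noted above.

Decisions where the rules left room:

- The linear-molecule drop is applied at pairing time to whichever list has
  exactly one entry more than the retained count (both, if both do). A
  mismatch not explained by this rule is an error naming the molecule and
  both counts; a lenient mode skips such molecules with a warning instead.
- Ties in sorting keep input order (stable sort); since pairing is
  value-based, tie order cannot change any fitted quantity.
- The neutral/singlet curation rules describe the published training sets,
  not the mathematics, so they warn by default and fail only under
  `strict_curation`.
- Everything is in cm⁻¹; there is no unit-conversion layer.

## Spectrum prediction

- `scale_uniform` multiplies all stick positions by one factor;
  `scale_hybrid` applies the absolute factor at/above a threshold (default
  2000 cm⁻¹, the conventional boundary between the fingerprint and X–H
  stretching regions) and the relative factor below. The decision uses the
  **unscaled** wavenumber, and the boundary is closed above (a line exactly
  at the threshold takes the absolute factor).
- `gaussian_broaden` evaluates I(ν) = Σ_k A_k·exp(−4 ln2·(ν−ν_k)²/FWHM²)
  on a uniform grid spanning the sticks ± `pad`. The normalisation is
  amplitude-preserving — an isolated peak's height equals its stick
  intensity — because predicted traces are compared in position and shape
  against independently normalised experimental spectra. Each Gaussian then
  carries area A_k·FWHM·√(π/(4 ln2)). Defaults `grid_step = FWHM/10`
  (resolves the lineshape) and `pad = 5·FWHM` (captures >99.99% of each
  line's area).
- `uncertainty_band` shifts the broadened trace rigidly by ±aRMSD along the
  wavenumber axis: the aRMSD quantifies frequency error, not intensity
  error, so the band envelope is horizontal, not vertical.

## Synthetic data generator

`generate_dataset` emulates the statistical structure the scaling relation
assumes. Per molecule: atom count uniform on `atom_count_range`, mode count
3N−6 (1 for diatomics), computed harmonics uniform on `freq_range` and
sorted, and

    ν_exp = s_true·ν_calc·(1 + ε_rel) − β·ν_calc² + ε_abs,

with centred Gaussian ε terms, clipped at 1 cm⁻¹ (a clip rate above 1%
raises a configuration error rather than silently distorting the noise
model). The optional quadratic term β mimics real anharmonicity's stronger
absolute downshift of high-frequency modes; under it the fitted relative
factor exceeds the absolute one, reproducing the trend seen for real
methods. Linear molecules with N>2 are emitted with one extra low-lying
computed bend so the pairing drop rule is exercised end-to-end.

Defaults — 2–12 atoms, 15% linear, frequencies 100–4000 cm⁻¹, s_true 0.96,
additive noise 30 cm⁻¹ in the recovery experiments — were fixed once to
resemble a small-molecule-dominated benchmark set scaled by a typical
dispersion-corrected composite method with a few-tens-of-cm⁻¹ accuracy.
What the generator does *not* emulate: mode-type-specific anharmonic
constants, Fermi resonances, degeneracy patterns beyond repetition,
intensity physics, or realistic mode-ordering swaps between theory and
experiment. Passing recovery tests therefore demonstrate the estimators'
statistical correctness under the stated noise models, not the accuracy of
any particular quantum-chemical method on real spectra.

`recovery_experiment` re-generates and re-fits `n_reps` datasets (replicate
seeds derived deterministically from the configured seed) and reports mean
fitted s, empirical SD, mean reported σ, and 2σ coverage of the truth.

## Numerical choices

- Sums S_xx, S_xy, S_yy and all RMSDs use compensated summation
  (`math.fsum`): ν² terms reach ~10⁷ cm⁻² and naive accumulation over ~10⁴
  pairs loses digits against the 1e-10 oracle tolerance used in testing.
- σ₀ is computed from the residual form Σ(s_min·x−y)²/N rather than
  S_yy − S_xy²/S_xx, which is algebraically identical but cancellation-
  prone; any negative round-off is clamped to zero.
- A single pair fits exactly: σ = 0 is reported with a warning, not an
  error.
- The printed style `0.9688(3)` rounds σ to one significant digit and
  quotes it at the last decimal of s (σ = 0 renders as `(0)` at four
  decimals with a logged note).
- Test oracles minimise the directly-summed objectives with SciPy's
  bounded scalar minimiser (xatol 1e-13); the oracle path shares no code
  with the closed form.

## Problem sizes

The test suite and `scripts/acceptance.py` use 1000 random tables (a few
with 10⁴ pairs) for oracle agreement, 200 replicates of 400-molecule
datasets (~5600 pairs each) for uncertainty validation, exhaustive
permutation checks up to 6 modes, and single/15-line spectra for the
broadening contract. These sizes give Monte-Carlo standard errors well
inside the asserted tolerances while keeping the default run in minutes.

## Known limitations

- One global factor per method: no frequency-dependent (polynomial or
  dual-range-fitted) factors, no per-mode-type factors, and no Bayesian
  posterior beyond the Gaussian σ_s.
- Lineshapes are Gaussian only (no Lorentzian/Voigt); intensities are
  taken as given, and overtones/combination bands are out of scope.
- Pairing is value-based only; no symmetry or character-based mode
  assignment.
- Dataset files are trusted on isotopologue composition and assignment
  completeness; vibscale validates structure and counts, not provenance.
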