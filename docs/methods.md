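# Methods

## Measurement model and synthetic cohorts

A spent-culture-medium Raman spectrum on the shift axis ν (default
600–1800 cm⁻¹, 1201 points, 1 cm⁻¹ step) is modeled as

    I(ν) = Σ_k A_k exp(−(ν − c_k)² / 2σ_k²)  +  B(t(ν))  +  W(ν)  +  ε(ν)  +  spikes

where B is a cubic fluorescence background in the normalized coordinate
t = (ν − ν_min)/(ν_max − ν_min) (so its four coefficients live on the
intensity scale regardless of axis range), W is a weak water contribution
modeled as two very broad Gaussians (σ > 100 cm⁻¹ — water's Raman response
is weak and featureless on this scale), ε is i.i.d. Gaussian detector
noise, and cosmic-ray spikes are single-channel events with Poisson count
(default rate 1 per spectrum) and amplitude 10–50× the local signal.

The default band library holds ten Gaussian bands spanning 815–1500 cm⁻¹
with widths 6–15 cm⁻¹, including the nominal 900 and 940 cm⁻¹ bands. It is
a stand-in: no composition-level inventory of a real medium's spectrum is
available, so the centers/widths/amplitudes are free parameters chosen to
look like a protein-and-metabolite-bearing aqueous medium. The strongest
band sits at 1003 cm⁻¹ so that max-normalization is never driven by the
effect-carrying band.

Cohorts default to 15 "pregnant" and 16 "nonpregnant" samples, matching
the study design this pipeline targets. The group effect multiplies the
900-band amplitude by `effect_size` (default 2) in the pregnant group.
Every band except the 900 band receives per-sample multiplicative
amplitude jitter (SD 5%), width jitter (SD 2%), and center jitter
(SD 0.5 cm⁻¹); the 900 band is deterministic so that the ratio of group
means of true 900-band areas equals `effect_size` exactly — an oracle the
tests rely on. Noise defaults to 1% of the strongest band. All draws
derive from a single seeded `numpy.random.Generator`, so a (config, seed)
pair reproduces a cohort bit-for-bit, and every realized parameter, spike
position and noise level is recorded in a `GroundTruth` record.

What the generator does **not** emulate: instrument line shape (no
Lorentzian/Voigt components), wavelength-dependent detector response,
shot-noise scaling with intensity, sample-to-sample exposure differences,
or correlated baseline drift. Passing tests therefore demonstrate that
each stage does what it claims under this measurement model, not that the
pipeline's operating characteristics transfer to any particular
instrument or medium.

## Preprocessing

Stage order: despike → calibrate → subtract water → baseline → normalize.

- **Despiking.** Modified z-score z = 0.6745·|d₂ − median|/MAD of the
  second difference d₂, threshold 8. The MAD is floored at 2×10⁻³ of the
  intensity range: on noise-free structured input the MAD of d₂ collapses
  toward zero and a bare MAD scale would flag genuine band curvature. A
  spike at channel i also inflates d₂ at i±1, so each flagged candidate is
  confirmed against its own intensity deviation from the unflagged 5-point
  neighborhood median before replacement; unconfirmed channels stay
  bit-identical. Detection limit: noise-free bands narrower than ~σ = 6 cm⁻¹
  at unit amplitude approach the floored threshold; at the default noise
  level the MAD path dominates and bands are far below threshold.
- **Wavenumber calibration.** Toluene peak apexes by quadratic
  interpolation around local maxima, matched to the canonical reference
  shifts (521.0, 785.8, 1003.6, 1030.6, 1210.0 cm⁻¹; those inside the axis)
  within ±15 cm⁻¹. A linear map (quadratic optional) is least-squares
  fitted and applied to the sample axis; the map must be monotone over the
  data range. Linear suffices for a grating spectrograph over this span
  and is identifiable from two peaks. Inside the cohort chain the
  calibrated spectrum is resampled back onto the common grid.
- **Water subtraction.** Default plain subtraction (mode `unit`); mode
  `lsq` estimates a non-negative scale α over a signal-poor window
  (default the top 15% of the axis) for unmatched exposures.
- **Fluorescence baseline.** Iterative modified polynomial fit of order 3
  (max 100 iterations, tolerance 10⁻⁶ relative): fit, clip the working
  vector to the fit, repeat. The clipping loop's fixed point is not the
  background polynomial — under an isolated band it retains a bias of
  order 2% of band height (verified numerically: a unit Gaussian on a zero
  baseline converges to a residual polynomial with max ≈ 0.02) — so a
  final refit uses only channels within 3 robust SDs of the converged
  baseline (MAD of the residuals). On band-free polynomial input every
  channel qualifies and the refit is exact to machine precision; under
  noise the kept set is symmetric about the background and the refit is
  unbiased.
- **Normalization.** Division by the maximum; idempotent and
  scale-invariant; a non-positive maximum raises (it signals a failed
  baseline correction).

## Band-component analysis

Each region (815–1065, 1140–1500 cm⁻¹) is fitted as a sum of Gaussians by
bounded trust-region least squares: centers within ±10 cm⁻¹ of their
seeds, σ ∈ [2, 40] cm⁻¹, A ≥ 0. Seeding is manual (nominal centers) in
the default pipeline — deterministic and robust for a known inventory —
or automatic from minima of the smoothed second derivative, which marks
Gaussian apexes even for partially overlapping bands. Areas use the
closed form A·σ·√(2π); parameter uncertainties come from the Jacobian.
Amplitudes that terminate within the solver's strict-interior epsilon of
the zero bound are snapped to zero. The 900/940 feature is the area ratio
of the fitted bands nearest those nominal centers (match tolerance
±10 cm⁻¹; fitted centers drift); a missing band or a zero denominator
marks the sample's feature as missing rather than failing the cohort.

## Screening

Two-sided Mann-Whitney U per feature, U by rank summation with midranks.
For n₁+n₂ ≤ 12 without ties the p-value is exact, by enumeration over all
C(n₁+n₂, n₁) group assignments with p = min(1, 2·min(P(U ≤ u), P(U ≥ u)));
otherwise the tie-corrected normal approximation with continuity
correction is used (the two agree within 0.05 for p ∈ [0.01, 0.99] at
n₁ = n₂ = 6). α = 0.05, no multiple-testing correction by default — the
screen mirrors a single-headline-feature design — with Benjamini-Hochberg
available. All-tied inputs return p = 1 with a degenerate flag.

## Classification

PCA is fitted on the 890–950 cm⁻¹ channel slice (half-open on the grid:
60 channels at 1 cm⁻¹), mean-centered without variance scaling, via SVD;
sign convention: each loading's largest-magnitude element is positive.
QDA on the first two scores uses per-class sample means and covariances
(denominator n_c − 1) regularized by λ·(trace/2)·I with λ = 10⁻⁶ —
per-class n ≤ 15 makes bare covariances near-singular — and empirical
priors. Posterior ties predict non-pregnant (conservative against a
clinically costly false positive).

Leave-one-out cross-validation refits both PCA and QDA on every fold's
n−1 training samples; the held-out spectrum never influences its own
projection. An exhaustive test confirms that corrupting a held-out
sample's label cannot change its own held-out score.

ROC thresholds sit at midpoints between consecutive distinct scores plus
outer sentinels; AUC by trapezoid (equal to the Mann-Whitney concordance
U/(n₁n₂) to 10⁻¹²); the operating threshold maximizes Youden's
J = sensitivity + specificity − 1, ties broken toward the lower
threshold. The score is the 900/940 band-area ratio by default, with the
held-out QDA posterior as an alternative. Orientation (which group has
the higher ratio) is auto-detected by flipping when AUC < 0.5, and the
flip is logged. Sensitivity and specificity are kept as exact fractions;
display rounding ("93" from 14/15, "62.5" from 10/16) happens only at
format time: values exact at one decimal print as-is, anything else
rounds to the whole percent.

### A note on the permutation null

Under label permutation the mean LOOCV balanced accuracy at n = 31 sits
≈ 3–5% **below** 50% (reproduced identically by an independent
scikit-learn implementation): removing a sample shifts the empirical
priors and class statistics against that sample's own class. This
pessimistic offset is a well-known property of leave-one-out, not a
leakage defect — leakage would bias the null upward. The test suite
asserts strict unbiasedness and therefore documents this property as an
expected failure of the strict form, while separately guarding against
any optimistic deviation.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to make their Monte-Carlo
error small relative to the asserted margins: 1000 spectra for the
Poisson spike-rate check, 100 replicates for band-area recovery at 1%
noise, 200 seeded cohorts per arm for the screening size/power study
(3 binomial SEs ≈ 0.046 around the nominal 0.05), 200 permutations for
the LOOCV null, and 100 seeded cohorts for end-to-end power.

## Known limitations

- The band inventory and all spectral amplitudes are synthetic; no claim
  is made about the Raman cross-sections of real culture media.
- The calibration model assumes a smooth (linear/quadratic) axis error;
  pixel-level distortions are out of scope.
- Water subtraction assumes the background spectrum shares the sample's
  acquisition conditions up to a scalar (mode `lsq`) or exactly (`unit`).
- QDA with two PCs and ~15 samples per class is near the small-sample
  limit; the regularizer keeps it defined but cannot manufacture
  information.
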