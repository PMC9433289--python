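# Methods

## Scope and model

qnmrquant implements internal-standard quantitative ¹H NMR around one
validated worked example: 5-hydroxymethyl-2(5H)-furanone (M = 114.10 g/mol,
purity 98%) quantified against vanillin (M = 152.15 g/mol, purity 99%) via
the one-proton signals at 6.16/7.50 ppm (furanone ethylenic protons) and
9.77 ppm (vanillin aldehyde proton). The mass relation is

    m_F = (A_F · M_F · m_V · P_V · n_V) / (A_V · M_V · P_F · n_F)

computed at full precision; the report layer rounds masses and percentages
to 2 decimals and leaf-level contents to 2 significant figures, matching the
precision at which such results are conventionally reported.

### Purity handling

`purity_mode` selects whether the purity factors enter (`"as_printed"`) or
are set to 1 (`"none"`). The published worked-example masses (25.22 and
25.39 mg) are arithmetic consequences of the relation only with purity
factors omitted, although the source states the purities; the quantitation
pipelines therefore default to `purity_mode="none"` so the reported numbers
are reproduced without altering the formula itself. The round-trip tests,
where simulated signal areas do include purity, use `"as_printed"` — the
physically consistent pairing.

The extract content percentage in the quantitation report is computed from
the 2-dp-reported mass (25.22/29.9 → 84.35%), the convention that matches
the worked example; computed from the full-precision mass it would read
84.34% for the H2 signal.

## Synthetic spectra

The simulator is first-class, tested code: it renders each signal as a sum
of Lorentzian lines, L(x) = h/(1 + ((x−x0)/(γ/2))²), γ = linewidth/frequency
in ppm, with total analytic area per signal equal to
n_protons · (mass·purity/M) · s in millimole units. The optional saturation
factor s = Mz/M0 applies the steady-state attenuation of each signal's T1;
by default s = 1. Any common scale cancels in area ratios, which is all the
quantitation uses.

Multiplets are first-order: each coupling J splits every line into two
half-intensity lines J/frequency ppm apart; lines coinciding within 1e-9 ppm
merge (two equal J give 1:2:1). The furanone's J values are not part of the
source data (only multiplicities are); the shipped defaults
(J(H2,H3) = 5.7, J(H3,H4) = 1.5, J(H4,H5a) = 3.8, J(H4,H5b) = 5.1,
J(H5a,H5b) = 12.3 Hz) are invented, configurable plumbing, and nothing
quantitative depends on them. The H4 multiplet is approximated as a
first-order ddd; strong coupling is out of scope, as are time-domain (FID)
simulation, apodization and phase correction.

Acquisition defaults mirror the worked example's recording conditions:
400.132 MHz, 6410 Hz spectral width, 30° flip angle, 2.56 s acquisition
time, 1.0 s relaxation delay (TR = 3.56 s). The window centre (7 ppm) and
point count are grid plumbing. The ppm axis is stored high→low (display
convention); readers accept either orientation and record the original.

Noise is iid Gaussian per point, seeded through `numpy.random.default_rng`;
identical seeds give identical spectra. This emulates thermal noise well
enough for S:N, LOD/LOQ and precision semantics. It does **not** emulate
baseline roll, phase errors, lineshape distortion, radiation damping,
overlapping matrix signals or t1-noise — so passing tests demonstrate the
arithmetic and statistical chain, not robustness to real-world spectral
artifacts. The worked example's signals are well resolved, which is the
regime this package targets; peak deconvolution is a non-goal.

## Integration and S:N

Areas are trapezoidal over the exact region bounds with linearly
interpolated endpoint intensities, making integration exactly additive over
adjacent regions and insensitive to bound ordering. The only baseline model
is endpoint-linear (subtract the chord through the region endpoints);
anything richer belongs to preprocessing. S:N is peak height (maximum in
the peak region minus the median of the noise region) over 2× the noise
standard deviation — a common spectrometer-software convention; the divisor
is configurable since conventions differ. A zero-noise region yields an
infinite ratio with a warning rather than an exception.

## Validation statistics

* Relative error: 100·(calculated − weighed)/weighed, displayed at 2 dp.
* Linearity: closed-form OLS of calculated on weighed mass; R² as explained
  over total sum of squares. On the seven-point calibration table this gives
  R² = 0.99998, which rounds to the reported 1.00.
* Precision: sample sd (n−1 denominator — the source does not state its
  estimator, so the standard unbiased-variance choice is used), two-sided
  Student-t half-width t(n−1, c)·sd/√n. On the five replicates at 99%
  confidence: mean 30.526 mg, sd 0.0493 mg, half-width 0.1015 mg = 0.33% of
  the mean. The source reports "30.51 mg ± 0.4%", where 30.51 is the weighed
  (not mean calculated) mass and 0.4% is not reproduced by this or other
  standard estimators we evaluated; the implementation documents its formula
  and does not force agreement.
* t quantiles: numeric inversion of the regularized incomplete beta
  function (`scipy.special.betaincinv`), accurate to well below 1e-4 —
  e.g. t(4, 99%) = 4.6041.
* LOD/LOQ: linear mode fits S:N = k·mass through the origin and inverts at
  thresholds 10 and 150, which fixes LOQ/LOD = 15; direct mode returns the
  smallest measured mass meeting each threshold. The published limits
  (0.14 and 0.59 mg) violate the 15× identity, are instrument-noise
  dependent, and are therefore not reproduction targets; the package's
  guarantees are instead the linear-model identity and Monte-Carlo recovery
  of the analytic limit from simulated spectra.

Accuracy rows whose printed relative error disagrees with the error
recomputed from the printed masses (two rows, evidently pre-rounded
upstream) are excluded from the validation pipeline's accuracy listing.

## Relaxation

`fit_t1` fits I(τ) = I₀ + p·e^(−τ/T1) by damped least squares
(`scipy.optimize.least_squares`, trust-region reflective with a positivity
bound on T1, xtol 1e-8, 600 function evaluations). Initialization: I₀ from
the longest delay; T1 from the interpolated zero crossing divided by ln 2
when a sign change exists, else a third of the τ span; p from the first
point. Non-convergence raises with the last iterate; a T1 driven to its
bound is returned flagged. Series need ≥ 4 points for a residual. At 16
log-spaced delays over [0.05, 4] s and 1% noise the estimator's median
relative error over 100 realizations is below 2%.

Steady state assumes complete transverse dephasing between scans (standard
1D acquisition, no echo terms): Mz/M0 = (1−E)/(1−E·cos α), E = e^(−TR/T1);
recovered signal sin α·Mz/M0; Ernst angle arccos E. At TR = 3.56 s and
α = 30°, Mz/M0 is 0.9999 (T1 = 0.5 s) vs 0.9974 (T1 = 0.9 s): ΔMz = 0.0025.
The source quotes "ΔMz = 0.1" for these conditions, which the standard
steady-state expression does not reproduce under any of the stated delay
choices; the module exposes the closed form and flags the discrepancy
rather than matching it. NOE differences between nuclei are acknowledged
qualitatively but carry no formula here; multi-exponential relaxation and
T2 are out of scope.

## Problem sizes and numerical choices

Tests and the acceptance script run on 65k-point spectra (≈10 samples per
1 Hz linewidth at 400 MHz), where trapezoidal areas agree with analytic
truncated-Lorentzian areas to ~0.05% and ±80 linewidths capture all but
0.4% of a Lorentzian's area — hence the 0.5% area-conservation guarantee.
Monte-Carlo checks use 20–100 seeded noise realizations. Degenerate inputs
fail fast with typed errors: zero reference area, constant-x calibration,
non-uniform axes, out-of-window regions, overlapping peak/noise regions.

## Fixtures

The worked-example constants (analyte descriptions, calibration and
replicate tables, extract quantitation inputs, yields, T1 values) live in
one checked-in JSON file, `src/qnmrquant/data/study_fixtures.json`; tests
and pipelines load it rather than retyping values. The GC-measured
enantiomeric ratio (96.90 : 3.10) is carried as metadata only.
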