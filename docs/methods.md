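# Methods

## Scope and model

`nirselect` implements supervised wavelength selection for linear NIR
calibration.  The data model is a spectral matrix `X (N × M)` with a
reference concentration `y` per sample (a fraction in [0, 1]); all errors
are reported as RMSE on that fraction scale, and all correlation figures
are sample Pearson coefficients.  One metric implementation
(`nirselect.models`) is shared by every selector, so method comparisons
differ only in selection logic.

## The selection method

**SPA chain.**  Starting from channel `k0`, each step projects the
remaining columns onto the orthogonal complement of the last selected,
already-projected column and takes the largest residual norm.  Maintaining
running residuals is algebraically equivalent to re-orthogonalising every
candidate against the full selected span (the suite verifies this against
an explicit Gram–Schmidt oracle over thousands of seeded chains) but costs
O(H·N·M) rather than O(H²·N·M).  Ties take the lowest channel index;
channels with zero variance are excluded as start candidates; the chain
stops early if every residual norm falls below 1e−12.

**Search.**  For every candidate `k0` (all M channels by default;
`k0_subsample` scans an even subset for large M) the RMSECV of every
prefix length 1..H is computed; the global minimum wins, ties preferring
the smaller length, then the smaller `k0`.  RMSECV for a PLS model is
itself minimised over the latent-variable count (1..`max_lv`), so the
model complexity is chosen by the same cross-validation that scores the
prefix.

**Ensemble.**  `T` bootstrap resamples (same size as the calibration set,
drawn with replacement) each get a full SPA search; each run's retained
prefix `F_i` enters the union `F_B`.  Per-iteration seeds derive from the
master seed by a counter-based scheme (`SeedSequence(seed, spawn_key=(i,
attempt))`), so increasing `T` never reshuffles earlier iterations and the
union is monotone in `T`.  A resample with constant `y` is redrawn with
the next derived seed.

**Evaluation index.**  `w_i = α_i · p_i · b_i` with

* `α_i`: within a chain of retained length `h`, position `j` (1-based)
  receives weight `h − j + 1`; a variable's α sums its weights over all
  chains.  The alternative `H − j + 1` scheme is available
  (`alpha_scheme="H"`); both honour the rule that earlier-selected
  variables weigh more, and the linear-descending-from-`h` form is the
  default because it does not reward a chain for unused capacity.
* `p_i = sd_i / max(|mean_i|, 1e−8)` on the preprocessed calibration
  matrix (sample sd, n−1).  The guard and the dropped sign keep the index
  non-negative on preprocessed data whose column means can cross zero.
* `b_i`: absolute coefficient of one PLS model (latent variables by CV)
  fit on the calibration matrix restricted to `F_B`.

**Accumulation.**  Union variables sorted by `w` descending (ties: higher
α, then lower channel index); the cross-validated PLS error of every
sorted prefix is computed on the original calibration set and the prefix
at the global minimum is `F_EB` (ties: smaller prefix).  The global
minimum, not the first local one, is used.

## Supporting machinery

* **Preprocessing** (all row-wise, shape-preserving): SNV
  `(x − mean)/sd`; MSC (OLS of each spectrum on a reference, distortion
  inverted); detrend (subtract the least-squares line vs wavenumber);
  Savitzky–Golay smoothing (window 11, polyorder 2 — conventional NIR
  defaults, configurable); moving average (window 11); SG derivatives of
  order 1/2 with respect to channel index.  Sample (n−1) sd everywhere.
  Per-spectrum transforms may precede splitting; MSC is the exception —
  its reference must be the calibration mean, so the pipeline computes the
  SPXY split on raw spectra for MSC runs and freezes the reference from
  the calibration split (no validation leakage).
* **SPXY split**: Kennard–Stone max–min selection on
  `d = dx/max dx + dy/max dy` (Euclidean spectral distance, absolute
  response distance, each max-normalised).  Calibration size is
  round-half-up of `N·ratio/(ratio+1)` (162 at 2:1 → 108/54).
  Deterministic; argmax ties take the lowest index.
* **Models**: MLR (OLS with intercept; rejects `N ≤ p + 1` or rank
  deficiency, naming the counts), PLS1 by NIPALS on centred data with
  coefficients in the original variable space (collapse of the residual X
  norm returns fewer components and records it), LS-SVM with RBF kernel
  `exp(−d²/σ²)` and ridge `I/γ` solved as one bordered linear system.
  LS-SVM tuning: exhaustive 7×7 log grid `γ ∈ 10^{−2..4}`,
  `σ² ∈ 10^{−4..2}`, leave-one-out RMSECV.  Default fold count is 10
  (chemometrics norm for N ≈ 100); folds are a deterministic function of
  `(N, folds, seed)`, and every fold refits the entire model, centring
  statistics included.  Default `max_lv = min(15, N−1, p)`.
* **Baselines**: FiPLS/BiPLS on near-equal contiguous intervals (remainder
  `r`: last `r` intervals one larger; 4001 into 30 → 19×133 + 11×134) with
  a no-improvement stopping rule (the literature gives no explicit one);
  UVE with a same-size noise block at 1e−10 of the mean absolute spectral
  magnitude, LOO coefficient stability `c = mean/sd`, and cutoff
  `threshold × max|c_noise|` (a quantile variant is exposed); MC-UVE with
  80 % subsamples and a ranked forward sweep evaluated every `eval_step`
  variables by CV (not on the validation set, to avoid leakage); CARS with
  a two-point exponential retention schedule through (1, 1) and
  (runs, 2/M) and weighted draws without replacement on |b|, winner by
  minimum 5-fold RMSECV.

## Performance

The SPA search evaluates a cross-validated PLS error at every
(k0, prefix) pair — roughly `M × H × folds` tiny PLS1 fits per search —
so the inner NIPALS/CV loops are numba-compiled (`nirselect._kernels`).
Test-set predictions propagate through the training deflation sequence,
which is exactly the coefficient-form prediction; the test suite pins the
kernels against sklearn's `PLSRegression` and brute-force fold loops.  A
full 501-channel k0 scan with H = 20 and 10-fold CV takes a few seconds on
one core; a complete EBSPA run (T = 10) about half a minute.

## Synthetic data: what it emulates, and what passing tests show

The generator mimics a two-component (ethanol/water-like) system on a
12,000→4,000 cm⁻¹ grid at 2 cm⁻¹ (4001 channels) with concentrations
4.5–85.0 % in 0.5 % steps (162 samples).  Each pure component is a sum of
Gaussian bands — analyte at 5162 cm⁻¹ (width 60, the O–H/C–H combination
feature used for alcohol assays) and 4400 cm⁻¹ (width 90); matrix at
5200 cm⁻¹ (width 45) and 6900 cm⁻¹ (width 110) — mixed as
`c·A_analyte + (1−c)·A_matrix`, then multiplied by a per-spectrum scatter
factor `N(1, 0.02)`, shifted by a linear baseline with `N(0, 0.01)`
coefficients, and dosed with `N(0, 0.002)` channel noise.  Scatter is
applied before the baseline so scatter-correcting transforms have a real
effect to remove.  `truth_mask` marks channels within ±2 widths of an
analyte band centre.  The selection benchmarks use a reduced grid,
6000→4000 cm⁻¹ at 4 cm⁻¹ (501 channels) — the combination-band region
holding the analyte bands — so the full k0 scan stays desk-scale; the
6900 cm⁻¹ matrix band falls outside that window.

What the generator does **not** emulate: instrument line shape, detector
nonlinearity, temperature/humidity response, wavelength-dependent scatter,
or any third component.  Passing tests therefore demonstrate algorithmic
correctness and the method's behaviour under controlled noise, not
instrument-grade performance.

One limitation deserves emphasis.  After SNV each spectrum is divided by
its own standard deviation, and in a two-component closed system that
scale tracks the analyte level; consequently even channels with no
absorption band carry concentration information after SNV (closure
effect — off-band channels reach |r| ≈ 0.8 with y on the benchmark data).
A supervised index will, correctly, keep some of them, so agreement with
`truth_mask` understates selector accuracy on SNV-processed data.
Running the selection on raw spectra does not help on this generator for
a different reason: the baseline is drawn with zero mean, so off-band
channel means sit near zero and the purity term `σ/μ` — designed for
strictly positive absorbances — explodes on exactly the channels that
carry no signal.  The recovery benchmark reports the SNV pipeline (the
package default) and its truth-band agreement of roughly 0.6–0.7 should
be read with that ceiling in mind; the accompanying quantities (strict
reduction from union to final set, and median validation RMSEP at parity
with or better than full-spectrum PLS) are the operationally meaningful
ones.

## Numerical choices and degenerate inputs

* Residual-norm / NIPALS breakdown tolerances: 1e−12 (norms), 1e−24
  (squared).  Zero-variance spectra are rejected by SNV; constant
  references by MSC; all-identical spectra or constant y by SPXY.
* Tie-breaks are total and documented per operation (lowest index, smaller
  h, smaller prefix, higher α), making every result a deterministic
  function of its inputs and seed.
* The purity guard ε = 1e−8 bounds `p` at `sd/ε`; see the limitation
  above for its interaction with zero-mean synthetic baselines.
* `make_grid` rejects spans that are not integer multiples of the step
  (within 1e−8 relative) instead of silently truncating.
* CSV round trips are bit-stable at 12 significant digits (`%.12g`).

## Benchmark problem sizes

The recovery benchmark runs ten seeds of the 501-channel dataset with
T = 10, H = 20, 10-fold CV and a full k0 scan (about half a minute per
seed on one core).  The sample-size study uses nested SPXY subsets at
(27, 14), (54, 27), (81, 41), (108, 54); the example script ships a
scaled-down variant (two sizes, T = 5, 80 start channels) that finishes in
about a minute.
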