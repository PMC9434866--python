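# Methods

## Scope and model

nircarb implements an NIR calibration workflow for non-structural
carbohydrates (NSC = starch + glucose + fructose + sucrose, all in % of
tissue dry mass): spectral preprocessing, PLS1 calibration with
leave-one-out component selection, sMC variable selection, repeated
random-split evaluation, wet-chemistry bookkeeping, and descriptive
statistics of the reference chemistry. Because no instrument data ships
with the package, a synthetic-spectra generator provides data with the
statistical structure the analysis assumes; it is first-class, tested
code, not a fixture.

## Synthetic spectra

**Forward model.** A sample's absorbance is a Beer–Lambert mixture
`a(λ) = Σ_k c_k s_k(λ)` over six named components — the four
carbohydrates, residual water, and a structural "matrix" — each with
Gaussian absorption bands, plus a structured background (below). Each of
the three replicate measurements per sample applies a multiplicative
scatter factor m ~ N(1, 0.03), an affine baseline (offset sd 0.02 AU,
slope sd 2×10⁻⁵ AU/nm), converts to reflectance R = 10^(−a), and adds
detector noise (sd 0.0015 reflectance units); R is clipped to (0, 1].
The scatter/baseline artifacts are exactly the per-spectrum affine
distortions SNV removes, aligning the generator with the preprocessing
rationale.

**Band library.** Starch absorbs at 1480, 1640, 2020 and 2123 nm;
glucose, fructose and sucrose share bands at 1150, 1210, 1748 and
2355 nm with component-distinct amplitude ratios so they remain
spectrally separable; water absorbs at 1941 nm. The sugar-diagnostic
region nominally extends below the 1100 nm grid start; only its in-grid
portion (1150/1210 nm) is represented. Band amplitudes are ~0.01 AU per
% dry mass, giving carbohydrate features of 0.1–0.2 AU over a ~1 AU
organic backbone (the matrix component: one broad Gaussian spanning the
grid at 0.012 AU/%, with a mean structural fraction of 80% dry mass).
A strong, stable backbone matters: the per-spectrum standard deviation
that SNV divides by must be dominated by structure that does not vary
with the analyte, as it is in real powdered tissue, or normalization
leaks analyte information into every channel.

**Concentrations.** Constituent concentrations are zero-truncated
normals with per-tissue means; where only a mean is known the sd
defaults to 15% of it. Trunk-phloem means are starch 11.05, fructose
1.93, glucose 1.03, sucrose 0.63% dry mass; one-year branch starch is
9.03%, root starch 9.64%; sucrose is trace (≤0.05%) in root and needle
tissue. Glucose and fructose can be drawn with a positive correlation
(0.8–0.9 in trunk-like designs) matching the strong covariation of free
hexoses in conductive tissue. NSC is always computed as the sum, never
drawn. Water (residual moisture after oven drying) is 5 ± 0.5%; the
matrix fraction is 80 ± 1%. Both are nuisance components drawn
independently of the carbohydrates.

**Structured background.** Real tissue contains many absorbing
constituents the library does not name (celluloses, lignin, protein,
resin). These are modelled as K fixed band-comb spectra — Gaussian bands
of width 22 nm spaced ~50 nm apart across the grid, unit-standardized —
whose per-sample loadings are i.i.d. N(0, 0.01 AU). The default K = 8.
This term is what gives every channel realistic analyte-independent
variance; without it, synthetic spectra are unnaturally clean and
variable selection degenerates (every channel becomes statistically
informative about the dominant constituent through the SNV
normalization). The generator does not attempt radiative-transfer or
Kubelka–Munk physics, instrument line shapes, or resin chemistry.

**What passing tests show.** The generator reproduces the *structure*
real calibrations face — collinear band signals, scatter artifacts,
masking background — but real tissue adds band shifts with temperature
and moisture, nonlinear detector response, and biochemical covariation
between the analyte and the background. Performance numbers obtained on
synthetic scenarios therefore validate the machinery, not any claim
about field-sample accuracy.

## Preprocessing

Order: replicate averaging (in reflectance, before the log) →
A = log₁₀(1/R) → SNV → Savitzky–Golay first derivative. Choices where
the convention was open:

- absorbance uses log base 10, the spectroscopy standard;
- SNV divides by the n−1 standard deviation;
- the SG filter is 13 points, polynomial order 2 (the common
  chemometrics default for first derivatives), scaled by the 8 nm step
  so units are AU/nm; the 6 channels at each edge are dropped rather
  than extrapolated, so 175 channels become 163;
- the wavelength grid is the half-open arithmetic sequence
  [start, stop) — 1100 + 174·8 = 2492 nm gives exactly 175 channels,
  where a closed interval would give 176.

## PLS1, component choice, metrics

Orthogonal-scores NIPALS for a single response, which is non-iterative:
w ∝ Xᵀy, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate and repeat. X is
centered but not autoscaled (SNV already standardizes spectra);
autoscaling is available behind a flag. The regression vector is
b = W(PᵀW)⁻¹q; PᵀW is unit upper triangular for PLS1 so per-truncation
solves are cheap, and one decomposition yields predictions for every
candidate component count — the LOOCV curve costs one fit per left-out
sample yet is exactly equal to a brute-force loop of independent refits
(tested). Component count is the RMSECV minimizer, ties to fewer
components; a parsimony rule (e.g., one-sigma) can be swapped in by
post-processing the CVCurve. R²_CV uses PRESS against the SST about the
full calibration mean. The component cap is min(20, n−1, p); requests
beyond the rank bound are capped with a warning. Degenerate inputs
(constant y, zero covariance) raise typed errors.

## sMC variable selection

F_j compares each channel's variance along the regression direction
(X̂ = X b bᵀ/(bᵀb)) against its residual variance with n−2 denominator
degrees of freedom, thresholded at the upper-alpha F(1, n−2) quantile.
Defaults: alpha = 0.05 (the package's single significance convention);
b taken from the full-spectrum model at its selected component count;
the reduced refit reuses that component count (observed to be stable
under selection), capped if the reduced matrix cannot support it. An
empty selection falls back to the single largest-F channel with a
warning so pipelines never crash on null signal. A channel whose
residual is numerically zero (e.g., p = 1, where the projection is
exact) reports the sentinel 10¹⁵ rather than infinity.

Two properties of sMC worth knowing when interpreting selections:
it is invariant to rescaling of b, and it flags channels *used by the
model*, which includes channels that help correct normalization and
background effects, not only channels inside the analyte's absorption
bands.

## Repeated-split evaluation

Each simulation i draws a reproducible 80/20 split (seed = base_seed+i,
calibration size ⌊0.8n⌋), runs LOOCV component selection and the full
fit on the calibration set, validates on the held-out 20%, then applies
sMC and repeats the statistics for the reduced model. Splits are
unstratified by default ("random sampling"); stratification by a
metadata label is available for mixed-tissue models. A split whose
calibration response is constant is skipped and logged. Summaries are
means and 2.5/97.5 percentile bounds over simulations, plus per-sample
prediction mean/sd across the simulations in which the sample was held
out. Tissue groups for separate models: trunk (phloem + both branch
ages), root, needle (both needle ages), mixed (everything).

## Tissue statistics

Pearson correlation matrices per tissue with two-sided t tests
(df = n−2) and significance flags at P < 0.05; part–whole correlations
(NSC with its own summands) are reported as computed, uncorrected, as
such tables conventionally are. Group contrasts (tapped vs control,
tapping side vs opposite side) use Welch's unequal-variance t test with
star codes * / ** / *** at 0.05 / 0.01 / 0.001. A mixed-effects
formulation with site/row random effects would be the fuller treatment
of the field design; Welch's test is the deliberate, documented
simplification, adequate for synthetic-data exercises. Constant columns
yield NaN correlations flagged non-significant rather than errors; two
identical zero-spread groups compare as (0, 1, "").

## Benchmark scenarios and problem sizes

Named scenarios freeze the study conditions the benchmarks run under:

- `root_like_scenario` — root tissue, n = 300, default noise (K = 8
  background components). Used for the calibration benchmark: 100
  repeated splits, mean R²_CV for starch ≈ 0.98, sMC retaining ~20–30%
  of channels at matching accuracy.
- `selection_fidelity_scenario` — a spectrally isolated single
  constituent (others at zero concentration, no moisture, constant
  backbone) over a richer background (K = 16), n = 60. Selection is
  sparse here (2–10 channels per dataset), so band-recovery — the
  fraction of selected channels within ±3σ of a true band of the target
  — is measured pooled over 12 generated datasets.
- The null-selection rate uses 200 replicates of a 30 × 163 pure-noise
  problem; the type-I rate of the correlation flag uses 1000 synthetic
  tables of 30 samples with independent constituents; interval
  narrowing uses 30 repeated splits at n ∈ {150, 300, 600} with a
  component cap of 12.

These sizes were chosen to make each quantity statistically stable at
desk scale; the acceptance script recomputes all of them from scratch.

## Numerical choices and degenerate inputs

Reflectance must be positive; values above 1 are clipped to 1 with a
warning (A = 0). SNV of a constant spectrum, PLS on a constant
response, sMC with a zero regression vector or n ≤ 2, correlation on
fewer than 3 samples, and splits with n < 5 all raise typed errors from
a single exception hierarchy. All generator randomness flows from one
integer seed through `numpy.random.SeedSequence`, so identical inputs
give bit-identical outputs.

## Known limitations

- PLS1 only; multi-response PLS2 and kernel/sparse variants are out of
  scope, as are alternative selectors (VIP, iPLS, UVE).
- The generator's Gaussian-band, linear-mixture optics ignore particle
  size effects beyond the affine scatter model.
- sMC selections on SNV-preprocessed spectra include
  normalization-correction channels by design; the band-recovery
  benchmark isolates the analyte precisely to make "true band" an
  unambiguous notion.
- Welch's test in place of the mixed model understates the field
  design's variance structure (site, row, repeated trees).
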