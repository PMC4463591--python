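# Methods

## The analysis problem

A single-cell Raman spectrum is a vector of scattered-light intensities
over Raman shifts ν ∈ [600, 1725] cm⁻¹ (the biological fingerprint
region). The measured trace mixes the cell's vibrational signal with a
multiplicative instrument/focus gain, a smooth fluorescence baseline, the
buffer (PBS) background, white detector noise, and occasional cosmic-ray
spikes. The scientific questions are (a) whether diagnostic band
intensities change monotonically with ICRS cartilage-damage grade, and
(b) how reliably a cell's grade can be predicted from its spectrum alone.

The package works on a uniform grid of 600–1725 cm⁻¹ at Δν = 1 cm⁻¹
(1126 points). The step is a working choice — finer than typical
dispersive-instrument pixel spacing — and all band logic is expressed in
cm⁻¹, not indices, so other grids interoperate via linear interpolation.

## Synthetic cohort generator

No public single-cell chondrocyte Raman dataset exists at this design, so
the cohort is simulated. The generator is first-class, tested code; its
defaults define the study conditions used throughout the tests.

A cell spectrum is

    I(ν) = b·[ Σ_p amp_p · shape_p(ν) ] + baseline(ν) + pbs(ν) + ε(ν) + spike(ν)

- **Peak library.** Gaussian (default) or Lorentzian lines at the
  assigned positions: 785 (DNA/RNA), 1004 (phenylalanine, FWHM 8 cm⁻¹),
  1094, 1267 (amide III, FWHM 42), 1304 (lipid/protein, FWHM 9), 1341,
  1451, 1657 cm⁻¹ (amide I, FWHM 38), plus three moderate-width
  (110–160 cm⁻¹) protein-envelope components near 975, 1250 and
  1600 cm⁻¹. Sharp peaks are narrow (8–22 cm⁻¹), amide bands broad —
  matching how the bands are integrated downstream.
- **Grade response.** Each peak carries per-grade multipliers. Protein
  and nucleic-acid features fall from grade I to III (e.g. amide I
  1.00/0.80/0.68); the 1304 cm⁻¹ band rises (0.62/0.86/1.00). The I→II
  step exceeds the II→III step so higher grades overlap more — diseased
  cells are the more heterogeneous population. The protein envelope also
  falls with grade; because band areas are ultimately normalized by the
  1004 cm⁻¹ *peak height*, it is this declining base under the sharp-peak
  windows that lets the phenylalanine *area* trend survive normalization.
- **Random effects.** Two kinds, both log-normal. Shared *intensity*
  effects (specimen sd 0.10, cell sd 0.15) scale a whole spectrum and are
  removed exactly by EMSC gain correction plus normalization; per-peak
  *composition* jitter (specimen sd 0.03, cell sd 0.07) changes band
  ratios and is the irreducible biological noise that limits
  classification. A purely scalar specimen effect would be invisible
  after preprocessing, which is why the generator separates the two.
- **Nuisance terms.** Gain b ~ U(0.7, 1.3); quadratic baseline with
  coefficient sds (0.5, 0.2, 0.1) in the scaled variable ν̃ ∈ [−1, 1]
  (degree matched to the EMSC model so correction is exact in the
  noiseless limit); a fixed smooth PBS profile (gentle slope, broad water
  band near 1640 cm⁻¹); white noise sd 0.012 (≈1% of the phenylalanine
  height, SNR typical of a 90 s acquisition); cosmic rays with
  probability 0.25 per spectrum, width 1–3 points, amplitude 5–20× the
  signal maximum.
- **Backgrounds.** One PBS trace per specimen, modelled as the average of
  25 acquisitions (noise sd/5). This matters: with single-shot background
  noise, subtracting one trace from all 30 cells of a specimen imprints a
  shared noise signature that cross-validation can exploit as a
  specimen — hence grade — label leak, strong enough to make accuracy
  *increase* with noise level.
- **Design and determinism.** Grade-major, specimen-major, cell-minor
  acquisition order (segmented CV blocks therefore hold out consecutive
  cells of one specimen). The cohort is a pure function of the
  configuration; per-specimen streams are spawned from the seed.

Calibration: the free effect sizes were set so the default pipeline's
leave-one-out efficiency lands in a designed 85–97% band with the II/III
confusion dominating, chance-level (~33%) performance when grade effects
are switched off, and all five band trends significant by ANOVA. Only
these qualitative constraints are encoded; none of the real study's
numeric outcomes (explained variances, exact efficiencies) are targets,
since they depend on data that was never deposited.

What the generator does **not** emulate: photobleaching dynamics,
detector etaloning and wavelength-dependent response, water-band
interference, peak-position shifts with disease state, non-Gaussian noise.
Passing tests therefore show the *analysis machinery* is correct and the
design trends are recoverable at realistic effect sizes — not that real
chondrocyte data will classify at these rates.

### The chance-level control

`null_config()` equalizes all grade multipliers *and* zeroes the per-peak
specimen signature. Specimens are nested in grades, so any recognizable
specimen signature lets leave-one-out CV recover a held-out cell's grade
above chance through its 29 specimen-mates even when grade carries no
biochemical signal; zeroing it makes the control measure chance, not
design leakage.

## Preprocessing chain

Order: despike → background subtraction → Savitzky-Golay → EMSC → peak
normalization.

- **Despike.** Outlier test on second differences: robust z-score
  against a rolling median/MAD (window 11, threshold 8). Two guards make
  the statistic usable across SNR regimes: the rolling MAD is floored by
  the spectrum-wide MAD (an 11-point MAD occasionally collapses, flagging
  ordinary noise), and a flagged point must also exceed the spectrum's
  robust intensity range (cosmic amplitudes are 5–20× the signal maximum;
  band curvature stays below ~0.1× — without this gate, noise-free sharp
  peaks are indistinguishable from spikes by z-score alone). Flagged
  points are replaced by linear interpolation of the nearest unflagged
  neighbours; flagging > 5% of a spectrum raises instead of silently
  rewriting it.
- **Background subtraction.** Pointwise, against the background trace of
  the same specimen; missing matches are errors, not warnings.
- **Savitzky-Golay.** 3rd order, 9 points (scipy, `mode="interp"` edge
  handling). Exact on polynomials of degree ≤ 3; on the 8 cm⁻¹
  phenylalanine line it biases the peak top by ~1.4% per pass — the
  reason the chain is only *near*-idempotent (≈2% relative change on a
  second pass), and a reminder that smoothing parameters trade noise
  against line-shape fidelity.
- **EMSC.** Least squares of s = b·r + Σ_{k≤2} cₖ ν̃ᵏ with ν̃ scaled to
  [−1, 1] for conditioning; correction is (s − baseline)/b. The reference
  r is the mean of all background-subtracted smoothed cell spectra — the
  standard convention when no pure reference exists. The reference is
  computed once on the full set, also when CV is run afterwards: EMSC
  uses no grade labels, so this sharing is label-free; refitting the
  reference inside every training fold changes third-decimal efficiency
  at ~450× the cost and is not done. Degree 2 is the common choice for
  residual fluorescence and is configurable.
- **Normalization.** Divide by the maximum intensity in [1001, 1007]
  cm⁻¹ (height, not area — the plainer reading of peak normalization;
  area normalization is a config option). A non-positive window maximum
  raises: it signals failed preceding corrections.

## Band quantification

Areas are trapezoidal integrals with no local baseline subtraction (EMSC
already removed the baseline). Amide I and III use the printed fixed
windows (1612–1696, 1229–1300 cm⁻¹). Sharp peaks (785, 1004, 1304 cm⁻¹)
use FWHM-derived limits: peak max within ±search half-width, local base =
mean of the flanking minima within 3× that, limits at half-prominence by
linear interpolation between grid points, falling back to the printed
windows (780–794, 1001–1007, 1302–1307 cm⁻¹) if detection fails.

Grade summaries report mean, SEM (sd/√n, n−1), and means normalized by
the largest grade mean per band (so the leading grade reads 1.0 — chosen
as the most natural reading of a "normalized mean area" bar chart), with
a classical one-way fixed-effects ANOVA across grades on per-cell areas.
Specimen clustering is deliberately ignored to match the stated method;
the p-values are accordingly anti-conservative for specimen-level
confounding, and a mixed-model variant is out of scope. Zero-variance
inputs return F = 0, p = 1 rather than NaN.

The variance spectrum — pointwise population variance (n divisor, the
three grade means being the complete set) across grade-mean spectra — is
the diagnostic that between-grade differences sit at Raman bands rather
than in the fluorescence background.

## Classification

- **PCA.** Mean-centred SVD; with more grid points than spectra the
  decomposition runs on the n×n Gram matrix (snapshot method,
  algebraically identical, ~8× faster — it is refit inside every CV
  fold), falling back to full SVD for rank-deficient cases. Loadings are
  sign-fixed (largest-magnitude element positive). Three components by
  default; the count is configurable.
- **Mahalanobis discriminant.** Class centroids and covariances in score
  space; per-class covariance by default, pooled as an option and as the
  automatic fallback for classes with fewer than k+2 members. Ridge
  regularization λ·(tr Σ/k)·I with λ = 10⁻⁶ is applied when the
  condition number exceeds 10⁸. Assignment is argmin d²; ties break
  toward the lower grade (deterministic; ties have measure zero on real
  data).
- **Cross-validation.** *Full*: PCA and the discriminant are refit on
  every training fold, so held-out spectra never influence the model that
  classifies them. Leave-one-out, and segmented CV over consecutive
  acquisition-order blocks (default 10; the trailing remainder forms a
  short block; segment size 1 reduces exactly to leave-one-out).
- **Metrics.** From a rows-=-actual confusion matrix: per-class recall,
  precision, specificity, NPV, and overall efficiency (trace/total).
  Percentages are *truncated* to one decimal, not rounded — the
  convention that reproduces the published worked-example values. A class
  never predicted yields NaN precision rather than a silent 0.

### The reference classification matrix

The packaged 450-cell matrix (rows actual, columns predicted):
150/0/0, 2/145/3, 0/30/120. Its column-wise predictive values truncate
to 98.6/82.8/97.5%, overall efficiency to 92.2% (415/450), and the NPVs
for grades I and II to 100.0/98.1% — matching the published
"sensitivities"/"specificities" under the mapping sensitivity →
column-predictive value, specificity → NPV. The published grade-III
specificity of 90.7% is *not* reproducible from the matrix: the natural
recomputation gives 297/327 = 90.8%. The discrepancy is documented and
deliberately not targeted; no formula we are aware of yields 90.7 from
these counts.

## Numerical and interface choices

- Spectra are exchanged as two-column CSV (`wavenumber_cm1,intensity`,
  `%.10e`), cohorts as a directory plus TSV manifest whose row order is
  the acquisition order (segmented CV depends on it); round-trips are
  lossless at that precision and order-stable.
- Band windows are closed intervals in cm⁻¹; off-grid FWHM limits are
  honoured by splitting boundary trapezoids.
- All cohort randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; reruns are bit-identical.
- Degenerate inputs raise typed errors naming the offending spectrum:
  non-monotone wavenumber files, grids not covering the target range,
  cells without a matched background, absent classes in training folds,
  > 5% despike flags, non-positive normalization windows.

## Problem sizes

The default test and reproduction runs use the full 450-spectrum design:
one leave-one-out pass refits PCA + discriminant 450 times (~10 s on one
CPU with the Gram-matrix path), segmented CV 45 times. The acceptance
script runs the complete analysis twice (default and chance-level
cohorts) in about half a minute.

## Known limitations

- The generator's effect sizes are design choices, not estimates; real
  effect magnitudes were never published numerically.
- ANOVA ignores the specimen level (see above).
- The EMSC reference is global rather than fold-local (label-free; see
  above).
- Percent truncation is a reporting convention; raw rates are always
  available alongside.
- FWHM limits assume a single dominant peak in the search window;
  strongly overlapped doublets resolve to the blend's half-prominence
  points, not the underlying components.
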