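# Methods

This note documents the models, algorithms and design decisions behind
`ramelan`, and what the synthetic-data generator does and does not emulate.

## Spectral model

All spectra live on one shared wavenumber axis (Raman shift, cm⁻¹, strictly
ascending, uniform 1 cm⁻¹ step by default). Datasets with mismatched axes
are rejected rather than resampled: silent interpolation hides unit errors.
The default axis spans 800–1850 cm⁻¹ — the upper fingerprint region. The
range matters more than it first appears: baseline correction fits a
polynomial envelope over the full span, and over too narrow a window a
low-order polynomial can follow the very broad glass-substrate band
(FWHM ≈ 220 cm⁻¹ at 1378 cm⁻¹) and destroy the very signal the substrate
subtraction step needs. Over the 1050 cm⁻¹ default span an order-3 envelope
leaves ≈ 87% of the glass band and essentially all of the pigment bands
intact.

A measured spectrum is modeled as

    x = g · (Σ_k a_k · s_k + b · f) + ε + spikes

with non-negative abundances `a_k` of four endmembers `s_k` (whole
eumelanin, DHICA, glass, paraffin; each a non-negative unit-norm vector
built from Gaussian bands), a smooth autofluorescence shape `f` with
per-spectrum amplitude `b`, a per-spectrum multiplicative scatter gain `g`
(lognormal, CV 0.10), white Gaussian noise `ε` and sparse single-channel
cosmic-ray spikes.

Two modeling choices deserve emphasis:

* **One fluorescence shape per acquisition.** The fluorophores are shared
  across a lesion, so the generator draws a single smooth shape (a decaying
  exponential with a random decay constant and a gentle random polynomial
  ripple — NIR tissue autofluorescence falls off toward higher Raman shift)
  and varies only its per-spectrum amplitude. Independent random baseline
  shapes per spectrum would make the baseline non-bilinear, which no
  curve-resolution step could absorb; the rank-1 form is both more
  realistic and analyzable.
* **Fluorescence rides with the substrate.** Dense melanin absorbs both the
  excitation and everything emitted from below the pigment layer, so the
  fluorescence amplitude is tied to the relative glass abundance. On maps
  this means background (glass + fluorescence) behaves as one bilinear
  component, which is exactly how the three-component map decomposition
  treats it.

## Synthetic study design

The generator reproduces the design of the lesion study: 14 MM, 17 DN and
13 CN samples, 15–20 spectra each (hierarchical truncated-lognormal
abundances: a sample-level mean drawn with the between-sample CV, spectrum
values around it with the within-sample CV). Default composition:

| class | eumelanin mean (CV) | DHICA mean (CV) | within-sample CV |
|-------|--------------------:|----------------:|-----------------:|
| MM    | 100 (0.25)          | 48 (0.15)       | 0.15             |
| DN    | 130 (0.25)          | 18 (0.15)       | 0.15             |
| CN    | 100 (0.25)          | 68 (0.15)       | 0.15             |

Glass: mean 200 (CV 0.25); paraffin: mean 10 (CV 0.50); noise sd 0.2 a.u.
(≈ 1% of a typical composite-spectrum peak); fluorescence scale 15 a.u.;
spike rate 0.02 per spectrum at 20–100 × noise sd. The DHICA ordering
CN > MM > DN and the higher whole-eumelanin load in DN are the study's
qualitative findings; the magnitudes are this package's choices, set so the
synthetic study sits in the regime the study reports (clearly significant
DHICA ordering and near-perfect cross-validated DN separation) and so that
the bilinear factorization is identifiable (abundance contrast is what pins
a curve-resolution solution down). They were fixed once and are not tuned
per test.

Maps are 25 × 30 px at 1 µm with smooth "nest" regions (thresholded
Gaussian random field) covering a configurable fraction of pixels. Both
pigments are proportional to the nest mask in colocalized mode — each with
an independent pixel-level jitter (CV 0.05) and an independent smooth
per-pigment modulation field (CV 0.15, capturing large-scale variation of
subunit composition across nests; real pigment pairs colocalize at r ≥ 0.9,
not r = 1). In anticolocalized mode DHICA follows the mask complement.
Glass is attenuated by up to 70% under the thickest pigment.

One `numpy.random.Generator` seeded from the config drives every draw, in a
fixed documented order, so identical configs are byte-identical.

## Conditioning chain (single spectra)

Fixed order: despike → autofluorescence subtraction → MSC → Savitzky–Golay
smoothing → substrate-background extraction and subtraction.

* **Despiking.** Cosmic rays are single-channel events at 1 cm⁻¹
  resolution. Each spectrum's residual from a short Savitzky–Golay fit
  (window 7, order 3 — follows any smooth band, however sharp, but not an
  impulse) is scored as a modified z-score against a rolling local
  median/MAD (window 25), with the MAD floored at half its spectrum-wide
  median (a purely local MAD collapses at array edges). Channels with
  |z| > 8 and their direct neighbours are replaced by linear interpolation
  from the nearest clean channels. Noise-free smooth spectra produce no
  flags at all, and the operation is idempotent.
* **Autofluorescence.** Iterative modified-polynomial fitting: fit an
  order-3 polynomial, clamp the spectrum to the fit wherever it exceeds it,
  refit until the fit changes by < 1e-4 of the intensity range (max 100
  iterations; non-convergence is a warning, not an error). Order 3 removes
  the generator's smooth fluorescence while sparing the broad glass band —
  a higher order would eat it (see above).
* **MSC.** Each spectrum is regressed on the dataset-mean reference,
  `x ≈ a + b·ref`, and replaced by `(x − a)/b`; spectra with |b| < 1e-12
  are dropped with a log entry.
* **Smoothing.** Savitzky–Golay, window 9, order 3 — preserves the sharp
  1787 cm⁻¹ DHICA band (FWHM ≈ 18 cm⁻¹).
* **Background removal.** A 4-component MCR pass (2 background + 2 pigment)
  is fitted; the component with the highest centered correlation to the
  glass band template is the glass component (error if none exceeds 0.5),
  and its per-spectrum score × loading profile is subtracted. A
  paraffin-like component, when present, is subtracted the same way. Plain
  cosines are not used for template matching: between non-negative vectors
  they are inflated (even a noise loading scores ≈ 0.5 against a broad
  positive template).

A rank-1 subtraction cannot remove glass content that band overlap has
smeared into the other components' scores (≈ 2% of the glass score); the
residual glass content after subtraction is ≥ 90% smaller than before, not
zero.

## Map analysis

Map pixels are short-exposure, low signal-to-noise measurements. Per-pixel
envelope fitting on such data injects composition-dependent distortions
larger than the pigment contrast, and per-pixel scatter normalization
rescales the very abundances being mapped. The map recipe therefore
conditions only by despiking and smoothing and resolves the fluorescence +
glass background as the third MCR component alongside the two pigments
(the attenuation coupling above makes it a single bilinear component).
Score images are reshaped row-major onto the lattice and the whole-image
Pearson r between the DHICA- and eumelanin-assigned images is reported with
no intensity threshold and no 8-bit quantization.

## MCR-ALS

`fit_mcr_als` alternates exact non-negative least-squares solves for scores
and loadings (small per-row/per-column problems via a shared QR; the
active-set solver is only invoked for rows whose unconstrained solution is
infeasible), renormalizes loading rows to unit norm after every iteration
(rescaling scores so `C·S` is unchanged), and stops when the lack of fit

    lof% = 100 · sqrt(Σ residual² / Σ D²)

changes by < 1e-4 percentage points (max 500 iterations). Because each
half-step is an exact solve, the lack of fit is non-increasing — asserted
in the tests.

Initialization is a SIMPLISMA-style purest-variable selection over
channels: purity = std/(mean + 5% of max mean) on a lightly smoothed copy,
channels below 5% of the maximum mean excluded as noise-dominated,
successive picks down-weighted by squared correlation with already-selected
channels, ties to the lowest index. The selected columns act as initial
concentration profiles; one constrained solve turns them into loadings.
Purest *spectra* would be useless here — every acquired spectrum is a full
mixture — whereas the 1787 cm⁻¹, ~1610 cm⁻¹ and ~1480 cm⁻¹ channels the
selection finds are nearly selective for DHICA, eumelanin and glass.

Component assignment is greedy over band windows with lowest-index
tie-breaks: DHICA first (1787 ± 15 cm⁻¹ integral × its share of the total;
at least 10% of the loading's integrated intensity must be in-window),
then whole eumelanin (largest min of the 1310 ± 40 and 1595 ± 40 integrals;
≥ 5% share), then glass (largest 1378 ± 80 integral outside the eumelanin
windows; ≥ 15% share — the map background component carries fluorescence
mass that dilutes its share). Components failing their qualification stay
unassigned, so a duplicated or spurious component is never mislabeled.

MCR solutions on strongly overlapping components have a rotational
ambiguity: factorizations within the noise of one another can differ in how
they split broad content. Recovery is therefore only as good as the data's
abundance contrast; the defaults provide enough (the acceptance study
measures median matched-component cosine ≥ 0.99 and score-truth Pearson
≥ 0.98 over twenty seeds on mixtures at default noise).

## Statistics

Sample summaries are per-sample means and (n−1)-denominator sds of each
pigment score; class summaries are unweighted means of per-sample means
with SE over samples. Class comparisons are Welch's unequal-variance
two-sided t-tests on per-sample means (the class variances differ visibly
and group sizes are unequal), with Satterthwaite degrees of freedom and
stars at strict thresholds (* < 0.05, ** < 0.01, *** < 0.001). No
multiple-testing correction is applied; the three pairwise comparisons are
reported raw, as is conventional for this kind of figure annotation.

## PLS-DA

One mean spectrum per sample; rows ordered deterministically by
(class, sample_id). NIPALS PLS2 on mean-centered spectra against
mean-centered one-per-class dummy responses (no autoscaling — the channels
share units); prediction is the argmax over class columns of the regression
prediction. Three binary schemes: DN vs everything, DN vs MM, DN vs CN.

Cross-validation is venetian blinds: sample i of the ordered rows goes to
fold i mod 10; each fold refits from scratch, including re-centering.
Sensitivity and specificity are computed per class one-vs-rest from the
aggregated confusion matrix and reported as percentages rounded to one
decimal. In a binary scheme the sensitivity of one class is by construction
the specificity of the other. The acceptance study uses 3 latent variables
— matching the three spectral degrees of freedom left after conditioning
(DHICA, eumelanin, background residual); `select_n_lv` chooses by CV
misclassification count with ties broken toward fewer variables.

VIP scores follow the standard formula

    VIP_j = sqrt( p · Σ_a SS_a (w_aj / ‖w_a‖)² / Σ_a SS_a )

with SS_a the response sum of squares explained by latent variable a, so
Σ VIP² = p exactly. On the synthetic DN-vs-rest problem the VIP maximum
falls at the 1787 cm⁻¹ DHICA band.

## What passing tests do and do not show

The generator emulates the statistical structure of the study — class
design, band positions, background physics, abundance hierarchy — not its
unknowable specifics: real eumelanin band shapes vary with chemical
environment; real fluorescence is not exactly rank-1 nor exactly coupled to
substrate visibility; real class effect sizes are unknown (only their
ordering and significance pattern are reported); pheomelanin, tissue
matrix bands and instrument response are absent. Passing tests therefore
demonstrate that the chain is correct and recovers known structure under
realistic contamination, not that the clinical accuracies would reproduce
on new biopsies. The study's own cross-validated accuracies (e.g.
94.1%/100% for DN vs rest) were measured on 44 real biopsies whose spectra
are not deposited; the acceptance suite substitutes property checks at the
same operating points (sensitivity/specificity ≥ 90% in ≥ 18/20 synthetic
studies, VIP at 1787 cm⁻¹, the DHICA ordering with significance, and map
colocalization r ≥ 0.9).

## Numerical details and degenerate inputs

* Axis validation: strictly increasing, uniform to 1e-9 relative, ≥ 16
  channels.
* Lognormal draws are truncated at ±5 sd in the underlying normal; CV = 0
  returns the mean exactly.
* MCR on a zero matrix, non-finite data, or k > min(n, p) raises; a
  mid-iteration NaN raises with the iteration index.
* Welch's test with both variances zero raises unless the means are equal
  (then t = 0, p = 1 by convention); singleton samples report sd 0 with a
  log warning; one-sample classes report SE 0 with a warning.
* Colocalization requires equal shapes and nonzero variance in both images;
  an optional pixel mask exists but defaults to the whole map.
* Venetian-blinds CV raises if a training fold loses a class, or if there
  are fewer samples than folds.
* Degenerate nest masks are redrawn up to 5 times before erroring.

## Problem sizes

Default synthetic campaigns are 44 samples × 15–20 spectra × 1051 channels
(≈ 770 spectra); maps are 750 pixels × 1051 channels. A full conditioning +
unmixing + classification run takes a few seconds; the twenty-seed
acceptance study runs in about two minutes.
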