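# Methods

## Reflectance calibration

A hyperspectral cube is held as `lines × samples × bands` with strictly
increasing band-center wavelengths in nm; the ENVI reader accepts BIL, BIP
and BSQ interleaves (little-endian uint16 or float32) and reorders to this
layout. Reflectance is the raw signal divided by the per-band spatial mean
of a user-designated white-panel region. Because the panel sits in every
scene, this single division removes the illumination spectrum, the sensor's
spectral response, and any global gain; no separate response-correction file
is modeled. Reflectance is not clipped to [0, 1]: specular pixels above 1
are preserved so that window means are unbiased, and masking is left to the
segmentation stage.

Wavelength → band mapping is nearest-band-center with ties resolved to the
lower band, never interpolation — the sensor samples at ~4.69 nm and
interpolating would invent sub-band data. A requested wavelength more than
one band spacing outside the sensor range is an error. A spectral *window*
(e.g. the 759.5–797.02 nm NIR term) selects all bands whose centers lie in
the closed interval and averages them; the window-mean reading follows the
three-band-index literature, where the NIR term is a plateau average. A
single-band window degenerates to that band's value.

## Index family and calibration

ARI = 1/R(green) − 1/R(red edge) isolates the anthocyanin absorption at
550 nm against a red-edge reference where anthocyanin is transparent;
mARI multiplies by NIR reflectance to compensate leaf structure/thickness.
Band defaults: green 550.14 nm, red edge 706.35 nm (wavelength-corrected;
701.06 nm selects the original variant), NIR window 759.5–797.02 nm. ACI is
kept only as a comparator; since no canonical band pair is fixed by the
sources this package follows, it is realized as R(green)/R̄(NIR) with the
formula recorded in the output's index name. The wet-extract "abs" index is
the baseline-corrected peak absorbance A(550) − A(700).

Leaf-level summary is the arithmetic mean over valid mask pixels (area
basis). Pixels with non-positive reflectance at a band the index uses are
flagged invalid and excluded; if more than 10% of leaf pixels are invalid a
warning is logged.

Index → content conversion is ordinary least squares y = a·x + b in mg/g
dry weight (scipy.stats.linregress; R² = squared Pearson correlation,
RMSE = root mean squared residual about the line). The built-in model
`bokchoy2021` (a = 1.8123, b = 0.0962) is compiled in because the 20-sample
dataset it was fitted on is not published; the mapping from leaf-mean index
directly to mg/g is an explicit assumption recorded here — the unit chain
through the per-area (mg/cm²) intermediate is not separately modeled.
`evaluate_agreement` reports R² and about-the-line RMSE as its primary pair
(the convention when the two are quoted together for a regression) plus the
1:1-line RMSE secondarily.

## Segmentation

Hyperspectral: NDVI = (R̄_NIR − R_670)/(R̄_NIR + R_670) > 0.3 by default. Any
leaf — green or purple — has strong red-edge contrast while the white panel
is spectrally flat (NDVI ≈ 0), so one threshold separates both. RGB: a pixel
is background iff min(R, G, B) > 0.85 (near-white). Both paths drop
connected components under 50 pixels, since a handful of stray background
pixels measurably bias leaf-mean indices. No specular-highlight filter is
applied by default.

## RGB color-area scoring

"Reference color ± 20%" is read as a per-channel *relative* band:
|pixel_c − ref_c| ≤ 0.20 · ref_c for all three channels. Absolute-band and
HSV variants are available behind the `mode` switch. Reference colors are
explicit configuration (defaults: purple (0.45, 0.20, 0.45), red
(0.60, 0.15, 0.20)); red and purple areas are scored separately. Color-card
correction applies per-channel gains from neutral patches only — a 3×3
matrix would need more card data than the protocol guarantees. The score
saturates once tissue is fully colored, so it ranks cultivars but cannot
resolve concentration differences within already-purple tissue; the
hyperspectral index does not share this ceiling.

## G×E partitioning

The design is genotype crossed with a single 4-level environment factor (the
NC/SC growing-condition × GS1/GS2 growth-stage combinations); a balanced
complete layout with equal n per cell is required, and n = 4 replicate means
is the packaged trial's structure. Sums of squares follow the standard
balanced decomposition from marginal means; the summary-statistics entry
point uses SS_residual = Σ (n−1)·sd² and is exactly equivalent to the
raw-data path (property-tested to 1e−10 relative error). No block term is
fitted: the randomized-block structure of the original trial is not
recoverable from cell summaries.

Two reporting conventions are exposed because they answer different
questions:

* `percent_of="ss"` (default) — shares of the observed total SS.
* `percent_of="variance_components"` — shares of the EMS variance-component
  estimates σ̂²_G : σ̂²_E : σ̂²_G×E : σ̂²_e (negative estimates clamped to 0),
  the convention of multi-environment-trial reports.

* `test_against="residual"` (default) — all effects over the residual MS
  (fixed-effects model).
* `test_against="interaction"` — genotype and environment over the G×E MS,
  appropriate when environments represent a sampled range and standard in
  G×E studies; the interaction is always tested over the residual.

Stars: * p<0.05, ** p<0.01, *** p<0.001.

`datasets.reconstruct_partition` rebuilds the packaged trial's published
partition with `variance_components` + `interaction`, the pair of
conventions the published table is consistent with: on the hyperspectral
channel the reconstructed genotype/environment/G×E shares land within about
one percentage point of the published 59.2/11.1/26.6, and the significance
pattern (genotype and G×E significant, environment not) reproduces exactly
for both channels. What cannot be reconstructed is the residual share
(published 4.8%/2.9%): the published analysis used raw per-plant data,
whereas the cell SDs are SDs *of replicate means* and imply a much smaller
within-cell error (0.08% destructive). This limit is inherent to the
summary data, not a numerical choice; the corresponding acceptance test
states the full-fidelity expectation and is allowed to fail on the entries
the residual term contaminates.

Fisher's LSD: LSD = t(1−α/2, df_res) · √(2·MSE/n) with the pooled
within-cell MSE; letters are assigned on means sorted descending by the
insert-and-merge rule (maximal runs whose extremes differ by ≤ LSD share a
letter), which with a common LSD encodes exactly the all-pairs comparisons.

## Synthetic data

The leaf forward model is reciprocal-linear (Kubelka–Munk-type) absorption:

    R(λ) = R_base / (1 + k_a·TA·g_a(λ) + k_c·Chl·g_c(λ))

with R_base = 0.55 spectrally flat, g_a Gaussian at 550 nm (σ 40 nm), g_c at
670 nm (σ 30 nm), k_a = 0.1 (mg/g)⁻¹ so 10 mg/g halves R at 550 nm, and
k_c = 0.19 so the default chlorophyll load (25 units) gives leaf NDVI ≈ 0.70.
This is the model class under which reciprocal reflectance — hence ARI and
mARI — is *linear* in pigment load, which is the physical premise of the
index family; an exponential Beer–Lambert tissue model was considered and
rejected because its curvature degrades the index–content linearity that
the calibration step relies on. The red edge emerges from the chlorophyll
term itself (pigment-free tissue is uniformly bright), so a pigment-free
leaf has mARI exactly 0. The panel is flat at reflectance 0.95; additive
Gaussian noise (default test level 0.005 reflectance units) and a gain into
counts complete the acquisition model.

What the simulator does *not* emulate: spatial pigment heterogeneity within
the leaf, veins and petiole, specular highlights, BRDF/shadowing, sensor
dark current, and wavelength miscalibration. Passing tests therefore
demonstrate the correctness of the algebra and the pipeline plumbing, not
field robustness on real leaves.

The sensor grid is 128 bands at 4.69 nm from 400 nm (the line-scan imager's
geometry); test cubes default to 64 × 64 pixels to keep the suite fast —
full 520 × 696 frames are available via the `shape` parameter and the CLI's
`--full-size`. RGB leaves place exactly round(f · leaf_pixels) reference-
colored pixels (default camera jitter sd 0.02, zero-jitter available).
G×E tables are additive (genotype mean + environment effect + interaction +
iid Gaussian replicate noise). Absorbance spectra invert the assay formula
exactly: the Gaussian peak is shifted and clamped to be zero at the baseline
wavelength, so the baseline-corrected reading reproduces the generating
mg/g to machine precision at zero noise. All generators are pure functions
of (parameters, seed).

## Numerical and degenerate-input conventions

Zero reflectance under a valid panel maps to reflectance 0; a non-positive
panel band is a hard error ("dead band"). All-equal ANOVA data yield zero SS
everywhere and percentages of 0 (percent_variation on an all-zero partition
is an error). Degenerate calibration inputs (all x equal) are an error
rather than a NaN fit. Negative baseline-corrected absorbance clamps to 0
with a warning. Ties in nearest-band mapping go to the lower band; LSD
letter assignment is deterministic given the means (sorted descending,
stable keys), making groupings invariant to input row order.
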