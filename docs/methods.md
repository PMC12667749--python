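# Methods

## The measurement model

A MIRSI acquisition is an H × W × B absorbance cube: each pixel carries a
mid-IR absorbance spectrum on a common evenly spaced wavenumber axis,
by default 950–1800 cm⁻¹ at 2 cm⁻¹ spacing (426 points). The analysis treats
each spectrum as

    A(ν) = s(ν) + Σ_b G_b(ν) + ε(ν)

where `s` is a smooth scattering background, `G_b` are vibrational absorption
bands, and `ε` is detector noise. The pipeline's job is to separate these
three terms: the background by rubberband correction, the bands by
second-derivative sharpening, and the noise by calibration on blank pixels.

## Pipeline stages and parameter choices

**Tissue masking.** Tissue is segmented on the single-band image at
1608 cm⁻¹ (a strong protein-region band at which tissue is bright and blank
substrate is dark) with Otsu's histogram threshold (256 bins over the image
range, via scikit-image). The band and bin count are parameters; the
requested band resolves to the nearest grid point with a logged notice.

**Noise scale σ.** The off-tissue pixels are the noise reference. Because
peak significance is tested on *individual* spectra, σ must measure the
noise of a single spectrum's Savitzky–Golay second derivative: σ is the mean
over off-tissue pixels of the per-pixel standard deviation (over trimmed
wavenumbers) of that derivative. Averaging the background pixels into one
mean spectrum first would suppress uncorrelated detector noise by √N and
yield a reference far too permissive for per-pixel 3σ calling; on real
instruments the two scales are closer because the background retains
correlated structure (water-vapor lines, detector drift) that does not
average out — the per-pixel estimator is the version that transfers to both
regimes. The mean background spectrum is still computed and reported.

**Rubberband baseline.** The baseline is the lower convex hull of the
(wavenumber, absorbance) sequence (monotone-chain construction, O(n)),
linearly interpolated between hull vertices and anchored at both endpoints;
the corrected spectrum is zero at both ends and nonnegative. A known
limitation: a convex hull cannot follow any *concave* (peak-shaped)
baseline component, which leaves a small positive residual under broad
scattering bumps, and on noisy single spectra the hull anchors on noise
minima (≈2 noise SD low). For this reason band *integrals* are computed on
the rubberband-corrected **ROI mean** spectrum (noise on the mean is
negligible), while per-spectrum correction is used where spectra are
analyzed individually (occurrence statistics, classification).

**Second derivative.** Savitzky–Golay, window 13 points, polynomial
order 2, in physical units (divided by the squared grid step); 13 points are
trimmed from each edge to discard filter edge effects (426 → 400 points,
976–1774 cm⁻¹ working range). Order-2 exactness means quadratic baselines
contribute a constant, not spurious structure.

**3σ dip detection.** Absorption maxima appear as negative dips of the
second derivative. A dip is a strict local minimum with value < −3σ;
each call records center, depth and significance |depth|/σ. On pure noise
the expected number of calls per 400-point spectrum is well below one.

**Peak occurrence.** For each ROI, 100 spectra (seeded subsample of the
2,000 sampled tissue pixels) are tested; a spectrum counts toward a
reference band if any of its calls lies within ±2 cm⁻¹ (±1 grid point) of
the band center. A band is "consistently observed" in a class when its
median per-ROI occurrence reaches 45% of the subsample. The threshold sits
just *below* one half deliberately: the kidney-FFPE fixation band is
expressed in half of the pixels, so its occurrence concentrates exactly at
50% and a cut at exactly one half would make the count an unstable coin flip
under binomial sampling; any threshold in (≈35%, 50%) identifies the same
band sets, and the parameter is exposed in the config.

**Band table and integrals.** The packaged reference table holds 15
literature band centers (966–1744 cm⁻¹) plus the 1026 cm⁻¹
fixation-artifact band. Integration windows are center ± 12 cm⁻¹, truncated
at the midpoint to any neighbor closer than 24 cm⁻¹, so windows can touch
but never cross a neighboring center. Integrals use the composite Simpson
rule on the grid points inside the window; an even point count is closed
with a trapezoid on the final subinterval. Bands whose centers fall outside
the trimmed working range (966 cm⁻¹ on the default grid) are excluded from
occurrence analysis with a logged notice. An alternative integration mode
integrates the negated second derivative over the same windows
(`integration_mode="second_derivative"`); the default integrates
baseline-corrected absorbance.

**Sub-band Gaussian fitting.** Mean spectra can be decomposed into a sum of
Gaussians, one per detected dip, by bounded least squares (centers within
±4 cm⁻¹ of initialization, fwhm in [6, 80] cm⁻¹, amplitudes ≥ 0), with
restarts on non-convergence and the residual RMS reported.

**Discrimination.** ROI similarity is the Pearson correlation of ROI mean
spectra. Before multivariate analysis each spectrum is Z-scored
individually (SNV-style, mean 0 / SD 1): the object of comparison is
spectral shape, and per-spectrum scaling removes path-length and offset
effects; per-wavenumber standardization is available as an option. PCA
(20 components) feeds a seeded 2-D UMAP (n_neighbors 15, min_dist 0.1) for
visualization, and an L2-regularized logistic regression on the full
z-scored wavenumber features ranks wavenumbers by absolute coefficient
(top 40 reported). The regression runs on wavenumber features rather than
embedding coordinates so that importance is attributable to specific bands.

## The synthetic study

The generator emulates the statistical structure the analysis assumes, per
class (tissue × preparation):

- **Bands** are Gaussian in absorbance — the same family the sub-band fitter
  uses, so parameter recovery is exact in expectation. FF kidney and FF
  liver each express 13 bands drawn from the reference table's working-range
  centers (the liver set contains the glycogen marker at 1030 cm⁻¹, the
  kidney set the 1035 cm⁻¹ DNA band instead; the two tissues further differ
  in band amplitudes). FFPE kidney expresses 8 bands and FFPE liver 7:
  amide bands are retained, DNA/lipid fine structure is lost, and the
  1026 cm⁻¹ fixation band appears (Bernoulli presence 0.5 per pixel in
  kidney, 1.0 in liver). Default widths are fwhm 20 cm⁻¹ (Amide I:
  40 cm⁻¹); the close pairs 1154/1168 and 1448/1462 (14 cm⁻¹ apart) get
  fwhm 12 with near-equal amplitudes, the narrowest width at which two
  second-derivative dips remain separable at the default noise level.
- **Amplitudes**: Amide I 1.0 (FF), Amide II 0.6, minor bands 0.18–0.40.
  FFPE Amide I is 0.337× (kidney) and 0.538× (liver) the FF value — the
  attenuations that produce 66.3% and 46.2% band-integral reductions.
  Other retained FFPE bands sit at 0.20–0.35 so they remain unambiguous
  detections, as observed FFPE bands must be.
- **Baseline** (tissue pixels only): offset 0.10/0.08 + linear slope + a
  broad Gaussian bump (fwhm 600 cm⁻¹, amplitude 0.05/0.04 FF/FFPE)
  emulating scattering. Off-tissue (blank substrate) pixels carry noise
  only — scattering originates in tissue, and this is what gives the
  single-band mask its contrast and the noise calibration its clean
  reference. The bump amplitude is kept small relative to band amplitudes
  because its concave shape is invisible to the convex-hull baseline and a
  large residual would dilute the configured FF/FFPE contrast.
- **Spatial amplitude field**: low-pass-filtered white noise, mean 1,
  CV 0.15, multiplying each pixel's band sum — a cheap stand-in for
  compositional variation across a section.
- **Noise**: additive white Gaussian, SD 0.02 (Amide I single-pixel
  SNR ≈ 50), identical on and off tissue.
- **Geometry**: 64 × 64 pixels per ROI (a desk-scale stand-in for full
  480 × 480 tiles, which add memory but no statistical structure), tissue
  fraction 0.70 as a smooth connected blob, 8 ROIs per class. Every ROI's
  seed derives deterministically from (master seed, class, ROI index).

What the generator does **not** emulate: Mie/resonant-Mie scattering
lineshapes, instrument line-shape convolution, paraffin residues,
correlated (non-white) detector noise, spatial texture of real tissue
compartments, and band-center shifts induced by crosslinking. Passing tests
therefore demonstrate that the pipeline correctly recovers the encoded
class structure from data obeying its assumptions — not that those
assumptions hold for any particular instrument or tissue.

## Numerical and degenerate-input conventions

Grids must be evenly spaced within 1e-9 relative tolerance; descending axes
are reversed on read. Otsu requires at least two distinct values; masks
must leave both classes non-empty. Rubberband requires ≥ 3 finite points.
Occurrence tolerance below the grid step is rejected. Constant spectra are
rejected at Z-scoring with the offending pixel named. Correlation matrices
are symmetrized and their diagonal pinned to exactly 1 after computation to
remove floating fuzz. All stochastic stages (mask geometry, pixel
sampling, occurrence subsampling, UMAP) consume seeds fanned out from one
master seed via counter-based SeedSequence derivation, so a full run is
bit-reproducible.

## Problem sizes

Default analyses use 8 ROIs per class, 2,000 sampled pixels per ROI
(16,000 spectra per class), 100-spectrum occurrence subsets, and five
seeded study replicates for headline statistics; the embedding stage uses a
per-class subset (500 spectra by default in the end-to-end run). These
sizes were chosen so a complete study, including five replicates, runs in
minutes on a single CPU while leaving the binomial noise on occurrence
medians and the seed-to-seed spread of the attenuation estimates small
against the reported effects.

## Known limitations

- The Amide I dip (fwhm 40 cm⁻¹) is broad, so its second-derivative
  curvature is shallow; at SNR 50 single-pixel dip positions jitter beyond
  the ±2 cm⁻¹ occurrence tolerance in roughly 5–20% of pixels (more under
  the FFPE attenuation). Its occurrence therefore saturates near 80–95%,
  not 100%, while narrow bands exceed 95%.
- Bands closer than ~5 cm⁻¹ to a real dip (e.g. reference centers 1026,
  1030, 1035) pick up a few percent of cross-talk occurrence from
  dip-position jitter of the neighbor.
- Rubberband correction under-corrects concave baseline components by
  construction; strongly curved scattering backgrounds call for model-based
  baselines (EMSC-type), which are out of scope here.
- UMAP coordinates are reproducible only for a fixed seed, library version
  and thread count (the embedding is seeded and single-threaded here).
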