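# mirsikit

Analysis toolkit for **mid-infrared spectrochemical imaging (MIRSI)** of
tissue sections, centered on the question of how tissue preparation —
fresh-frozen (FF) versus formalin-fixed paraffin-embedded (FFPE) — alters the
biochemical information a hyperspectral mid-IR microscope can recover.

It is written for spectroscopists and computational biologists working with
QCL- or FTIR-based hyperspectral absorbance cubes (H × W pixels × B
wavenumbers over the 950–1800 cm⁻¹ fingerprint region), and implements the
full chain from raw cubes to class-level statistics:

1. **Tissue masking** — Otsu thresholding of the single-band image at
   1608 cm⁻¹ separates tissue from blank substrate pixels.
2. **Noise calibration** — the discarded off-tissue pixels calibrate the
   noise scale σ of a single spectrum's Savitzky–Golay second derivative.
3. **Rubberband baseline correction** — the lower convex hull of each
   spectrum is subtracted to remove broad scattering backgrounds.
4. **Second-derivative sub-band analysis** — SG differentiation
   (window 13, order 2, 13 points trimmed per edge), dips significant when
   deeper than −3σ (the *3σ rule*), per-band occurrence statistics across
   ROIs with ±2 cm⁻¹ tolerance, sum-of-Gaussians sub-band fitting, and
   composite-Simpson band integrals over reference windows:

   percent reduction = 100 · (∫FF − ∫FFPE) / ∫FF

5. **Discrimination** — ROI correlation matrices, per-spectrum Z-score (SNV)
   normalization, PCA → UMAP embedding, and logistic-regression ranking of
   the top-40 discriminative wavenumbers.

Because no public FF/FFPE rat kidney/liver acquisitions exist, the package
ships a first-class **synthetic cube generator** (`mirsikit.synth`) whose
defaults encode the study conditions: 13 vibrational bands in FF kidney,
8 in FFPE kidney, 13 in FF liver, 7 in FFPE liver; FFPE Amide I amplitude
attenuated to 33.7% (kidney) / 53.8% (liver) of FF; and a fixation-artifact
band at 1026 cm⁻¹ present only in FFPE tissue (in half of kidney pixels, all
liver pixels). Every pipeline stage is validated end to end against this
generator.

## Worked example

```bash
mirsi run --rois-per-class 8 --seed 0 --out runs/demo
```

runs the whole synthetic study (32 cubes of 64×64×426) and prints:

```json
{
  "band_counts": {
    "kidney-FF": 13,
    "kidney-FFPE": 8,
    "liver-FF": 13,
    "liver-FFPE": 7
  },
  "amide_reductions": {
    "kidney": 65.60668654261701,
    "liver": 45.148184471948895
  }
}
```

`band_counts` are the numbers of reference bands whose median per-ROI
occurrence (out of 100 spectra per ROI) clears the consistency threshold —
FFPE processing collapses the kidney fingerprint from 13 to 8 bands and the
liver fingerprint from 13 to 7. `amide_reductions` are the Amide I
(1646–1670 cm⁻¹) Simpson-integral losses of FFPE relative to FF in percent,
recovering the generator's configured attenuations (66.3% / 46.2%) from raw
cubes through the full pipeline. The output directory also holds
`occurrence.csv`, `integrals.csv`, `comparison.csv`, `correlation.csv`,
`embedding.csv`, `importance.csv` and a `report.json` with seeds and stage
timings. Subcommands `mirsi synth / preprocess / subbands / discriminate`
expose the individual stages; the same functionality is available as a
library (`import mirsikit`).

## Layout

```
src/mirsikit/
  model.py        wavenumber grids, spectra, cubes, band tables, ENVI/HDF5 I/O
  synth.py        synthetic FF/FFPE cube generator (study conditions)
  preprocess.py   Otsu masking, noise calibration, rubberband, sampling
  subbands.py     SG second derivative, 3σ dips, occurrence, integrals, fits
  discriminate.py correlation, Z-score, PCA/UMAP, feature importance
  pipeline.py     end-to-end orchestration, config validation, run reports
  cli.py          `mirsi` command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
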