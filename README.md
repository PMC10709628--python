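# starchir

FTIR chemometric authentication and classification of starch residues.

## The problem

Starch grains recovered from the used surfaces of ancient ground stone
tools are direct evidence of plant-food processing — if they are genuinely
ancient. Morphology alone (optical or electron microscopy) cannot rule out
modern contamination picked up during excavation, curation or analysis.
Mid-infrared (FTIR) micro-spectroscopy can: a single grain's spectrum
carries both its carbohydrate identity (O–H and C–H stretching, the
900–1200 cm⁻¹ glucan fingerprint) and, for genuinely aged grains, the
marks of diagenesis — biomineralization bands from calcium carbonate
(~1430, 1790, 2520 cm⁻¹), clay/kaolinite (3750–3580 cm⁻¹), silicates
(~1030 cm⁻¹) and calcium oxalate (~1322 cm⁻¹), together with dehydration
and fingerprint attenuation.

`starchir` implements that workflow end to end for method development and
validation on synthetic data:

1. **synth** — a generative model of modern starch reference (MSR) spectra
   (pseudo-Voigt band sets with class-specific amplitude profiles), aged
   ancient starch candidates (ASC), soil matrices, and 64×64-pixel
   hyperspectral imaging scenes with ground truth.
2. **preprocess** — the model feature chain: interpolation to a common
   grid, rubber-band (lower convex hull) baseline correction,
   Savitzky–Golay second derivative (window 23, polynomial 3), vector
   normalization; plus adjacent-pixel soil background subtraction.
3. **imaging** — ROI chemical maps (ROI1 3600–3100, ROI2 3000–2800,
   ROI3 1200–900 cm⁻¹), co-localized hotspot detection (a particle must be
   bright in *all three* maps; soil minerals light up ROI3 alone), hotspot
   spectrum extraction.
4. **chemometrics** — PCA retaining ≥ 95 % of training variance (capped at
   16 components) and kNN (k = 4, Euclidean, inverse-distance weights) in
   score space; stratified 10-fold cross-validation repeated 6×, reporting
   AUC (macro one-vs-rest), classification accuracy, and support-weighted
   F1 / precision / recall; degree-of-similarity classification of
   unknowns.
5. **mineralization** — SNR-ratio presence scores for the diagnostic
   mineral bands and the verdict rule
   `modern_like / ancient_candidate / non_carbohydrate`.

## Worked example

The numbered scripts under `analysis/` run the whole study; each writes
its tables under `results/`. For example:

```bash
$ python analysis/02_crossvalidate_model.py --seed 42
pooled cross-validation indicators (10-fold x 6 repeats, n=320):
  auc        1.000
  ca         1.000
  f1         1.000
  precision  1.000
  recall     1.000
PCA components retained per fold: [12] (min cumulative variance 0.954)

$ python analysis/05_authenticate_minerals.py --seed 42
verdict  ancient_candidate  modern_like  non_carbohydrate
truth
aged                    93            0                 7
modern                   1           99                 0
verdict agreement with generator truth: 96.0% (theta_low=0.2)
```

The first run says the 16-class synthetic reference library is cleanly
separable by the preprocessing + PCA + kNN pipeline (12 principal
components capture 95.4 % of the training variance), i.e. the generator
sits in the well-separated regime where all five indicators reach 1.0.
The second says the mineralization verdict recovers the generator's
modern/aged truth for 96 % of a 200-spectrum panel; the aged spectra it
misses are heavily mineralized grains whose glucan fingerprint no longer
passes the carbohydrate pattern test — exactly the grains a conservative
analyst would also refuse to call starch.

The same functionality is exposed as a CLI
(`starchir simulate|preprocess|imagemap|hotspots|train|crossval|classify|minerals|report|run`)
driven by a YAML configuration with one master seed.

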