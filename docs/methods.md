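# Methods

This note documents the models, parameter choices and numerical decisions
behind `starchir`, and what the synthetic study conditions do and do not
establish about real archaeological data.

## Spectrum model

A spectrum is an absorbance trace on a strictly increasing wavenumber grid
(cm⁻¹). All instrument conventions (4000 → 800 ordering) are canonicalised
to ascending order on read; every band is a closed interval `[lo, hi]`.
The default acquisition grid is 800–4000 cm⁻¹ at 4 cm⁻¹ (single-point
microscopy); imaging scenes use 8 cm⁻¹, matching the coarser spectral
resolution typical of focal-plane-array acquisition.

## Synthetic data generator

**Band shape.** Absorption bands are pseudo-Voigt profiles — a weighted sum
of a Gaussian and a Lorentzian sharing one FWHM — with Gaussian fraction
0.7, the standard mid-IR band model when only positions and qualitative
widths are known. Amplitude is the peak height in absorbance units.

**Modern starch classes.** All classes share one starch band library
(broad O–H stretch at 3300 cm⁻¹, methylene stretches at 2925/2850,
carbonyl and amide/water-bending bands at 1740/1658/1640/1622, β-glucan
1428, and the glucan fingerprint at 1174, 1163, 1135, 1065, 1060, 1033,
985, 950 cm⁻¹). A class is a reproducible multiplicative amplitude profile
(unit-median lognormal, log-sd **0.45**) plus band-center offsets (normal,
sd **2.0 cm⁻¹**) applied to that library; the two methylene bands share one
multiplier so the asymmetric stretch stays dominant, as in every real
starch. Within a class, replicates jitter amplitudes with CV **0.15** and
centers with sd **0.8 cm⁻¹**, and carry a random non-negative quadratic
baseline drift (≤ 0.02 a.u.) and i.i.d. Gaussian noise (sd **0.005 a.u.**).
These values emulate the qualitative observation that within-species
spectral variability is smaller than between-species variability; they were
fixed in one calibration pass and then frozen. The default roster has 16
classes: 9 above-ground storage-organ species, 5 underground, and 2
non-Eurasian tuber taxa as modern-contamination references.

**Aging.** Diagenesis is a *signature* transformation (so noiseless limits
stay analytic): O–H amplitudes scale by (1 − dehydration), fingerprint
amplitudes by (1 − fingerprint attenuation), and mineral bands are appended
with total amplitude `mineral_fraction × Σ(original amplitudes)`,
partitioned over carbonate / clay–kaolinite / silicate / oxalate by a mix
vector (default 0.4/0.3/0.2/0.1). The one-knob severity mapping used in the
analyses sets dehydration = 0.6 s and fingerprint attenuation = 0.5 s at
mineral fraction s, so degradation is jointly monotone.

**Soil and scenes.** The default soil is a thin scattered sediment layer:
broad silicate (1030 cm⁻¹, amplitude 0.30), sharp clay/kaolinite peaks
(3620/3695), weak carbonate, adsorbed water, and trace organic C–H
(0.022/0.014). Particles are discs blended convexly into the soil with a
cosine taper (weight 1 at center → 0 at radius), an optical-thickness
factor of **3.5** relative to the reference deposition (a solid grain in
transmission absorbs severalfold more than the surrounding smear — without
this no particle could ever out-shine soil in the fingerprint map), and
per-pixel lognormal soil texture (log-sd 0.10). Two soil properties matter
for detection realism: the soil must absorb in the fingerprint region
(creating the "false hotspot" hazard) but only at trace level in the C–H
region (otherwise soil texture correlates all three ROI maps and defeats
co-localization). Ground-truth masks are the full discs.

## Preprocessing chain

Order: linear resampling to 1800–900 cm⁻¹ at 2 cm⁻¹ → rubber-band baseline
→ Savitzky–Golay second derivative (window 23 points, polynomial degree 3)
→ vector (L2) normalization. The composite is invariant to additive linear
baselines and global positive scaling (property-tested end to end). The
1800–900 cm⁻¹ window is where starch loadings are most diagnostic; range,
spacing and SG parameters are configuration.

**Rubber band.** The baseline is the lower convex hull of the spectrum's
points (Andrew's monotone chain on points scaled to the unit square for
conditioning — the hull itself is invariant under positive axis scaling),
linearly interpolated between hull vertices. The corrected spectrum is
clamped at 0 against floating-point dust and is exactly 0 at hull vertices.
An O(n²)-pair brute-force envelope is the test oracle.

**Savitzky–Golay edges.** Boundary values come from the polynomial fitted
to the first/last full window evaluated at the edge points
(`scipy.signal.savgol_filter(..., mode="interp")`), not from padding.
Non-uniform grids are rejected with instructions to resample first.

**Background subtraction.** `target − s·background` with `s` fitted by
projecting the target onto the background over the silicate-dominated
1150–950 cm⁻¹ window, clipped to [0, 2], and additionally capped by
non-negativity: `s` never exceeds the smallest target/background ratio in
the fit window, since absorbance cannot be negative. The projection is
accurate (±10 %) when the window is background-dominated — the
heavily-encrusted-deposit regime it exists for; when the target itself
dominates the window (clean hotspot cores), the non-negativity cap is what
keeps the estimate physical.

**Water vapor.** Instrument-side atmospheric compensation is replaced by an
optional, documented simplification: least-squares removal of a synthetic
rotational-vibrational line spectrum over 1900–1300 cm⁻¹ (fitted jointly
with a linear baseline). Off by default everywhere.

## Imaging

ROI maps are per-pixel trapezoidal integrals over ROI1 (3600–3100), ROI2
(3000–2800) and ROI3 (1200–900 cm⁻¹), by default after subtracting the
straight line joining the spectrum values at the ROI edges and clipping at
zero (background maps to zero). Hotspots are the 8-connected components of
the intersection of the three maps thresholded at their own 90th
percentile — a scale-free reading of "common local maxima" — discarding
components under 4 px (≈ one 5 µm starch at 2.6 µm pixels); `two_of_three`
and `or` modes exist for sensitivity analysis. Per hotspot the pipeline
extracts the mean spectrum of the eroded core (rim pixels are mostly
soil), the mean of a surrounding annulus (dilation by 2 px, minus all
hotspot masks) as local background, and the auto-scaled
background-subtracted candidate spectrum. Cubes read/write an ENVI-style
pair (text header, float32 band-sequential body); mosaics concatenate
tiles without stitching correction.

## Chemometric model

Features are the preprocessed second-derivative vectors. PCA retains the
minimal leading components reaching 95 % cumulative explained variance,
capped at 16; centering by the training mean, no further scaling. Under
the frozen generator the cap never binds (typically 11–12 components at
≈ 95.3–95.5 %). kNN uses k = 4, Euclidean metric and inverse-distance
weights `1/(d + 1e-12)` normalized per query; an exact-distance-zero
neighbour takes weight 1; neighbour-rank ties break by smaller training
index and top-class ties lexicographically, making predictions fully
deterministic. "Weighting distance calculated as Euclidean distance" is
read as inverse-distance weighting over the Euclidean metric (the common
chemometrics-suite reading); uniform weighting is available in
configuration.

Cross-validation is stratified 10-fold, repeated 6 times with independent
seeded partitions. Per-sample preprocessing is deterministic and
sample-local, so features are computed once; PCA is refitted on each
training fold (no leakage). The five indicators — macro one-vs-rest AUC on
the similarity weights, overall accuracy, and support-weighted
F1/precision/recall — are pooled over all held-out predictions across
repeats; per-repeat means are reported alongside. The multiclass AUC
scheme and weighted averaging are choices a single printed number does not
determine; both follow the most common suite defaults.

## Mineralization scoring and verdict

Each diagnostic band (carbonate 1430 broad / 1790 / 2520; clay 3613;
kaolinite window 3750–3580; oxalate 1322 shoulder; silicate 1030 broad) is
scored `h / (h + 3σ)`: a local straight baseline through the medians of
two flanking segments, a mildly smoothed peak statistic (window maximum
for sharp/shoulder bands, window *median* for broad bands, so a narrow
interloper — e.g. the β-glucan 1428 band inside the carbonate window —
under-counts), minus a 3σ noise-maximum offset so featureless noise scores
≈ 0, with σ a robust MAD scale bounded below by a quiet-window
(2300–2050 cm⁻¹) estimate. Scores are ratios, hence invariant to global
positive scaling; bands above 2.5 a.u. are flagged saturated and score 1.0.

The composite mineralization score is the weighted mean over the six
deposition markers; silicate is reported but carries weight 0 by default
because 1030 cm⁻¹ coincides with the starch C–OH band and is precisely the
soil interferent the imaging workflow distrusts. The carbohydrate profile
requires an O–H excursion, a C–H peak (apex position reported; 2920–2925
cm⁻¹ for intact methylene), and a fingerprint *pattern*: peaks in at least
two of the windows 1150–1160, 1060–1080, 980–1040 cm⁻¹ (±10 cm⁻¹ margin
for overlap-shifted apexes) — a single broad silicate hump fails this even
though it is intense. Verdict: no fingerprint pattern →
`non_carbohydrate`; composite < θ (default **0.2**) → `modern_like`;
otherwise `ancient_candidate`. θ is honest plumbing, reported in every
output row; no quantitative cutoff separates "mineralized enough to be
ancient" in the literature.

## Problem sizes and determinism

The packaged analyses use a 320-spectrum library (16 × 20), 50-scene
imaging batteries, 50-trial recovery runs per severity and a 200-spectrum
authentication panel — sizes at which the full battery completes in well
under a minute while Monte-Carlo error stays a small fraction of every
margin being tested. All randomness flows from one master seed through
named substreams (`SeedSequence([master, crc32(stage)])`), so every stage
is independently reproducible and every seed stays below 2³¹.

## What the synthetic conditions do not show

The generator emulates band positions, class structure, diagenetic
transforms and soil interference, but not scattering artefacts (Mie
ripple), detector nonlinearity, atmospheric CO₂, mixed multi-grain
aggregates, or the true biochemical diversity of wild-taxa starches. The
cross-validation indicators on the synthetic library therefore demonstrate
the pipeline's correctness and its behaviour in a well-separated regime —
not field performance on real residues. Likewise the authentication
thresholds are calibrated to the generator's noise model; on real spectra
θ and κ should be revisited against measured references. The classifier
makes no claim of true botanical identification: with a 16-species
reference roster, "similarity to a reference organ" is the honest reading
of its output.
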