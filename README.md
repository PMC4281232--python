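# carapace-pheno

Objective quantification of shore-crab (*Carcinus maenas*) colour and
pattern phenotypes from calibrated multispectral photographs, for studies
of camouflage and phenotype–environment associations.

Field studies of camouflage need appearance measured as physical
reflectance, not human judgement. This package implements the full
analysis chain for cohorts of crabs photographed in four camera channels
— longwave (LW), mediumwave (MW), shortwave (SW) and ultraviolet (UV) —
alongside a Spectralon grey standard and a ruler:

1. **Calibration** — per-channel linearization of the camera response
   fitted from an 8-step grey ladder (2–99% reflectance), equalization to
   the in-frame 40% standard, and scaling to reflectance (image value 255
   ≡ 100% reflectance), followed by resizing to a common pixels-per-mm
   scale.
2. **Colour metrics** over the carapace region of interest:
   brightness `(LW+MW+SW+UV)/4`; saturation as the distance from the
   achromatic centre of a tetrahedral colour space built on
   brightness-normalised channel proportions; and two opponent-style hue
   ratios, `hue1 = UV / ((LW+MW+SW)/3)` and `hue2 = (LW+UV)/(MW+SW)`,
   both equal to 1 at the achromatic point.
3. **Granularity analysis** — Fourier band-pass decomposition of the
   carapace pattern into 23 half-octave marking-size bands from 2 to
   4096 px; band energy `E = Σv²/N` versus marking size forms the
   granularity spectrum, summarised as dominant marking size, total
   energy (pattern contrast) and proportion energy (marking-size
   dominance).
4. **Diversity** — each crab is a point in a six-dimensional phenotypic
   space (hue, saturation, brightness, marking size, total energy,
   proportion energy, each scaled by its dataset-wide maximum); group
   diversity (MDPS) is the mean of individuals' mean pairwise Euclidean
   distances, with a 99-subsample resampling control for unequal group
   sizes.
5. **Statistics** — age-class assignment (25 mm carapace-width rule or
   sex-specific maturity thresholds), leave-one-out cross-validated
   ("jackknifed") linear discriminant classification with confusion
   matrices, Spearman rank correlations of each metric against carapace
   width, and Box-Cox + fixed-effects GLMs (site × shore zone × life
   stage) with stepwise removal of non-significant interactions using
   Type II tests.

A seed-deterministic synthetic-data module generates multispectral scenes,
patterned crab images and full cohort tables with known ground truth, so
every stage is testable end to end without field data.

## Worked example

Measure a synthetic crab photographed through a nonlinear camera
(response exponent 2.2) under 0.8× illumination:

```python
import carapace_pheno as cp

sc = cp.ImageScenario(base_quad=(120, 60, 20, 40), pattern_scale_px=16,
                      pattern_contrast=20, camera_exponent=2.2,
                      illumination=0.8, seed=42)
raw, mask, truth = cp.make_crab_image(sc)
curve = cp.fit_linearization(truth["ladder"])
cal = cp.equalize_and_scale(cp.linearize(raw, curve), 0.40)
cal.roi_mask = mask
quad, pattern = cp.extract_roi(cal)
colour = cp.compute_colour_metrics(quad)
spectrum = cp.granularity_spectrum(pattern, cp.build_ladder(max_size=256))
pat = cp.summarize(spectrum)
```

Printing the metrics gives:

```
brightness        60.5
saturation        0.264
hue1 (UV ratio)   0.60
hue2              1.96
marking size (px) 16.0
total energy      71.0
proportion energy 0.82
```

The base colour (120, 60, 20, 40) has `hue2 = (120+40)/(60+20) = 2`
exactly; the measured 1.96 recovers it through the full camera model.
The dominant marking size lands in the 16 px band the texture was
generated at, and the high proportion energy (0.82) reflects a pattern
dominated by a single marking scale. Brightness is the mean carapace
reflectance on the 0–255 scale (60.5 ≈ 24% reflectance).

The same stages run from the shell:

```sh
carapace-pheno run --config run.yaml          # full pipeline
carapace-pheno simulate cohort --seed 1 --out data/
carapace-pheno mdps --metrics data/cohort.csv --group site,stage \
    --reps 99 --seed 1 --out mdps.csv
carapace-pheno stats --metrics data/cohort.csv --analysis site-dfa --out results/
```

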