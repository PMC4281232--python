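# Methods

This note documents the models, numerical choices and limitations behind
each stage of the pipeline, and what the synthetic-data tests do and do
not establish about real photographs.

## Calibration

**Camera model and linearization.** Camera raw values respond
nonlinearly to radiance. The response is fitted per channel as a
monotone power law `value = a · reflectance^b` by least squares in
log–log space on the grey-standard ladder (nominally eight Spectralon
steps, 2–99% reflectance), and inverted to map raw values onto a linear
scale where 255 predicts 100% reflectance. A power law matches typical
sensor behaviour and is analytically invertible; a monotone PCHIP-spline
mode is available for ladders a power law cannot describe. Fit quality
is reported as the R² of linearized ladder values against the true
reflectances.

Ladder steps measured at the 8-bit clip point (raw ≥ 254.5) are excluded
from the fit: a saturated photograph of a standard carries no response
information. Adjacent-step decreases up to 1 raw unit (the
`monotone_tol` parameter) are treated as measurement noise; larger
decreases reject the ladder as non-monotone. At least three unsaturated
steps are required per channel.

**Equalization.** Each channel is multiplied by a single factor chosen
so the mean over the in-frame standard region equals
`standard_reflectance × 255` (102 for the default 40% standard). This
removes global illumination differences between photographs exactly and
is idempotent. A standard region reading zero rejects the image as a
failed photograph.

**Spatial standardization.** Images are resized (bilinear, anti-aliased
on downscale) to a canonical 10 pixels/mm so marking sizes are
comparable across crabs. The constant is arbitrary but fixed; all
marking sizes in pixels convert to mm through it.

**ROI measurement.** One shared carapace mask is used across the four
channels (they are assumed co-registered). Raw pixels at the 8-bit clip
point are flagged during linearization and excluded from ROI channel
means — the numeric analogue of avoiding specular highlights when
drawing ROIs. For pattern analysis, pixels outside the mask are filled
with the masked brightness mean: filling with the mean minimises
spurious low-frequency energy injected by the mask boundary.

## Colour metrics

Brightness is the plain four-channel mean, deliberately free of any
receiver-vision assumption. Saturation is computed on channel
proportions (each channel over the channel sum), placed in a regular
tetrahedron whose vertices — ordered (UV, SW, MW, LW) — represent
exclusive stimulation of one channel and sit 0.75 from the achromatic
origin; saturation is the Euclidean distance of the proportion-weighted
vertex sum from the origin. Any regular tetrahedron yields saturations
identical up to a global constant, so the vertex distance is pinned (and
configurable) purely for reproducibility; only relative comparisons are
meaningful.

The hue ratios are fixed formulas: `hue1 = UV/((LW+MW+SW)/3)` and
`hue2 = (LW+UV)/(MW+SW)`, the latter read as a ratio of red/brown-plus-UV
against blue-green light; both equal exactly 1 for spectrally flat
colours. A PCA of the cohort's proportion covariance matrix is provided
as a diagnostic that these fixed channels capture the main axes of
colour variation; it never redefines them. A pairwise correlation screen
(default threshold |r| ≥ 0.7, Pearson) flags redundant metrics; hue1
typically correlates with saturation and is excluded from downstream
statistics by default, leaving six metrics: brightness, saturation,
hue (hue2), marking size, total energy, proportion energy.

## Granularity analysis

The pattern raster is mean-subtracted, zero-padded to square
power-of-two dimensions, and decomposed by ideal annular band-pass
filters in the Fourier domain. Band sizes are spatial periods in pixels:
`2 · 2^(k/2)` for k = 0…22 (multiplier √2, printed 1.414), from 2 px —
the Nyquist period — to 4096 px, 23 bands. Half-octave sizes are rounded
to three significant figures; exact powers of two are kept exact so the
ladder terminates at 4096 rather than 4100. Band edges sit at geometric
midpoints between adjacent sizes, with the first band open below and the
last open above (excluding only the DC term), so the bands tile the
non-DC spectrum exactly.

Band energy is `Σv²/N`. Spectra are computed from a single FFT by
summing power over each annulus, normalising by the original (unpadded)
pixel count so padding does not dilute energies; this route is equal (by
Parseval) to filtering each band and summing squared pixels, and the
equality is tested to machine precision on unpadded inputs. Energy
conservation — band energies summing to the raster variance — is then
exact up to rounding, and amplitude scaling by k multiplies every energy
by exactly k².

A marking size of s pixels means spatial period s (not a full light–dark
cycle of 2s). The analysed raster is the per-pixel brightness
(four-channel mean) by default; per-channel analysis is available by
configuration and flagged in output metadata as an assumption. Spectra
whose total energy is below 1e-20 (the floating-point residue of a
constant raster at typical reflectance values) are rejected as
featureless rather than summarised.

## Diversity (MDPS)

Each of the six metrics is divided by its maximum over the entire
dataset — never per group — placing all axes on (0, 1]. Within each
site × life-stage dataset, each crab's mean Euclidean distance to every
other member is averaged over crabs to give the group MDPS;
cross-group distances are never pooled. Groups of one crab have
undefined diversity and are reported missing.

Because diversity estimates can grow with sample size, the resampling
control draws 99 random subsamples (configurable) of the smallest group
size in the comparison, **without replacement** — subsets of the data,
not bootstrap replicates — and reports their mean and standard
deviation. The smallest group is computed like the rest and labelled as
the reference group (its resampled SD is zero by construction). All
draws come from a single seeded generator recorded in the output.

## Statistics

**Age classes.** Two criteria are implemented: sex-specific maturity
(females mature at ≥ 28 mm carapace width, males above 21 mm) and a
single threshold (adult iff ≥ 25 mm, any sex). A comparison harness runs
the jackknifed discriminant analysis under each and selects the
criterion with the higher overall proportion correct.

**Jackknifed DFA.** Linear discriminants (shared within-group
covariance) with priors proportional to training group sizes; each
observation is classified by a function fitted on all others.
Posterior ties break toward the first-listed group. Exactly collinear
feature sets are rejected (singular within-group covariance). This
leave-one-out scheme is conservative: with proportional priors the
held-out observation's own class is slightly under-weighted in training,
so accuracy under label permutation sits at or marginally below chance —
never above.

**Spearman correlations** use midranks for ties; p-values come from the
t approximation `t = r_s·√((n−2)/(1−r_s²))` with df = n − 2 (the form
matching reported t and df statistics), with full-enumeration
permutation p available for n ≤ 8.

**GLMs.** Responses are Box-Cox transformed — `(v^λ−1)/λ`, `ln v` at
λ = 0 — with λ accepted as a fixed input or estimated by maximum
likelihood. Fixed effects are site, shore zone and life stage with the
three pairwise interactions as candidates; the interaction with the
largest p ≥ α (default 0.05) is removed and the model refitted,
repeating until all remaining interactions are significant. Main
effects are never removed. Unbalanced designs are tested with marginal
(Type II) F statistics, the standard choice when testing main effects
after discarding interactions; the removal trace is returned alongside
the final table. No multiple-testing correction is applied across
response models — a documented limitation, deliberately not silently
added.

## Synthetic data

The generators exist to give every stage a ground truth. Calibration
scenes are flat grey patches (a 40% standard, the 8-step ladder, and
four probe patches at 8–70% reflectance) rendered through
`raw = 255·(illumination · reflectance)^(1/exponent)` plus Gaussian
sensor noise (SD 0.5 raw units), clipped at 255. Rasters are
float-valued on the 0–255 scale: an idealised sensor without
quantisation, so recovery accuracy is limited by noise and fit error
alone. Crab images fill an elliptical carapace with band-limited noise
texture — white noise annulus-filtered to within half an octave of the
target scale — at a stated contrast over a base four-channel colour,
shared across channels so the expected channel means are preserved.

Cohort tables draw the six metrics per site × stage cell from diagonal
multivariate normals clipped to physical ranges. Default cell sizes
follow the field campaign the package models (677 crabs across four
Cornish sites, juveniles outnumbering adults roughly 3:1); cell means
encode its qualitative structure — juveniles brighter, more saturated,
higher proportion energy, smaller markings; the mudflat site darker,
bluer-green and more saturated; one rockpool site with much higher
pattern contrast — and juvenile cells carry 1.75× the adult SDs, making
juveniles the more variable stage. Carapace widths are uniform within
stage ranges chosen so the 25 mm rule separates stages exactly.

What passing tests show: the calibration inverts the stated camera
family; the filter bank recovers known scales; the statistics detect
effects of known size at the stated rates. What they do not show:
robustness to mis-drawn ROIs, channel misregistration, non-power-law
sensors, quantisation, or metric distributions unlike the clipped
normals generated here. Real-data behaviour on those axes is untested
by construction.

## Problem sizes and determinism

Simulation-heavy checks use fixed sizes chosen to exercise the asymptotics
without waste: 200 replicates for GLM power (n = 600) and type-I
(n = 240) rates, 50 replicates for the cohort-structure checks, 1024²
rasters for energy conservation, 10⁴-point simplex grids for colour
identities. Every stochastic component takes an explicit seed
(numpy `default_rng`); pipeline runs record config hash, seeds and
package version in a manifest, and re-running a configuration reproduces
all CSVs byte-for-byte.

## Known limitations

- No automatic carapace segmentation, UV/visible registration, or
  camera spectral-sensitivity estimation: masks, channel order and
  response ladders are inputs.
- Background substrates are neither synthesised nor quantified; the
  pipeline measures crabs, not camouflage match.
- No receiver-vision modelling: metrics are receiver-agnostic physical
  quantities.
- Mixed/random effects are out of scope; the GLM stage is fixed-effects
  OLS only.
- The saturation constant (vertex distance 0.75) is a convention;
  absolute saturation values are not comparable across conventions.
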