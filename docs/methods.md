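# Methods

`scarseg` implements an interactive, prompt-conditioned pipeline for
segmenting and quantifying myocardial scar on short-axis late-gadolinium-
enhancement (LGE) cardiac MR, together with the statistical machinery used
to validate such a pipeline (repeatability, method agreement, image-quality
stratification).  Patient LGE data cannot be redistributed, so every claim
the package makes about itself is demonstrated on a synthetic phantom with
exact ground truth.  This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## The phantom

A slice is rendered from `PhantomSpec`: a circular blood pool (radius
`r_endo_mm`), an annular myocardium (`r_endo_mm`–`r_epi_mm`), and a
hyperenhanced scar wedge spanning `scar_extent_deg` of the annulus from
`scar_start_deg`, reaching `scar_transmurality` of the wall thickness from
the endocardium outward (the subendocardial-first convention of ischemic
scar).  Mean intensities default to background 20, myocardium 80, blood
180, scar 200 (arbitrary signal units chosen so that scar–myocardium
contrast is strong while scar and blood overlap — the clinically relevant
confusion).  Corruptions are applied in a fixed order: a multiplicative
low-order (quadratic) polynomial bias field scaled to `bias_amplitude`
(default 0.08), then additive Gaussian noise (`noise_sd`, default 8, i.e.
scar:noise contrast ≈ 15:1 against myocardium).  Masks are the exact
pre-corruption label sets.

Pixels are treated as unit cells and labelled by 5×5 supersampled area
coverage with majority vote (odd sample count so no exact ties).  This
keeps rasterized wedge areas within ~1% of the analytic annular-sector
formula at sub-millimetre spacing; pixel-centre sampling was measured at
up to ~3% on thin wedges and was rejected.  Geometry validation (mass
conservation) is therefore run at 0.5 mm in-plane spacing, where the
residual quantization is comfortably below the 2% tolerance used in tests.

Cohorts draw one spec per subject from a sampler that emulates acquisition
variability (in-plane resolution 1.17–1.96 mm, slice thickness 6–10 mm,
varying radii, scar geometry, intensities, noise, bias).  Slices within a
subject differ in noise realization and scar angular position.  The
generator is fully deterministic under a seed.

What the phantom does **not** model: microvascular obstruction, papillary
muscles, through-plane continuity, partial-volume grey zones, motion and
flow artifacts.  Tests passing on the phantom therefore demonstrate the
correctness of the algorithms and the qualitative behaviour of
prompt-conditioned training, not clinical-grade accuracy on patient data.

## Stratified splitting

Subjects are ranked by scar burden (total scar pixels), cut into quantile
strata (default 4; the bin count is a package choice), shuffled within
strata, and allocated to train/val/test with fractional quotas carried
across strata; overall set sizes match the target fractions (default
70/15/15) to within one subject.  A rank test on the resulting burden
distributions across splits is part of the test suite.

## Pre-processing

Slices are resampled bicubically (no anti-alias pre-blur) to a square
target grid (default 256²), scaling both axes by the same mm-per-pixel
factor so anatomy keeps its aspect ratio; the shorter axis is padded with
the image minimum.  Masks follow by nearest neighbour and stay binary.
Intensities are then clipped at the 0.1st/99.9th percentiles (linear
interpolation, whole-slice support) and z-scored per slice with the
population (1/N) standard deviation.  Resampling happens before
normalization.  Note that re-normalizing an already-normalized slice trims
the extreme ~0.1% tail slightly (linearly interpolated percentiles are not
an exact fixed point of clipping): the bulk of the image is idempotent to
~1e-5, tail pixels to a few 1e-3.

## Augmentation

Per training sample a `TransformPlan` is drawn: CLAHE always; horizontal
and vertical flips and gamma modulation each at probability 0.5; rotation
(±15°), isotropic scaling (±10%), shear (±8°, a package choice), elastic
deformation (7×7 control grid, per-control-point displacement up to 7.5 mm,
converted to pixels via the slice geometry), polynomial bias fields
(third order, coefficients up to 0.5, exponentiated), Gaussian noise
(σ ∈ [0, 0.1] of the normalized scale) and mild blur (σ ∈ [0, 1] px) each
at probability 0.3.  Spatial transforms are composed into one coordinate
mapping applied bicubically to the image and by nearest neighbour to every
mask, so binarity and scar ⊆ myocardium survive by construction.
Intensity transforms run in the fixed order bias → blur → noise → gamma →
CLAHE; gamma operates on a min–max rescaled copy and maps back, making
γ then 1/γ an exact inverse pair.  Plans serialize to JSON and replay
bit-identically.

## Supervision

Soft labels are Gaussian blurs of the binary mask (σ = 2 px by default;
reflective boundaries, kernel truncated at 4σ so label mass is conserved
away from borders).  The composite objective is

    L_total = λ_Dice·L_Dice + λ_BCE·L_BCE + λ_KL·L_KL,
    λ_Dice = 0.60, λ_BCE = 0.62, λ_KL = 0.64, ε = 1e-6,

with the soft-Dice complement, mean binary cross-entropy, and the
pointwise divergence Σ s·log(s/(p+ε)) on the scar channel.  Two scale
conventions for the KL term are exposed: the raw pointwise **sum** (the
analytic definition; may be negative because the maps are not normalized
distributions) and a **per-pixel mean**.  Training uses the mean: at
N ≈ 10⁴ pixels the raw sum dwarfs the other two terms and its optimum is
gross over-segmentation (empirically, validation Dice collapses below
0.1), so the package normalizes the term scales to keep the composite
objective stable.  A
`normalize_lambdas` flag (divide the λ by their sum) exists and is off by
default.  Analytic gradients of all three terms are provided and checked
against central finite differences to 1e-4 relative.

## Prompts

Boxes are minimal enclosing rectangles of the mask with a 2-pixel margin
(one union box for multi-blob scars; a per-component mode is a flag),
half-open `[r0,r1)×[c0,c1)`.  Prompt augmentation shifts the whole box by
one integer offset pair within ±10 px and expands width/height about the
centre by a uniform factor up to 1.2, clamped to the grid.  Positive
points (2–10) are sampled uniformly without replacement from the mask
foreground, with no boundary-distance weighting.  Box IoU uses the
half-open pixel-area convention.  Simulated raters jitter the box with
rounded Gaussian shifts and folded-Gaussian expansion; distinct seeds are
distinct raters/rounds.

## Engine

Any backbone exposing `forward(image, prompt) → probability map` over
named parameter groups can be trained.  The built-in `TinyPromptNet` is a
per-pixel MLP (7 features → 48 tanh units → sigmoid): raw and σ=2-smoothed
intensity; a filled box channel; the intensity z-scored against in-box
statistics (scar is usually the brightest structure in its own box); a σ=2
point heatmap; and two point-proximity decays (8 px scale and 0.35 of the
box diagonal, so point influence adapts to lesion size).  Prompt-channel
gains form a separate `prompt` group, frozen by default — the analogue of
keeping a prompt encoder frozen while image encoder and decoder adapt.
Small-magnitude initialization (N(0, 0.15)) keeps the tanh units
unsaturated; short training runs were otherwise noticeably init-sensitive.

Training uses AdamW-style decoupled weight decay (default 1e-2), a
stepwise schedule halving the rate every 10 epochs, at most 100 epochs,
and early stopping after 20 epochs without validation-Dice improvement
(strict improvement by >1e-5); the best-validation checkpoint is restored.
The schedule/early-stop defaults mirror the clinical training recipe; the
default `lr0 = 1e-4` suits a large backbone, while desk-scale runs of the
~1k-parameter MLP use `lr0 = 2e-2`, chosen as appropriate for a small
model.  Prompts are regenerated each epoch with prompt augmentation.
Binarization threshold is 0.5.  Mask refinement is a single erosion or
dilation with the 3×3 "elliptical" element, which at that size is the
4-connected cross.

### Desk-scale benchmark conditions

The end-to-end claims (learning sanity, prompt-strategy ordering, jitter
robustness) are evaluated on 96×96 phantoms: 84 subjects × 3 slices,
split 200 training / 12 validation / 50 held-out slices, 30 epochs, one
training run per prompting strategy, all seeded.  Box jitter at
evaluation uses the same ±10 px / ≤20% model as prompt augmentation.
Typical results: combined box+points ≈ 0.84–0.87 mean Dice, box-only and
points-only lower, and <0.05 degradation under jittered boxes.

## Quantification

Dice is 2|A∩B|/(|A|+|B|) with both-empty = 1, one-empty = 0.  Hausdorff
distance is the symmetric maximum over boundary pixels (foreground pixels
4-adjacent to background, image border counting as background), with
coordinates scaled anisotropically by the pixel spacing; the true 100th
percentile is the default (an `hd95` percentile option exists).  Empty
masks yield an undefined sentinel excluded from aggregates.  Scar mass is
pixel count × in-plane spacing² × `through_plane_mm` × 1.05 g/cm³; the
through-plane extent defaults to the slice thickness only (no gap added —
acquisition gap handling is left to the caller).  Mass error is reported
in grams and as a percentage of a supplied LV myocardial mass.

The FWHM reference method takes an operator ROI inside the enhanced core
(must lie within the myocardium), finds the peak intensity there, and
labels myocardial pixels **strictly above** half of that peak, minus any
exclusion zone.  The printed half-peak rule is invariant to positive
intensity scaling but not to additive offsets; a `baseline="min"` variant
(threshold halfway between the myocardial minimum and the peak) is fully
affine-invariant and is provided for offset-shifted reconstructions.

## Agreement statistics

Differences are oriented first-argument minus second everywhere.
Bland–Altman reports mean difference and bias ± 1.96·SD (sample SD).
Lin's CCC uses population (1/n) moments.  ICC is the two-way
random-effects absolute-agreement form computed from the subjects×raters
mean squares; both single-measure ICC(2,1) and average-measure ICC(2,k)
are reported because published agreement values rarely state which form
was used.  The within-subject CV uses the root-mean-square method
100·√(mean(d²/2))/grand-mean (CV definitions vary widely in the literature —
this one is stated so numbers are comparable).  The paired t-test is the
standard two-tailed form.  Bonett's (2002) ICC sample size is the closed
form ⌈8·z²·(1−ρ)²·(1+(k−1)ρ)²/(k(k−1)w²)+1⌉; for ρ=0.90, w=0.10, k=2,
α=0.05 it evaluates to 57.  Published repeatability studies sometimes
quote smaller n for the same inputs (variant formulas and software
defaults differ); this package documents and uses the closed form above.

## Image quality and clustering

SNR = mean(scar)/SD(healthy myocardium) by default (the numerator is
switchable to healthy myocardium — both conventions exist); CNR =
|mean(scar) − mean(healthy myo)|/SD(healthy myo), with healthy myocardium
defined as myocardium minus scar.  Entropy (base-2, 256-bin histogram),
dynamic range and the intensity CoV are computed on the min–max rescaled
8-bit image.  Cluster structure uses k-means (20 seeded restarts) on
z-scored quality vectors with silhouette-selected k, and a two-sided
Mann–Whitney rank test compares any per-slice metric between two clusters.

## Numerical choices and degenerate inputs

ε = 1e-6 throughout the losses; BCE clamps probabilities to [ε, 1−ε];
0·log 0 := 0 in the KL term.  Constant slices normalize to zeros with a
warning.  Empty masks: error for prompt construction and FWHM ROIs,
sentinel for Hausdorff, mass 0.  Degenerate agreement inputs (zero
variance) return undefined sentinels rather than NaN.  All stochastic
components accept explicit seeds and are reproducible run-to-run on one
device.

## Known limitations

The tiny backbone is a per-pixel classifier: it has no learned spatial
context beyond its engineered features and is not a substitute for a
foundation-model backbone on real data — it exists to exercise the
training, prompting and evaluation contracts at desk scale.  The phantom's
intensity model is piecewise constant plus smooth corruption; real LGE
texture, surface coils and reconstruction filters are richer.  Agreement
statistics assume paired, roughly Gaussian measurement series.
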