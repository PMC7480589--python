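# Methods

`evsort` reimplements an imaging-flow-cytometry cell-sorting pipeline that
separates **apoptotic cells** from **EV-decorated cells** (live cells with
phosphatidylserine-positive extracellular vesicles attached), using only the
two images the cytometer records per cell: a brightfield channel and one
fluorescence channel from a PS-binding stain. This note documents the model,
the synthetic data that stands in for the unavailable raw images, the
numerical choices, and what the tests do and do not establish.

## The sorting model

### Channel-wise convolutional autoencoder (CAE)

Each 32×32 16-bit channel is compressed by its **own** encoder
(three stages of 3×3 convolution → batch normalisation → ReLU → 2×2 max
pooling; widths 16→32→8; spatial size 32→16→8→4) into a 4×4×8 tensor.
The two bottlenecks are concatenated (4×4×16) and flattened into the
**256-dimensional feature vector** — brightfield coordinates 0–127,
fluorescence coordinates 128–255. Because the encoders never see the other
channel, zeroing one channel provably leaves the other half of the feature
vector unchanged; the channel-wise Gini-importance analysis rests on this.

A single decoder maps the 4×4×16 bottleneck back to the 2-channel image:
three convolutions at 4×4 resolution (widths 128, 128, 32), then
2× nearest-neighbour upsampling with one convolution at each of 8×8 (→8)
and 16×16 (→8), and a final linear 3×3 convolution to 2 channels with no
batch normalisation. Placing the wide convolutions at the 4×4 resolution
keeps the parameter count at ~221k (inside the intended ≈200k budget)
while costing roughly a third of the arithmetic of a decoder that widens
after upsampling — this is what makes 30-epoch CPU training practical.

Training is unsupervised reconstruction: MSE loss (MAE available), Adam at
1e-3, batch size 64, a seeded 90/10 train/validation split, and the
checkpoint with the lowest validation loss is the one used everywhere
downstream. The decoder is never evaluated at inference time.

**Intensity handling.** Pixels are fed as raw integer counts divided by the
fixed full-scale constant 65535. The first layer of each encoder is
conv + batch-norm, so extracted features are exactly invariant to this
constant; it exists because a reconstruction target of order 10⁴ cannot be
reached by Adam-scale (≈lr per step) parameter updates within a realistic
epoch budget, whereas a target of order 1 can. No data-dependent
normalisation is applied anywhere.

The layer stack itself (`evsort.nn`) is a small numpy implementation —
im2col convolutions executed as BLAS matrix products, with an equivalent
shift-accumulate path chosen automatically where the im2col buffer would
dominate memory traffic. Both paths are checked against each other and
against finite differences in the test suite.

### Random-forest sorter

A scikit-learn random forest (1000 trees, `max_features="sqrt"`) is trained
on the CAE features of an annotated cohort (CAE-RF), or on a classical
feature set (CP-RF baseline). "Training the sorter" always means training
only the forest; the autoencoder is trained once, unsupervised, and reused.
Every cell receives a label — `ev` iff P(ev) strictly exceeds the 0.5
threshold, ties resolved to `apoptotic` — so forest-based sorting never
produces an "unknown" class. No class weighting is applied by default
(configurable); the forest is explicitly exercised at the ~66:1 imbalance
of the annotated corpus.

### Classical feature baseline

52 features, 26 per channel, covering the families a CellProfiler-style
pipeline would produce: intensity statistics (mean, median, sd, mass,
min/max, 4 quantiles), morphology of the Otsu-thresholded object (area,
perimeter, eccentricity, solidity), Haralick texture at distance 1 over a
32-level co-occurrence matrix (6 properties, 4 directions averaged), a
granularity spectrum (fraction of intensity removed by grey openings at
radii 1, 2, 4), and spot-like descriptors (local-maximum count above
median + 3·sd, max/mean ratio, max − median). Degenerate inputs are
defined: a constant image has zero sd, zero texture contrast and zero
local maxima. The schema is deliberately compact rather than a clone of
any particular published pipeline; its role is to be strong within-batch
and to expose the batch-effect brittleness of fixed decision thresholds.

### Manual gating baseline

Axis-aligned rectangular gates over two named features, one rectangle per
class; containment is closed on the lower bound, open on the upper. Cells
in neither gate are `unknown`; cells in both resolve to `apoptotic`
(documented priority) and are counted in a diagnostics field. Accuracy is
reported both with unknowns as errors and with unknowns removed from the
denominator.

## Synthetic data

No raw images are distributed with the study this package reproduces, so a
generator (`evsort.simulate`) emulates the two phenotypes from their
qualitative descriptions; all sizes in pixels, intensities in 16-bit counts:

* **Cell body** — soft-edged ellipse, radius ~N(9.5, 1.0) clipped to
  [7, 12], mild ellipticity and centre jitter. Brightfield: flat background
  18000 with a darker, textured body and a dark rim.
* **Apoptotic** — fluorescence covers 70–95% of the body (an unstained cap
  cut at a random orientation) at level ~12000, modulated by a clumpy,
  strictly positive patch field (patchiness 2.0, mean 1) — *in-vivo*
  staining is patchy, not even — plus 1–6 densely stained blebs
  (radius 1.3–2.4, intensity 18000) at the body periphery.
* **EV-decorated** — body fluorescence stays at the background (1500);
  1–4 punctate spots (radius 1–2.5, amplitude ~20000) sit on an annulus at
  0.8–1.1× body radius with ≥14 px separation (so defaults are
  well-separated for spot counting). Spot-count probabilities
  (0.4, 0.3, 0.2, 0.1) favour single spots.
* **Noise** — Gaussian PSF blur (σ 0.6), Poisson shot noise (gain 8), and
  additive Gaussian read noise at 2% of the dynamic range, clamped to
  [0, 65535].

Apoptotic cohorts therefore carry a higher total fluorescence than EV
cohorts (as the real stain does), and a single threshold on total
fluorescence already separates the classes with AUC > 0.95: the learning
problem is well-posed by construction, and "near-perfect same-batch AUC"
is the expected outcome, not a discovery.

### Batch effect

`BatchEffectConfig` implements two image-level acquisition shifts:

* `gain_shift` — fluorescence × gain + offset, clamped.
* `in_vitro_uniform` — *evenly distributed* staining: the smooth
  within-body fluorescence is replaced by a uniform fill at
  gain × (cell's own mean level) + offset, while small-scale bright detail
  (spots, bleb tips) is preserved on top. The default
  (`BatchEffectConfig.in_vitro()`: gain 1, offset 12000) additionally
  raises the whole cell interior, as excess dye does.

The batch-robustness trial mirrors the original study design: the CAE is
trained on *in-vivo-like* images; the annotated cohort that trains the
forests is *in-vitro stained* (transform applied); the test cohort is
in-vivo-like again. Under this shift the classical baseline collapses while
CAE-RF degrades only mildly. The mechanism is worth stating because it
constrains interpretation: scale-free classical features (granularity,
max/mean ratio) encode punctate-vs-diffuse staining so directly that *no*
class-preserving intensity shift breaks their within-cohort ranking — the
collapse comes from the train-side contrast compression (uniform fill +
background elevation) placing the forest's decision thresholds off the
test distribution. A batch effect dominated by multiplicative gain does
the opposite (hurts the CAE, spares the ratios) and is not what the
in-vitro/in-vivo contrast looks like.

### What the generator does not model

Optics beyond a Gaussian blur (no realistic PSF/defocus), debris and
doublets, necrotic or live/dead-positive cells, segmentation errors from
the instrument, spectral spillover, and the full heterogeneity of real
staining. Passing tests therefore demonstrate that the *pipeline* behaves
as specified on data with the stated structure — not that the reported
AUCs would be attained on any particular real dataset.

## Spot and colocalisation analytics

* **Spot mask** — Gaussian pre-filter (σ 1, attenuates single-pixel noise
  spikes several-fold while leaving multi-pixel spots nearly intact); bright detail
  = white top-hat with a radius-3 disc; local background = annulus median
  (radii 4–7) above the global image floor (detection is therefore
  invariant to constant offsets); a pixel seeds a spot when its detail
  exceeds (ratio − 1) × background with ratio 3, subject to an absolute
  floor of 50 counts so blank images stay empty. Seed regions containing a
  local maximum are kept, restricted to their half-maximum core (so
  adjacent spots stay separable), filtered at ≥2 px, and dilated by a
  radius-4 disc. Spot count = 8-connected components of the mask; spots
  closer than roughly twice the dilation radius merge — documented
  behaviour, not an error.
* **Bright detail similarity (BDS)** — Pearson ρ of the two channels'
  bright-detail images over the union of their spot masks, transformed as
  log2((1+ρ)/(1−ρ)) and capped at ±10; an empty or degenerate mask scores
  0. Cells with BDS above the operating threshold (default 0.7) count as
  colocalised; cohort colocalisation fractions carry 95% Wilson intervals.
  The vendor's exact BDS formula is proprietary; this transform preserves
  the published decision rule's shape and threshold.

## Evaluation

ROC/AUC via the empirical curve (equivalently the tie-corrected rank
statistic; an exhaustive pairwise oracle backs this in tests), Wilson score
intervals with the z-quantile computed from the requested confidence
(closed form; cross-checked against statsmodels), stratified seeded k-fold
cross-validation (stratification matters because the annotated corpus has
a 415-cell minority class), and 3×2 confusion tables with accuracy both
counting and omitting `unknown` gating output.

## Numerical and design choices

* Seeds control every stochastic step (generation, splits, initialisation,
  forests); identical seeds give bit-identical images, checkpoints and
  population files.
* Population files use an open plain-text dialect (`#population <name>`,
  one object id per line) rather than the vendor's binary format;
  round-trips are value-exact and duplicate ids are rejected by name.
* Centre-crop/pad for non-32×32 exports is symmetric with the extra pixel
  trimmed at the high end; coordinates are 0-based, row-major.
* Gates in the acceptance comparison are drawn as per-class [0.5%, 99.5%]
  quantile boxes over (total fluorescence mass, stained area) of the
  annotated cohort — the kind of rectangle an operator would draw on a
  training scatter plot.
* Study sizes used by the acceptance checks: 2,000 training and 1,000 test
  cells per class, 30 autoencoder epochs, forests of 1000 trees trained on
  400 annotated cells. These are the package's desk-scale study
  conditions; the architecture and every default above are independent of
  them.

## Known limitations

The decoder reconstruction is optimised for feature quality, not fidelity
(nearest-neighbour upsampling leaves block artefacts). The CAE's batch
robustness is an empirical property of the feature geometry, not a
guarantee; transforms far outside the calibrated in-vitro shift can break
it. Spot counting is reliable only at the documented separation; merging
under dilation is inherent to the mask definition. The classical schema is
a family-faithful stand-in, not a reproduction of any specific published
feature list.
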