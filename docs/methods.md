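# Methods

## Problem setting

The package implements the analysis chain used to classify grain (paddy rice)
varieties from visible/near-infrared hyperspectral images of grain piles:
radiometric calibration of raw cubes, mean-spectrum extraction from a square
region of interest (ROI) per grid cell, spectral preprocessing, feature-
wavelength selection, supervised classification, and Shapley-value attribution
of the classifier's decisions back to wavelengths. A sample throughout is one
mean ROI spectrum on a 224-band axis spanning 397–1003 nm.

Because comparable real datasets are typically proprietary, every stage is
driven by a seeded synthetic generator that emulates the study design
(13 varieties × 10 storage boxes × 4×7 grid cells = 3640 spectra) and the
statistical structure of grain reflectance. All empirical statements below are
recomputed by the test suite or `scripts/acceptance.py`; none are copied in.

## Synthetic data model

**Template curve.** Each variety's noise-free reflectance is a sum of
interpretable components: a logistic red-edge sigmoid (centered 720 nm, width
38 nm) rising from a 0.16 visible base to a 0.55 NIR plateau; a Gaussian green
peak at 550 nm (height 0.05); Gaussian absorption dips for blue husk pigments
(420 nm, depth 0.04), the ~670 nm pigment band (depth 0.05), and water
overtones at 930/970 nm (depths 0.02/0.03). Templates are clipped to
[0, 1.05].

**Variety signal.** Varieties share this base curve and differ through
Gaussian bumps at eight fixed centers inside three signal windows — 400–440,
580–700 and 880–960 nm — with amplitudes `~ Normal(0, s)` and center positions
jittered by `Normal(0, 800·s)` nm (clipped to two bump widths), where
`s = separation_scale`. Amplitude effects model pigment/water loading
differences; center shifts model absorption-maximum position differences, the
part of the signal that is genuinely nonlinear in band space. Green-peak
height, NIR level and red-edge position get jitter an order of magnitude
smaller, so between-variety variance concentrates in the windows (a planted
contract the tests verify by per-band F-statistics). `s = 0` reproduces
identical templates exactly.

The default `separation_scale = 0.008` was fixed once, by running the desk-
scale benchmark below across template seeds, so that the CNN-Transformer
lands in the mid-90s test accuracy — the difficulty regime of closely related
hybrid varieties — while the model ordering (attention-augmented CNN over
plain CNN over linear PLS-DA) is stable in the median. Smaller values put the
linear baseline above the 1D-CNN on a nontrivial fraction of template draws;
larger values saturate every model near 100%.

**Noise model.** Per spectrum: multiplicative gain `~ Normal(1, 0.10)` and
additive offset `~ Normal(0, 0.02)` (the scatter pair SNV removes exactly), a
random quadratic baseline drift of amplitude 0.01 (what baseline correction
and detrending target), and i.i.d. per-band sensor noise with SD 0.006 —
deliberately larger than the ~0.001 a 50×50-pixel ROI average would give, to
stand in for the grain-arrangement and moisture variability that ROI
averaging does not remove. Spectra are clipped to [0, 1.2] (calibrated
reflectance can exceed 1 on specular pixels). Scatter parameters are drawn
from per-(box, cell) seed substreams, so simulating a raw scene and
calibrating it reproduces the directly simulated dataset up to pixel noise —
a two-path consistency the tests assert.

**What the generator does not model.** Radiative transfer in husks, within-box
spatial correlation, instrument drift over sessions, moisture kinetics, or the
actual effect sizes of real varieties. Passing tests therefore demonstrate
that the pipeline recovers planted structure under realistic noise — not that
real varieties are separable at any particular accuracy.

## Acquisition

Calibration is the flat-field identity `(raw − dark) / (white − dark)`,
mapping the dark frame to 0 and the white reference to 1 per voxel; voxels
where white equals dark raise an error (naming the voxel count) rather than
being masked, because silent masking would change band counts downstream.
ROIs are squares centered in each grid cell; coordinates are 0-based,
row-major, half-open. The train/test split holds out whole boxes per variety
(2 by default: 2912 train / 728 test on the full design), eliminating
acquisition-unit leakage; the seed is recorded in the split for audit.

## Preprocessing

All five methods are stateless row-wise maps, so train/test application is
leakage-free by construction.

* **SNV** — subtract the row mean, divide by the row SD (sample SD, divisor
  n−1, stated so tests are bit-stable). Exactly invariant to per-spectrum
  gain/offset.
* **SG** — Savitzky–Golay smoothing, default window 11 / polyorder 2, edges by
  polynomial fit on the truncated window.
* **BC** — subtract the least-squares straight line, then shift the row
  minimum to 0. The projector form makes the map exactly linear-drift
  invariant and idempotent; a rubber-band variant through the two lowest hull
  points was rejected because its contact points move under drift, breaking
  exact drift cancellation.
* **DT** — subtract a least-squares polynomial (default order 2) over the
  wavelength axis.
* **FD** — central differences divided by the nm spacing (gap 1), one-sided at
  the edges so band count is preserved; an SG-derivative is available by
  composing SG with FD.

## Wavelength selection

CARS, UVE and IVISSA share a PLS2 core (partial least squares on one-hot
class indicators, no autoscaling — autoscaling would inflate UVE's tiny noise
columns to unit variance). The inner criterion is stratified k-fold RMSECV of
the one-hot response, with the argmax misclassification rate recorded
alongside; RMSECV was chosen over the misclassification rate because the
latter is coarse enough that band subsets tie constantly, making "best
subset" ill-defined.

* **SPA** grows greedy chains by maximal projection residual norm; with labels
  available, chains from each candidate start are compared by inner CV.
* **CARS** runs a Monte-Carlo loop: PLS on a random 80% sample subset, band
  weights from |coefficients| (summed over classes), retention count from the
  exponentially decreasing schedule `r_i = a·e^(−k·i)` fixed by `r_1 = 1` and
  `r_N = 2/p`, then adaptive reweighted sampling *without* replacement of
  exactly the scheduled count (so the retained-count trace is deterministic
  and nonincreasing). Exact RMSECV ties resolve toward the smaller set.
* **UVE** appends uniform noise columns scaled to `1e−5` of the data SD,
  refits PLS over leave-one-out (small n) or 80% Monte-Carlo splits, computes
  reliability `c_j = mean(b_j)/SD(b_j)` per column (max over classes), and
  keeps real bands whose |reliability| exceeds the largest noise-column
  reliability. Noise columns can never be returned.
* **IVISSA** is an interval-weighted shrinkage approximation of the published
  interval-space family: contiguous intervals (default width 8, last interval
  shorter but never dropped), submodels drawn with inclusion probability equal
  to interval weights, weights reset to each interval's frequency among the
  best fraction of submodels, bands returned from intervals with final weight
  above 0.5.

Selected cardinalities are data-dependent outcomes, not targets; the exact
arithmetic the package reproduces is `reduction % = 100·(1 − kept/total)` to
two decimals.

## Classifiers

* **PLS-DA** — PLS2 on one-hot labels, argmax decision; components chosen by
  4-fold CV over a small grid when unset.
* **SVM** — RBF kernel, one-vs-one multiclass (one-vs-rest decision values for
  scoring); (C, γ) grid-searched by 4-fold CV when unset.
* **1D-CNN** — three conv blocks of (8 filters, kernel 5), (16, kernel 3),
  (16, kernel 3), stride 1, each followed by batch normalization, ReLU and
  width-2 max pooling (pool width is a package choice; the source
  architecture leaves it open), then flatten, a 64-unit fully connected layer
  with dropout 0.1, and a linear output layer. 'Same' padding keeps selector-
  reduced inputs viable through three pool stages.
* **CNN-Transformer** — non-overlapping patches of 8 contiguous bands are
  linearly embedded to d_model = 64, sinusoidal positional encoding is added,
  and one post-norm encoder block (4-head scaled-dot-product self-attention,
  feed-forward width 128) mixes long-range inter-band structure before the
  identical conv stack and head. Patch tokens rather than per-band tokens are
  a deliberate choice: they cut the attention cost by ~64× (28×28 versus
  224×224 weight matrices per head) while preserving the long-range-dependency
  mechanism; the patch width shrinks automatically on short inputs so at
  least 8 tokens survive pooling.

Both networks train with softmax cross-entropy and Adam (lr 0.001), batch
size 64, dropout 0.1; the nominal budget is 1000 epochs, and every entry
point accepts a reduced budget. The whole forward/backward engine is plain
numpy with explicit gradients, validated against central finite differences
in the tests; all randomness (init, shuffling, dropout) flows from one seeded
generator, so runs are bit-reproducible single-threaded. Network inputs are
standardized per band with training statistics (recorded in the model).

Desk-scale benchmark: the reduced design 13 varieties × 4 boxes (728 train /
728 test after holding out 2 boxes per variety), raw spectra, a 100-epoch
budget for both networks. The budget matters: at 60 epochs the transformer is
still converging (its loss decays more slowly than the plain CNN's) and the
two networks' medians can cross; by 100 epochs the attention model is
reliably on top. Median test accuracy over template seeds orders
CNN-Transformer ≥ 1D-CNN ≥ PLS-DA; the acceptance suite asserts the ordering
over 10 seeds and the acceptance script reports the medians over 10.

## Evaluation

Multiclass metrics use the one-vs-rest decomposition: per class,
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); accuracy is the
trace over the total. The recall formula follows the standard definition; a
printed source formula equating recall with precision is a typographical
slip and is not reproduced. Aggregation is support-weighted by default —
under which aggregate recall is algebraically identical to accuracy
(Σᵢ (supportᵢ/N)·(TPᵢ/supportᵢ) = trace/N), the signature visible in result
tables whose recall column equals test accuracy — with macro averaging by
flag. Division by zero yields 0 with a warning so aggregates stay defined.
PCA is mean-centered SVD with the largest-magnitude loading of each component
forced positive.

## Shapley attribution

One estimator serves all four model kinds through their per-class score
functions (class probabilities by default; decision values for the margin
models are softmax-normalised), keeping cross-model comparisons on one scale.
The sampling estimator walks random band permutations from a background
spectrum to the explained spectrum, averaging score increments; the
background is cycled in shuffled order, so when the permutation count is a
multiple of the background size, local accuracy (base value + attributions =
model output) holds exactly, not just in expectation. The exact estimator
enumerates all 2^p coalitions with Shapley kernel weights and is the oracle
the sampling estimator is tested against (≤ 14 bands). Default background:
100 training spectra; the explained class is the model's prediction per
sample unless a class index is fixed. Summaries rank bands by mean |value|
across samples, ties toward the shorter wavelength; window enrichment reports
the top-k fraction inside nm windows against the uniform baseline.

## Pipeline

`run_experiment` executes the preprocess × selector × model grid with a fixed
stage order (preprocess, then selection on the training partition only —
whole-set selection exists behind a flag but is leakage-prone — then CV, fit,
and held-out evaluation). Each grid cell is failure-isolated; finished cells
are reused byte-identically on rerun (crash-resume); a manifest records the
config hash, seeds, and train/held-out box ids so leakage is auditable. The
best cell is the maximal test F1, ties broken by test accuracy, then fewer
bands.

## Numerical and degenerate-input policy

Constant spectra make SNV undefined → error naming the offending rows.
White = dark voxels → calibration error, not masking. Classes smaller than
the fold count → stratification error. Selector indices are always sorted,
unique, in range. Zero-probability attention rows cannot occur (softmax).
Metric zero-divisions → 0 with a warning. All preprocessors preserve shape
and finiteness; these are property-tested.

## Known limitations

* IVISSA is the least specified method of the four in its source lineage; the
  implementation is an interval-weighted shrinkage faithful to the name and
  is labelled an approximation.
* The numpy training loop is single-threaded and desk-scale; the 1000-epoch
  nominal budget on the full 2912-sample design is possible but slow, and all
  shipped runs use reduced budgets, stated where they occur.
* Synthetic accuracies are not forecasts of real-data accuracies; only the
  qualitative structure (preprocessing effects, selector enrichment, model
  ordering) transfers.
* ENVI I/O covers the flat-binary + text-header layout with BSQ/BIL/BIP
  interleaves and byte order 0; exotic header features (bad-band lists,
  per-band gains) are out of scope.
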