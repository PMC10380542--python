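# Methods

This note records the models the package implements, the defaults it ships
with, what the synthetic designs do and do not emulate, and the choices made
where the design space was genuinely open. Every number quoted here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not itself measure.

## Problem setting

A seed lot contains three rice varieties (zheyou5, chuan398A, chuan345A),
each in a genetically modified (*cry1Ab/cry1Ac*-carrying) and an unmodified
parent form. Per-seed spectra come from two instruments: NIR hyperspectral
reflectance (256 bands, 874–1734 nm, trimmed to 200 bands in 958–1630 nm)
and terahertz time-domain absorbance (93 bands, 0.3–2.0 THz). Two facts
shape the method: between-variety spectral differences are large, and the
GM effect is a small, consistently *negative* shift (non-GM reflectance /
absorbance sits above GM) concentrated in a minority of bands. A single
flat 6-class model must spend capacity separating varieties before it can
attend to the GM signal, so classification is split into a cascade:
phase 1 predicts the variety; phase 2 hands the same spectrum to that
variety's dedicated binary GM model.

## Network architecture

Both phases share one template, differing only in output width (3 vs 2):

1. **Multireceptive-field module 1** — four parallel stride-1 Conv1d layers
   (kernel sizes 1/3/5/7, 'same' padding, 128 filters each) over the
   1-channel spectrum; outputs are summed elementwise and rectified. The
   raw spectrum is concatenated back along the channel axis (→ 129
   channels), letting later layers reuse the unprocessed signal.
2. **Module 2** — the same four-kernel pattern with 64 filters on the
   129-channel tensor, summed and rectified. The summed 64-channel map
   feeds forward directly; no second concatenation (the tabulated channel
   budget lists module-2 outputs as 64).
3. **Common stage** — Conv1d(64, k=3, pad=1) → ReLU → MaxPool(k=3, s=2,
   p=1) → Conv1d(32, k=3, pad=1) → ReLU → MaxPool. Each pool maps length
   L to ⌊(L+2−3)/2⌋+1 (200→100→50; 93→47→24).
4. **Head** — a single affine map from the flattened features to the class
   scores. A one-layer head is the minimal reading of "fully connected
   layers"; the class confidence is the softmax maximum, applied at
   inference only (training uses softmax cross-entropy on the raw scores).

The stack (conv/pool/linear forward and analytic backward, Adam, Kaiming
fan-in init) is implemented in numpy within the package; gradients flow to
the parameters and to the *input*, which the wavelength selection reuses.
Unit tests verify every backward pass against central finite differences.

**Training protocol.** Adam, batch size 256, learning rate 5·10⁻⁴, 10,000
epochs, Kaiming-normal init, and a stratified 10% validation carve-out of
the training set whose accuracy decides which parameter snapshot is kept
(ties → earliest epoch) — these are the protocol defaults in `TrainConfig`.
Two learning rates circulate for this protocol (10⁻³ and 5·10⁻⁴); the
config default is 5·10⁻⁴ and the scaled experiments below use 10⁻³. All experiments in this package
override `epochs` downward and divide the filter counts by a width scale
(usually 8), because at desk scale (hundreds of samples, 1 CPU) the
full-width 10,000-epoch protocol is unnecessary for the synthetic designs
— the scaled models already saturate validation accuracy.

**Tie-breaks and contracts.** Argmax ties resolve to the lowest class
index. A spectrum routed to a variety with no registered GM model raises a
`MissingModelError` naming the variety rather than guessing.

## Synthetic designs

No public dataset pairs GM/non-GM rice-seed spectra, so the package ships a
simulator whose defaults encode the study conditions:

* **Terahertz design** (93 bands, 0.3–2.0 THz): per-variety templates =
  rising baseline + Gaussian absorption peaks near 0.3, 0.6, 1.0 and
  1.25 THz with variety-specific amplitudes (chuan345A strongest around
  0.6 THz) plus constant variety shifts; per-cell sample counts
  550/554/588/543/578/565 (total 3378). The GM offset is −0.025 absorbance
  units at eight bands around the 1.0 and 1.25 THz features and zero
  elsewhere; non-GM mean ≥ GM mean at every band by construction.
* **NIR design** (256 bands, 874–1734 nm): smooth reflectance with broad
  water/starch-like dips, 800 seeds per cell, GM offset −0.02 at ten bands.
* **Noise** is i.i.d. Gaussian per band, sd 0.01 (≈ 2–4% of the
  between-variety contrasts). Gaussian noise keeps per-band statistics
  analyzable (the planted bands are exactly the bands with the largest
  two-sample t-statistics, which a test verifies by brute force).
* **Cubes**: seeds are axis-aligned ellipses with jittered radii placed
  without contact on a dark background; the simulator returns the exact
  label image so segmentation can be scored pixel-by-pixel.

What the simulator does **not** emulate: scattering artifacts, correlated
(pink) instrument noise, moisture gradients, seed-orientation effects,
overlapping/touching seeds, or any physical radiative-transfer model.
Passing the recovery experiments therefore shows the pipeline is correct
and sensitive under its stated assumptions, not that accuracies obtained
on real instrument data transfer.

## Preprocessing choices

* Calibration is the standard flat-field form `(raw − dark)/(white −
  dark)`; a voxel with white = dark raises an error naming the position.
* Segmentation thresholds the 1363 nm reference image against its 11×11
  local mean (strict ">", offset 0 by default) and labels 8-connected
  components, dropping components under 5 px. A scale-relative guard
  (10⁻⁹ × image max) keeps separable-filter rounding from flipping the
  strict comparison on flat regions. On noiseless planted cubes the
  recovered partition equals the ground truth exactly.
* The moving average (window 5) truncates at the edges (mean over the
  in-window bands) rather than padding with phantom values.
* airPLS: second-difference penalty λ = 1, 15 iterations, weights zeroed
  where the residual is nonnegative and grown exponentially with
  negative-residual magnitude, early exit when the negative-residual mass
  falls under 0.1% of the total absolute signal; endpoints stay anchored.
  On a fixture of sharp Gaussian lines (sd 1.5 bands, heights 0.7–1.2) on
  a linear drift of amplitude 0.5 over 200 bands, the estimated baseline's
  RMSE stays under 5% of the drift amplitude and every corrected apex
  lands on its planted band. λ = 1 is a *weak* smoother: it tracks drift
  under narrow lines but climbs into features broader than ~5 bands, which
  is also why the demo pipeline leaves baseline correction off for
  simulated spectra (they carry no drift; correction would only erase the
  broad variety features). Enable it (`baseline: true`) for real
  terahertz measurements.
* Band trimming keeps centers in the closed interval; on the uniform
  256-point grid the printed interval retains exactly 200 bands.

## Wavelength selection

**Guided input optimization.** With the trained network frozen, a uniform
[0,1] random vector x is updated by plain gradient descent on
`L_C(x) = −f_C(x) + Σ_{i≠C} f_i(x) + w·Σ_j |x_j|` (f = pre-softmax scores).
The third term is implemented as an L1 (LASSO-style) penalty — the loss's
sparsity role only makes sense with magnitudes — with a `signed_sum` flag
for the literal signed sum. The protocol default is 15,000 iterations at
learning rate 6 with w = 1; because the loss is unbounded below for a
piecewise-linear network (x escapes along a ray), only the *relative* peak
structure of the optimized x is meaningful, and peak extraction is
scale-invariant by construction. Peaks of |x| above 0.2 × max are kept
greedily (descending amplitude, pairwise index separation ≥ 2). The
extraction rule is this package's own design; identity curves do not come
with a canonical discretization into wavelengths.

**SPA.** Chains are grown by repeated orthogonal projection on centered
columns (residual norms checked against an explicit Gram–Schmidt oracle in
the tests); every chain prefix from every start band (capped at 256 random
starts above 256 bands) is scored by PLS-DA cross-validation accuracy, best
subset wins (ties → fewer bands, then lexicographic). Maximum selection
size 13.

## Validation experiments (problem sizes and thresholds)

* **Cascade recovery** — default terahertz design at 200 seeds/cell
  (1,200 seeds), stratified 7:3 split, width scale 8, 60 variety epochs /
  150 GM epochs at lr 10⁻³. Pass: held-out variety accuracy ≥ 0.95 and
  every per-variety GM accuracy ≥ 0.90. The cross-variety transfer matrix
  is also computed; a GM model typically does best on its own variety
  (off-diagonal transfer degrades, the cascade's raison d'être), though the
  margin can be small at some seeds because the simulated GM offset vector
  is shared across varieties.
* **Band recovery** — five replicates of a binary fixture (40 bands,
  GM effect = five Gaussian dips of depth 0.08 and width 1.2 bands centered
  at known bands, noise sd 0.065, 300 seeds/class). Each planted feature is
  individually weak (≈ 1.2 noise sd), so a model good on validation must
  have pooled the whole set — the premise of attribution-based selection —
  and the validation ceiling stays below 1.0, so the best-accuracy
  checkpoint (width scale 4, 250 epochs, batch 32, lr 10⁻³) keeps refining
  instead of freezing on an early snapshot. Guided selection (lr 0.05,
  1,500 iterations, w 0.3, saliency averaged over five restarts per class)
  must recover ≥ 70% of planted bands within ±1 index and fully cover the
  SPA selection (max_k 6) in ≥ 4 of 5 replicates. The coverage outcome is
  itself stochastic: across three disjoint replicate batches the protocol
  achieved full coverage in 13 of 15 replicates, i.e. a batch can
  occasionally land at 3 of 5. Features span ~3 bands
  because the kernel-7 receptive fields can otherwise read a strictly
  single-band signal from a position shifted by up to 3 indices, which no
  ±1 tolerance could absorb; physical absorption features are likewise
  several bands wide.
* **Gradient check** — analytic ∇L_C vs central differences on a float64
  model, 30 probes, max relative error < 10⁻⁴.
* **Oracle equivalence** — moving average, SPA chains, confusion/metrics,
  PCA and softmax against brute-force references on 100–1,000 random
  instances each; micro-F1 ≡ accuracy on 1,000 random tabulations.

## Known limitations

* The numpy network is single-threaded and CPU-bound; the full-width
  10,000-epoch protocol is impractical here and is not what the experiments
  run. Accuracies quoted for real rice-seed instrument data cannot be
  reproduced because no such spectra are publicly available; the recovery
  experiments above are the substitute evidence that every pipeline stage
  behaves as intended.
* Guided selection on small fixture models has high sensitivity but modest
  precision: averaged saliency still yields extra peaks beyond the planted
  bands. The acceptance experiments score sensitivity (recovery, coverage)
  only.
* `softmax` logits are exponentiated after max-shifting; probabilities
  under ~1e-300 underflow to 0 (irrelevant for classification).
* PCA sign convention (largest-|loading| positive) makes score plots
  deterministic but is arbitrary, as any sign convention is.
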