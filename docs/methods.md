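# Methods

`texens` classifies biological texture images — the motivating case is
phase-contrast microscopy of stem-cell-derived retinal pigment
epithelium (RPE), whose cultures pass through fusiform, epithelioid and
cobblestone morphologies as they mature — by fusing large ensembles of
texture-descriptor channels. Each channel is a normalized feature
histogram feeding its own support vector machine; per-class scores are
added across channels (the *sum rule*) and performance is measured as
one-vs-all area under the ROC curve at image-level cross-validation.

## Sample unit and folding

The classification sample is a *subwindow*: one tile of a 4×4 grid cut
from a parent acquisition. All subwindows of a parent share a
`parent_id`, and the image-level protocols (`kfold_image(k)`,
`leave_one_image_out`) assign whole parents to folds, so a model is
never tested on tiles of an acquisition it has seen in training.
`kfold_plain(k)` ignores parentage and, when labels are supplied,
stratifies by class — the usual convention for row-level classification
CV, which also keeps label-permutation nulls centred near 50% AUC
(unstratified pooled CV on permuted labels is biased a few points below
chance at these sample sizes, a small-sample "anti-learning" effect).

## Base descriptors

All descriptors consume 2-D grayscale arrays in [0, 255]; RGB inputs are
converted with BT.601 luma weights (0.2989, 0.5870, 0.1140). Codes are
computed only where the full neighborhood fits (no padding), with
bilinear interpolation at off-grid circle positions.

* **LBP** — multi-scale uniform local binary patterns at (radius,
  points) = (1, 8) and (2, 16); the u2 mapping keeps the P(P−1)+2
  uniform patterns (≤ 2 circular transitions) in individual bins plus
  one bin for the rest (59 and 243 bins), riu2 additionally merges
  rotation orbits (P+2 bins). The comparison is `q_p − q_c ≥ 0`, so a
  tie counts as 1.
* **LTP** — the same difference coded ternary with threshold τ
  (default 5 intensity levels); the ternary pattern splits into a
  positive and a negative binary pattern, histogrammed separately and
  concatenated. At τ = 0 the positive half reduces exactly to LBP.
* **LPQ** — short-term Fourier phase in an r×r window (r = 3 and 5
  multi-scale) at the four low frequencies {(f,0), (0,f), (f,f),
  (f,−f)}, f = a/r. Kernels are DC-corrected (mean-subtracted) so
  constant regions respond exactly zero for every scalar frequency a.
  The 8 real/imaginary responses are decorrelated under the correlation
  model cov(x_i, x_j) = ρ^{‖x_i−x_j‖} using **symmetric (inverse square
  root) whitening** D^{−1/2}: unlike an SVD eigenbasis it is a unique
  matrix function of D and stays well-defined when the symmetric
  frequency pairs make eigenvalues degenerate. Bits are `y_i > 0`
  (so sign(0) → 0). The ternary variant thresholds variance-normalized
  components at ±τ (each decorrelated component divided by its standard
  deviation over the valid region), putting the published threshold
  grids {0.2 … 1} on a meaningful scale; a constant image (zero
  variance) keeps all components at zero.
* **LCP** — per riu2 pattern class, ridge-regularized (λ = 1e−6) least
  squares weights reconstructing the centre from its P neighbors over
  all class occurrences; the feature is |DFT(weights)| per class plus
  the class-occurrence histogram ((P+2)·P + (P+2) values per scale).
  The ridge keeps constant images (rank-deficient systems) finite;
  empty classes contribute zero blocks.
* **RICLBP** — co-occurrence of LBP code pairs at displacement 2R in
  four directions (0°, 45°, 90°, 135°), radii {1, 2, 4}. Pairs use
  **4-point** LBP codes; the 8-point variant in common use for plain
  LBP would give ≈33 000 co-occurrence classes per radius, which is
  disproportionate to the sample sizes this ensemble targets (and makes
  the 69-channel preprocessing ensemble of RICLBP infeasible in
  memory), while 4-point codes give ≈272 classes per radius. The
  rotation-invariant classes are orbits of (code₁, code₂, direction)
  under the quarter-turn map — rotate both codes by P/4 bits, advance
  the direction two 45° steps, swapping the pair when the displacement
  flips through 180° — enumerated by brute force and cached.
  Histograms are exactly invariant to 90° image rotation; a constant
  image occupies two classes (the axis-pair and diagonal-pair orbits,
  which quarter turns cannot merge).
* **WLD** — joint histogram of differential excitation
  ξ = arctan(Σ₈(q_p−q_c)/(q_c+1)) and central-difference gradient
  orientation. Bin counts (6 excitation × 8 orientation) are package
  defaults — the construction leaves them open — and configurable.
* **COLORS** — per RGB channel: mean, co-occurrence homogeneity
  (offset (0,1), 8 gray levels, Σ p(i,j)/(1+|i−j|)), standard
  deviation, 3rd–5th central moments and an 8-bin marginal histogram
  (42 values). Mean and sd are scaled by 255 and the k-th moment by
  255^k so blocks are commensurate; z-scoring happens later in the
  per-channel scaler anyway.

## BSIF

Filters are learned by PCA whitening to n = 8 components followed by
fixed-point ICA on l×l patches (l ∈ {3, 5, 7, 9, 11}). Patches are
per-patch mean-subtracted, confining them to the zero-DC subspace, so
every filter has exactly zero DC response — hence BSIF histograms are
invariant to additive intensity offsets. n = 8 (256-bin histograms) is
the descriptor's common operating point. Because shipping photographs
is out of scope, the default patch source is seeded noise with a 1/f²
power spectrum, matching the second-order statistics of natural images;
externally learned banks load from CSV+JSON. Banks are canonicalized
(unit-norm rows, sorted by response variance, sign fixed at the largest
coefficient) so learning is deterministic under a fixed seed; the
default bank seed is a package constant so channel definitions are
stable across runs. Thresholds th ∈ {−9 … 9} are in raw response units
of unit-norm filters on [0,255] images. `Size_Bsif` fuses the five
sizes at th = 0; `Full_Bsif` crosses sizes with the seven thresholds
(35 channels), reusing each size's response stack across thresholds.

## Preprocessing ensembles

Channel images are db4 wavelet subbands (1-level `Wa`: A,H,V,D;
2-level `WaH`: H1,V1,D1,H2,V2,D2,A2 — seven subbands, the approximation
retained once), Gaussian scale space `MRS` (original plus k = 3 and
k = 5 kernels, σ = 1, replicate borders), soft-quantized gradient
orientation images `OR` (d = 3), and a Gabor bank `Ga` of 4 scales × 4
directions. `Comb` applies Wa ∪ OR ∪ Ga to each MRS image:
(4+3+16)×3 = 69 channels. Every channel is linearly rescaled to
[0, 255] before descriptor extraction (BSIF/LPQ thresholds assume that
range); numerically-constant channels map to all zeros.

Numerical choices: DWT uses periodization so orthonormal db4 satisfies
Parseval's identity exactly (tested). Gabor scale s maps to frequency
ν_s = 0.25/2^{s−1} cycles/pixel with σ_s = 0.56/ν_s (a standard octave
bank; the construction names scales only), kernels are DC-corrected and
L2-normalized so responses are comparable across scales; with
x′ = x sinθ + y cosθ, the θ = 0 kernel modulates along y. OR defaults
are cell size w = 5, block radius L = 3, n = 8 surrounding cells
ordered counterclockwise from +x with weights 2^{−j}, and similarity
threshold τ = 0.01 on [0,1]-normalized aggregated magnitude maps; the
self-similarity test fires when the squared difference reaches τ. All
are configurable; the source formula's rendering is ambiguous and this
reading is the package's convention.

## Region-based splitting

The descriptor's label image is computed **once** from the original
image; complementary mask pairs (Map⁺, Map⁻) that partition the pixel
grid then split each histogram block in two, one SVM per side. Sources:
Sobel gradient magnitude binarized by Otsu (edge/non-edge; the
binarization rule is unstated upstream, Otsu is the package default),
difference of Gaussians with σ = (1, 2), DCT image-signature saliency
(x̄ = IDCT(sign(DCT(x))), m = G(σ=2)·(x̄∘x̄), min-max normalized,
thresholds 0.5 and 0.7 — nested masks), and db4 detail subbands
(|coefficients| bilinearly resized to image size, thresholded at their
mean; three detail-band pairs, the approximation pair behind a flag).
Counts in the plus and minus histograms always sum to the unmasked
histogram; an empty region yields an all-zero block rather than NaN, so
its SVM sees an uninformative sample.

## Multi-quinary coding and loci

The neighbor difference is coded into five levels by thresholds
0 < τ₁ < τ₂ and split into four binary patterns (digit values 2, 1, −1,
−2 in that order), each u2-mapped and histogrammed. MLQP crosses the 25
threshold pairs τ₁ ∈ {1,3,5,7,9}, τ₂ = τ₁ + {2,4,6,8,10} with geometric
loci: circle, ellipse (a=2, b=1), parabola (y = −x²/2c + c/2, c = 1,
|x| ≤ 2c), hyperbola (both branches via the cosh/sinh parameter,
|x| ≤ 2a), and Archimedean spiral r = a + bθ over θ ∈ [0, 4π) (b = 0
degenerates to points on the circle of radius a). Non-circular loci
rotate by β ∈ {0°, 45°, 90°, 135°}, giving the default family of 17
loci with P = 8 sampling points; the exact roster is open upstream, and
channel builders default to circle-only (25 channels) so the
combinatorial grid stays opt-in. MLCP applies the LCP construction to
each of the four binary patterns. MLPQ is ternary LPQ at five
thresholds (r = 3 and 5 concatenated); MLPQens crosses r × a × ρ × τ =
2×4×4×3 = 96 channels.

## SFFS

Sequential forward floating selection over channels maximizes the
internal 10-fold (group-aware) CV AUC of the sum-rule ensemble.
Out-of-fold score matrices are precomputed once per channel with a
fixed linear C = 1 SVM — a subset's objective is then a matrix sum plus
a ranking, which keeps the floating search (and the exhaustive oracle
used in tests) cheap; the full kernel grid belongs to the outer
per-channel training, not the selection objective. Forward steps add
the argmax channel (ties → lowest index), floating backward steps
remove any channel whose removal strictly raises the objective, and the
search stops at `max_size` (default 10) or when no addition improves,
so accepted objectives are non-decreasing.

## Classification and evaluation

Each channel standardizes features and selects kernel and
hyperparameters by stratified 5-fold CV on the training rows over
{linear, RBF} × C ∈ {0.1, 1, 10, 100} × (RBF) γ ∈ 2^{−6}…2², scored by
mean one-vs-all AUC; ties resolve to the earlier grid entry (linear,
then smallest C). The winner is refit with sigmoid (Platt) calibration
(`CalibratedClassifierCV`, `ensemble=False`): raw SVM margins are on
fold-specific scales, and calibrated posteriors are what make pooling
test scores across folds meaningful. Scores are row-stochastic; the
sum rule adds them and renormalizes.

One-vs-all AUC treats each class as positive against the rest, computed
as the Mann–Whitney rank statistic with ties counting ½, averaged over
classes and reported in percent. The primary figure pools test scores
from all folds; per-fold AUCs and their mean are also reported (which
of the two the original protocol used is not stated; pooled is this
package's primary).

## Synthetic fixture

The generator renders Voronoi-style cell mosaics with class-specific
parameters: anisotropic seed metric (elongation 3.0 / 1.3 / 1.0),
cell diameter (40 / 24 / 13 px on 256² parents), pigmentation
(0.15 / 0.25 / 0.7 — darker, more variable cell interiors and stronger
cell walls), additive Gaussian noise σ = 8, and a jittered hexagonal
seed lattice for the cobblestone class. It emulates the morphological
contrasts the real dataset is annotated by (spindle vs. globular vs.
tightly packed hexagonal cells) but none of the optics of
phase-contrast imaging — no halo artefacts, defocus, illumination
gradients, clutter or mixed-morphology tiles — so passing fixture runs
demonstrate that the pipeline's machinery is correct and that its
channels separate texture classes of this kind; they say nothing
quantitative about performance on real microscopy data, whose published
benchmark must be downloaded separately and run through the shipped
configs. Generation is bitwise deterministic given the seed.

## Problem sizes

Tests and the acceptance script use desk-scale inputs chosen to keep
the whole suite in the minutes range: descriptor oracles run on 8×8 to
16×16 random images; the full fixture is 3 classes × 5 parents × 16
subwindows of 64×64 (240 samples) evaluated with the complete SVM grid;
the ensemble-no-harm and permutation-null checks use reduced channel
grids or a fixed linear SVM where the full grid would multiply runtime
without changing what is being verified.

## Known limitations

* The upstream descriptor implementations are unpublished; filter
  banks, SVM internals and selection subsets will differ in detail, so
  numeric equality with published benchmark tables is not claimed.
* BSIF filters learned from 1/f² noise approximate, but are not, banks
  learned from natural photographs.
* The RICLBP pair-code order (4-point) and the WLD bin counts are
  package conventions where the constructions leave choices open.
* COLORS applies only to RGB inputs and is skipped for grayscale
  pipelines.
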