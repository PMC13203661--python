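# Methods

`dermopt` implements a two-part optimization pipeline for dermoscopy image
analysis: per-image contrast stretching driven by a hybrid bat /
artificial-bee-colony (BA–ABC) search, and wrapper feature selection by a
whale optimization algorithm (WOA) with a Shannon-entropy fitness, plus the
statistical evaluation layer used to compare the resulting classifiers.
This note records the models, their assumptions, the numerical choices, and
the places where the design was genuinely open.

## Contrast model

Images are converted to bi-hexcone HSL (lightness `L = (max+min)/2`); only
the lightness channel `ψL` is transformed, so hue and saturation are
preserved exactly (up to pixels whose lightness clips to pure black or
white, where RGB cannot carry chroma). Intensities are kept in `[0, 1]`
internally; 8-bit files are scaled by 255 at the I/O boundary.

The transformation is the classical local-statistics contrast form

    δg(x,y) = [Pδ·μg / (ψσ(x,y) + Pβ)] · (δf(x,y) − Pτ·ψμ(x,y)) + ψμ(x,y)^Pα

with windowed mean `ψμ` and population standard deviation `ψσ` (replicate
padding; default 3×3 window — the neighbourhood size is not dictated by the
model, and 3×3 is the smallest window that still defines a local scale) and
global mean `μg`. The gain amplifies deviations from the weighted local
mean, most strongly in flat regions; the `ψμ^Pα` offset conserves local
brightness. Outputs are hard-clipped to `[0, 1]`. Where `ψσ + Pβ = 0`
(zero-variance window with `Pβ = 0`) the gain term is defined as 0.
Negligible windowed variances (< 1e-14, pure float-cancellation residue)
are snapped to zero so this guard actually engages on constant regions.

The four parameters are box-bounded: `(Pα, Pβ, Pτ, Pδ)` in
`[0, 1.6] × [0, 0.5] × [0, 0.8] × [0.5, 1.5]`. This positional assignment
is the only physically coherent one — `Pδ` around 1 is a gain, `Pβ` a small
smoothing constant, `Pα ≤ 1.6` an exponent.

## Image-quality objective

A candidate enhanced channel is scored by

    C = log(log(ψs)) · edgels · G / (M·N)

* `ψs`: summed Sobel gradient magnitude (standard 3×3 kernels, replicate
  padding, magnitude = √(gv²+gh²)); gradient magnitudes below 1e-12 are
  snapped to zero so flat images score exactly zero.
* `edgels`: pixels with magnitude strictly above a threshold; the default
  threshold is the mean magnitude — parameter-free, and never satisfiable
  by every pixel of a non-constant field.
* `G`: Gini coefficient of the pixel intensities, computed by the sorted
  identity `Σ(2i−n−1)x(i)/(n²μ)` (O(n log n)); equivalence to the
  double-sum definition is a tested property. All-zero input returns 0 by
  convention.
* The double logarithm (base e) damps runaway stretching; its argument is
  floored at `e + 1e-9` so it is always defined. A gradient-free channel
  has zero edgels and scores exactly 0, so the floor only prevents NaN.

`C` is maximized. The Sobel/Gini factors are evaluated on the clipped
output channel — the image a user would actually see.

## Hybrid BA–ABC search

A shared population of 50 parameter vectors alternates between the two
metaheuristics (default one round: 50 bat iterations, then 50 colony
iterations — a 100-iteration budget; the bat swarm's final population seeds
the colony's food sources).

**Bat stage.** Frequency `ω = ωmin + (ωmax−ωmin)β`, velocity
`ν' = ω(d−d*) + ν + α(u−ν_thresh)` with a centred random term
(`ν_thresh = 0.5`, valid range `[0.45, 0.55]`), position
`d' = d + ν' + β(d−d*)·α·u`, all clipped to the box. With probability
`1 − P_i` the flight candidate is replaced by a local walk around the best
position scaled by the mean loudness (one objective evaluation per bat per
iteration). Acceptance requires improvement *and* a uniform draw below the
bat's loudness; acceptance decays loudness (`λ' = 0.9λ`) and raises the
pulse rate (`P' = 0.9(1−e^{−0.9t})`). The acceptance rule and the defaults
`ωmin=0, ωmax=2, λ0=1, ϑ=ϱ=0.9, α=0.5` are the canonical choices; all are
exposed in `BatConfig`. The `ν^{t−1}` in the velocity update is read as the
bat's current velocity — no two-step memory.

**Bee-colony stage.** Canonical employed/onlooker/scout phases with greedy
replacement and a scout limit of 20 failed trials. The roulette fitness is
the canonical mapping of the minimized surrogate `Cmin = −C` (`1+|Cmin|`
when negative, `1/(1+Cmin)` otherwise) minus `α_e·H`, where `H` is the
Shannon entropy of the source's bounds-normalized coordinates and
`α_e = 0.1`. The entropy term biases onlooker attention by how evenly a
source spreads across its box; `α_e = 0` recovers canonical ABC exactly
(tested against an independent canonical implementation sharing the draw
protocol). The subtraction's sign is configurable through the weight.

Per-coordinate random draws are independent; every draw derives from the
single run seed (default 42), so results are bit-reproducible.

## Whale-optimization feature selection

Agents hold continuous positions in `[0,1]^d`; a mask is the position
thresholded at 0.5 (the standard wrapper-FS encoding). Per agent per
iteration, with `α = 2 − 2t/Itermax` and fresh scalar draws `ρr, ρ, l`:
coefficients `A = 2αρr − α`, `C = 2ρr` (so `|A| ≤ α` always); with
probability `τ = 0.5` the agent exploits — shrinking encirclement
`O' = Obest − A·|C·Obest − O|` when `|A| ≤ 1`, else the logarithmic spiral
`O' = |Obest − O|·e^{bl}·cos(2πl) + Obest` (`b = 1`) — otherwise it
explores toward a random agent `O' = Orand − A·|C·Orand − O|`. Positions
are clipped after every update. Draws are scalars per agent because the
branch condition `|A| ≤ 1` needs a scalar amplitude. Defaults: 30 agents,
100 iterations. An empty final mask falls back to the top quarter of the
best position's coordinates, with a warning.

**Fitness.** The information a candidate subset carries is measured with
Shannon entropy, in one of two modes:

* `info_gain` (default, requires labels): each feature is scored by its
  information gain `IG_j = H(y) − H(y|x_j)` with the feature
  quantile-binned (8 bins); gains are normalized to sum to one across all
  `d` columns, and a mask of size `k` scores
  `Σ_{j∈mask} w_j − λ_s·k/d` with `λ_s = 0.5`. A feature is worth keeping
  exactly when its share of the total individual label-information exceeds
  the per-feature penalty `λ_s/d`; on the synthetic fixtures this retains
  the class-informative and redundant columns and drops most pure-noise
  columns, which is what produces substantial reduction percentages.
* `variance_entropy` (label-free fallback): the normalized Shannon entropy
  of the selected features' variance shares, `H(η)/log₂k − λ_s·k/d` with
  `η_p = var_p/Σvar`. This favours small, evenly dispersed subsets. It was
  measured during development to be indifferent to class information (its
  optimum is any two near-equal-variance columns), which is why it is not
  the default when labels are available; it remains useful as an
  unsupervised compaction criterion.

Masks with fewer than two features, or (in variance mode) only
zero-variance features, score `−∞`.

## Fusion and evaluation

Fusion is pure column-wise concatenation (`R^p ⊕ R^q → R^{p+q}`) with
per-column provenance tags; no normalization is applied at fusion time
(the classifier harness standardizes in-pipeline). Reduction percentages
are rounded to the nearest integer.

Confusion metrics follow the usual definitions; Jaccard `TP/(TP+FP+FN)`
and Dice `2TP/(2TP+FP+FN)` satisfy `D = 2J/(1+J)` identically. Ratios with
empty denominators are NaN rather than errors. Multi-class counts are
micro-averaged by default (macro averaging available). One-way ANOVA uses
the textbook decomposition with `p` from the F survival function; an
all-zero within-group SS reports `F = ∞, p = 0`. The classifier harness
wraps scikit-learn presets (quadratic SVM with inhomogeneous degree-2
kernel, weighted 10-NN with inverse-squared-distance weights, one-layer-25
and three-layer-10 MLPs, and a 30-member random-subspace ensemble of
linear discriminants) behind a stratified 80:20 split or stratified
k-fold.

## Synthetic fixtures

The lesion generator emulates the features the enhancer keys on: a
skin-toned background (lightness ≈ 0.65, hue 25°) with Gaussian texture
(SD 0.03), a darker elliptical lesion whose radius is modulated by random
low-order harmonics (irregular border) and whose edge is softened by a
σ=1.5 blur (diffuse boundary), optional dark hair strokes drawn as
quadratic Bézier curves, and a known mask. The default lightness gap of
0.12 is the low-contrast regime that motivates enhancement. It does *not*
emulate specular reflections, air bubbles, colour charts, vignetting, or
multi-tonal lesions — so a passing enhancement test shows the optimizer
improves the stated objective on controlled low-contrast inputs, not that
enhanced images help any particular downstream segmenter on clinical data.

The feature generator produces two balanced classes with informative
columns at `±separation/2` (unit noise SD; default separation 3),
redundant columns as scaled informative parents plus small noise
(|r| > 0.9), and standard-Gaussian noise columns, shuffled with recorded
index sets. Real CNN feature matrices are correlated in richer ways; the
fixture establishes recovery of *known* signal, not performance on deep
features. The group generator draws Gaussian accuracy samples for the
ANOVA layer.

## Problem sizes and determinism

Default study conditions: 128×128 fixtures, population 50 with a
100-iteration budget for enhancement (~8 s per image on one core), 30
agents × 100 iterations on 200×50 matrices for selection, 20-seed sweeps
for the behavioural summaries, and 1000 replicates for the type-I
calibration of the ANOVA layer. Every stochastic component takes a single
integer seed and is bit-reproducible; sweeps derive per-run seeds from the
master seed.

## Known limitations

* The objective's edgel threshold (mean gradient magnitude) adapts to each
  image; costs are therefore comparable between transforms of the *same*
  image, not across images.
* The per-image optimization offers no cross-image parameter sharing; a
  batch of images costs linearly.
* Information-gain weights score features individually; jointly
  informative but marginally silent feature pairs would be missed.
* The metaheuristics provide no optimality guarantees; tests assert
  behavioural properties (monotone best-so-far traces, bound adherence,
  recovery of surrogate optima within tolerance), not convergence.
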