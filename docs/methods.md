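# Methods

## Model

`leafmoe` classifies leaf-disease images with a mixture-of-experts (MoE) head
on vision-transformer features.  An input image `X` is split into fixed-size
patches, embedded and passed through transformer blocks, giving a token
matrix `H ∈ R^(N×D)` (N patches plus a class token, feature dimension D).
A pooled per-image vector `h` (class token by default, mean over patch
tokens as an alternative) is layer-normalized to `h_norm`; during training,
zero-mean Gaussian noise `ε ~ N(0, σ²)` is added, `h_pert = h_norm + ε`, as
a feature-space regularizer.

A linear-softmax gate `g(h_norm) ∈ Δ^E` scores E experts; routing keeps the
K largest gate weights, renormalizes them to sum to one and zeroes the rest
(ties break to the lower expert index, so routing is deterministic).  Every
expert is a two-layer MLP with dropout emitting a class distribution
`p_k = softmax(W2 · relu(dropout(W1 h_pert + b1)) + b2)`, and the final
prediction is the convex combination `p_final = Σ_k w_k p_k`.  All experts
are evaluated densely — the pool is small and the regularizers and
diagnostics need every expert — with unselected experts weighted zero.

The gate reads **detached** normalized features.  Its supervision (below) is
a noisy self-generated label; letting that gradient flow into the backbone
measurably stalls representation learning on some seeds, while detaching it
leaves the backbone driven purely by the classification loss.

## Objective

`L_total = L_class + L_gating + λ_e·L_entropy + λ_o·L_orthogonal + λ_u·L_usage`

* `L_class`: mean cross-entropy of `p_final` against the true label.
* `L_gating`: cross-entropy of the dense gate distribution against a
  self-supervised target — the expert assigning the highest probability to
  the true class (gradient-detached, ties to the lower index).  No extra
  annotation is needed and the gate is rewarded for recognizing
  specialization.  Config-switchable (`loss.gating_enabled`).
* `L_entropy`: the **negative** Shannon entropy of the renormalized routing
  weights, `(1/B) Σ_i Σ_j w_ij log w_ij ∈ [−log K, 0]`.  Minimizing it
  pushes the gate toward balanced, high-entropy routing.  The sign matters:
  adding positive entropy to a minimized objective would reward confident
  gates, the opposite of what an entropy regularizer is for.
* `L_orthogonal`: `Σ_{i<j} ‖W_i W_j^T‖_F` over the experts' first-layer
  matrices (configurable to second-layer or both).  Zero iff the experts'
  row spaces are mutually orthogonal; pushes experts toward non-overlapping
  feature detectors.
* `L_usage`: `Σ_j (ū_j − 1/E)²` where `ū_j` is the batch-mean routing weight
  of expert j, computed over the **full** pool with the sparse post-top-K
  weights (zeros for unselected experts).  Its purpose is keeping all E
  experts engaged, so the uniform target is 1/E; a `pool="selected"` option
  restricts the target to 1/K.  Range `[0, 1 − 1/E]`.

Defaults: E=10, K=3, expert hidden width 256 (64 in the desk-scale
experiments), dropout 0.1, σ=0.05, λ_e=0.5, λ_o=0.01, λ_u=0.1.  The entropy
weight is deliberately the largest: at 0.1 it is empirically too weak to
counteract the winner-take-all pull that the classification loss exerts on
the gate, and expert collapse proceeds almost unchanged.

## Training

AdamW (lr 1e-3 end-to-end, 2e-3 for head-only runs on cached features,
weight decay 0.01 on matrices only), batch size 32, 2-epoch linear LR
warmup — small from-scratch ViTs otherwise sit in a long loss plateau.
Everything is seeded: parameter init, batch shuffling, dropout masks and
feature noise derive from per-component generators, so a (config, seed)
pair reproduces a run bit-for-bit on the same hardware.  A non-finite loss
component aborts training naming the component.

The shipped backbone (`TinyViT`) is deliberately small — 64-px inputs, 8-px
patches, D=32, 2 blocks, 4 heads — sized to train from scratch on the
synthetic benchmark in seconds per epoch on one CPU core.  It runs on a
hand-written reverse-mode autodiff tape over numpy (float64); every op's
gradient is finite-difference-tested.

## Synthetic benchmark

The generator renders an elliptical leaf on a background and paints a
class-specific lesion motif on it, emulating the qualitative structure of
curated "lab" collections versus in-the-wild photos:

* **Motifs** follow the shape/color/texture taxonomy of foliar disease:
  Poisson-placed discs (spots), irregular patches (blotch), oriented
  sinusoid texture (stripes), global hue shift (discoloration), or none
  (healthy).  Class identity fixes the motif kind and its hue/scale.
* **Severity ∈ [0,1]** is the alpha-blend weight of the motif overlay, so
  severity 0 renders exactly the healthy leaf — a scalar knob emulating
  early versus advanced infection.
* **Lab domain**: uniform bright background, centered unrotated leaf, fixed
  scale, no lighting jitter.
* **Wild domain**: the background blends toward cluttered earth tones in
  proportion to `clutter_density` (zero density degenerates to the lab
  process), plus Poisson-placed colored blobs, brightness jitter
  U(−0.05, 0.25) (deliberately asymmetric: field photos are brighter and
  more variable), contrast jitter, leaf scale/position/rotation jitter and
  per-image severity jitter.
* **Redundancy**: `plant_redundancy` appends jittered near-duplicates with
  traceable identifiers, emulating the minimal within-class variation of
  curated collections.

Determinism: every image draws from `SeedSequence(seed, domain, class,
index, stream)` substreams, so identical specs are bit-identical and the
motif stream is independent of the base-leaf stream (which is what makes
the severity-0 equality exact).

With default parameters the dominant pixel-statistics shift is
*wild-darker-than-lab* (the clutter background outweighs the positive
brightness jitter).  The generator documents this as its dictated
direction; the brightness-jitter effect itself is monotone and tested on
the wild side alone.

What the generator does **not** model: photo-realistic leaf venation or
texture, specific real diseases, occlusion, multiple leaves or multiple
simultaneous diseases per image, camera noise models beyond i.i.d.
Gaussian.  Passing tests therefore demonstrate the architecture's
mechanisms (routing, regularization, curation, shift detection) at desk
scale, not field-ready accuracy on real crops.

## Curation

Per class: deep features → seeded t-SNE to 2D (perplexity 30, learning
rate 500; the perplexity is capped at (class−1)/3 for small classes) →
k-means with `n_per_class` clusters → keep each cluster's medoid (the
actual image nearest the centroid).  The medoid rule replaces a manual
representative pick with a reproducible one.  Classes smaller than the
target are kept whole.  Offline-friendly feature extractors: raw
block-mean pixels, a seeded Gaussian random projection, or pooled tokens
of a (optionally trained) TinyViT.

Domain shift is reported as KL divergence between diagonal-Gaussian fits
to the two feature clouds, per matching class and pooled overall, with a
1e-6 variance floor.  The closed form is exact for the fitted Gaussians,
zero-consistent (KL(P‖P)=0) and stable in high dimension; absolute values
depend on the extractor and are meaningful for ordering and contrast, not
as universal constants.  RGB per-channel means/stds accompany the KL rows.

## Study harnesses

* **Collapse** (`collapse_experiment`): 6 classes × 150 lab images,
  severity 0.7; features cached from a frozen seeded TinyViT; a 5-expert
  dense-gated head (K=E so every expert's contribution is visible) trains
  30 epochs with all auxiliary losses off except the toggled entropy term.
  The gating loss is off in both arms: its best-expert target acts as an
  implicit balancer that would mask the collapse phenomenon the experiment
  exists to show.  Reported: final max/min expert usage per seed.
* **Orthogonality** (`orthogonality_experiment`): same data and head,
  λ_o toggled, paired seeds; reports mean pairwise normalized
  `‖W_i W_j^T‖_F / (‖W_i‖_F ‖W_j‖_F)`.
* **Desk scale** (`desk_scale_experiment`): end-to-end TinyViT+MoE (E=10,
  K=3) against an identically trained single-head baseline; 600 lab
  training images, held-out lab and wild test sets of 180 images each,
  30 epochs, paired seeds.  Accuracies are measured in eval mode.

Head-only training on cached frozen-backbone features isolates gating
dynamics from representation learning and keeps each run to a few seconds;
the behavioral contrasts are about the gate and experts, not the backbone.

## Numerical choices

* Logs are clamped with ε=1e-12; `0·log 0 := 0` holds exactly for sparse
  routing weights.
* The orthogonality term guards its square root with 1e-16 so the gradient
  at exactly-orthogonal configurations stays finite.
* Layer normalization uses ε=1e-6; constant vectors map to zeros.
* Top-K ties: stable argsort on negated weights → lower index wins.
* Metrics come from the confusion matrix; macro and weighted averages are
  both reported (the averaging mode materially changes numbers under class
  imbalance).  Classes absent from a test set are skipped from macro
  averages with a warning.

## Known limitations

* The autodiff engine is eager and unfused; it is sized for desk-scale
  models (thousands of parameters, minutes of CPU), not for pretrained
  ViT-Base-class backbones.
* Pretrained backbone adapters (and hence KL reports on ImageNet-pretrained
  features) require locally available weights; none ship with the package.
* The self-supervised gating target is one of several defensible
  constructions; it rewards specialization but its cross-entropy is noisy
  early in training (hence the detached gate input).
* Stochastic behavioral claims (collapse, transfer advantage) are
  majority-of-seeds statements over fixed seed lists, not significance
  tests.
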