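# Methods

This note documents the models, protocols, numerical conventions, and design
choices behind `petreid`, and states what the synthetic experiments do and do
not demonstrate.

## The verification model

Photographs are mapped to fixed-dimension embeddings; identity decisions are
cosine-similarity comparisons in that space. The training objective combines
two terms:

**Triplet term.** For anchor x_a, positive x_p (same identity), negative x_n
(different identity):

    L_triplet = mean over triplets of
                max(0, ‖f(x_a) − f(x_p)‖² − ‖f(x_a) − f(x_n)‖² + α)

with margin α = 0.45, computed on *raw* (unnormalized) embeddings with
squared Euclidean distances. The mean runs over all mined triplets, active
or not; this convention is stated so that reported loss values are exactly
reproducible.

**Intra-pair variance term.** With within-batch positive-pair cosine scores
{s_pi} (mean s̄_p) and negative-pair scores {s_nj} (mean s̄_n):

    L_var = meanᵢ max(0, (1−ε_pos)·s̄_p − s_pi)²
          + meanⱼ max(0, s_nj − (1+ε_neg)·s̄_n)²

ε_pos = ε_neg = 0.01. The square applies to the *hinged* deficit
(max(0, ·)²), so the term is exactly zero when every positive score reaches
the tolerance-scaled positive mean and every negative stays below the
tolerance-scaled negative mean; the alternative nesting (hinge of a square)
would penalize every pair and contradict the intended "only violations are
penalized" semantics. Note the band flips automatically when a group mean is
negative: for s̄_n = −0.5, the negative band edge is (1+ε)·s̄_n = −0.505.

**Combination.** L = λ₁·L_triplet + λ₂·L_var with λ₁ = 1.0, λ₂ = 0.5 —
identity separation is weighted above intra-identity consistency. The
triplet term uses Euclidean geometry while the variance term uses cosine
geometry; this mixed-metric design is intentional and kept as specified.

**Mining.** The batch-to-triplet conversion supports `batch_all` (every
valid anchor/positive/negative combination; the default, because it is
deterministic for a fixed batch) and `batch_hard` (per anchor, the most
distant positive and the closest negative, chosen on detached values so the
selection itself is not differentiated through). Pair scores for the
variance term are the cosine similarities of all unordered within-batch
same-identity and different-identity pairs.

## Balanced sampling

Each batch holds exactly P distinct identities contributing exactly K
distinct photos (defaults P = 58, K = 2, i.e. 116 samples), drawn uniformly
over eligible identities (those with ≥ K photos) regardless of photo count.
Epoch semantics had to be pinned down: one epoch is ⌊n_eligible/P⌋ batches
with no identity reused within the epoch; leftover identities rotate across
epochs because the identity permutation is redrawn per (seed, epoch).
Identities with fewer than K photos are excluded with a warning; fewer than
P eligible identities is an error naming the shortfall.

## Encoders and the freeze policy

All encoders satisfy one adapter contract: an ordered list of *blocks* (the
unit the freeze policy reasons about), an input/embedding layer, and a final
projection head. The transfer policy unfreezes exactly min(depth, N) final
blocks (default N = 5); embedding/input layers stay frozen and the head —
which sits after the last block — stays trainable. Frozen parameters are
verified bit-identical via SHA-256 checksums before and after training.

Three adapters ship:

- a 2-block patch transformer over 64×64 toy images (8×8 patches, model
  width 32);
- a hashed bag-of-token-embeddings + 1-block transformer text encoder
  (CRC-32 token hashing into a 512-slot table, so tokenization is stable
  across processes);
- an embedding adapter — input projection, residual MLP blocks, head — that
  wraps precomputed embedding stores in the same contract, used for
  experiments on stored features.

Because no automatic-differentiation framework is part of the dependency
set, the package includes a compact reverse-mode autodiff engine over numpy
(`petreid.autodiff`) with exactly the operator coverage these modules need;
Adam is implemented with the conventional defaults (β = (0.9, 0.999),
ε = 1e-8, no weight decay, no schedule, no early stopping).

## Fusion heads

Both modalities are first projected into a shared space (default dimension
128; the desk-scale studies use 64) by separate trainable linear maps. Then:

- **concat**: [v ; t], vision first (fixed order for reproducibility);
- **weighted text**: [v ; w·t], w a single trainable scalar initialized
  to 1;
- **cross-attention**: one attention layer, 4 heads, text tokens as queries,
  image patches as keys/values; attended token outputs are mean-pooled into
  a single vector that *replaces* concatenation. When only vector (pooled)
  embeddings are available, each vector is treated as a length-1 sequence —
  degenerate but well defined;
- **gated**: a one-hidden-layer ReLU MLP (hidden width 2·shared_dim) over
  [v ; t] with softmax over two outputs yields (g_img, g_txt), and the fused
  vector is g_img·v + g_txt·t. Gate weights are exposed for inspection.

Gating operates on projected embeddings. Fused vectors are used raw by the
triplet term and L2-normalized only implicitly at cosine-scoring time.

## Training loop

Encode both modalities → fuse (if configured) → mine pairs/triplets →
combined loss → Adam step on the trainable partition only. When a fusion
head is configured the loss sees the fused embeddings; otherwise the vision
embeddings. Unimodal and multimodal runs share every other code path so
comparisons isolate the fusion choice. Runs are deterministic given the
seed; a non-finite loss aborts with the epoch/batch/step named.

## Evaluation protocol

**Pair generation.** Positive pairs per identity are drawn uniformly from
the identity's C(n,2) candidates, capped at 15 per identity, under a global
constraint that no photo appears more than 5 times across the union of all
pairs. Negatives share the same usage counter (carried over from the
positive phase) and are matched in count to the positives. Two conventions
had to be added where the protocol is underdetermined: (i) the positive
phase only consumes up to ⌊5/2⌋ uses per photo, reserving budget so the
negative pool can actually match the positive count — without this, dense
identities exhaust the cap and the negative pool collapses; (ii) negatives
are chosen greedily on remaining budget (least-used photos first, seeded
tie-breaking), with species mixing allowed. Violations of any invariant
raise; generation is deterministic per seed.

**Metrics.**

- *ROC AUC* is computed in the exact rank formulation (midranks, so ties
  count ½) rather than by curve integration — on perfectly separated scores
  the trapezoid route returns 1 − O(1e-16) while the rank route returns
  exactly 1.
- *EER*: predict positive when score ≥ θ; sweep all ROC thresholds, and at
  the FPR/FNR crossing interpolate linearly between adjacent ROC points,
  breaking ties toward the lower FPR (the standard biometric convention).
  EER is invariant under strictly monotone transforms of the scores.
- *Top-k* uses leave-one-out retrieval over the pooled evaluation set: every
  photo whose identity has ≥ 2 photos queries the gallery of all other
  photos; a query is correct at k if any of its k nearest cosine neighbours
  shares its identity. Published Top-k numbers depend on this
  query/gallery construction, so it is stated loudly here.
- *McNemar*: χ² = (b−c)²/(b+c) on the discordant counts of two models'
  per-query Top-1 outcomes, no continuity correction, p from χ²(1);
  b + c = 0 returns (0, p = 1) by convention.

## Synthetic data generator

The generator emulates a lost-and-found pet corpus: identities with 2–10
photos each (uniform; matching the range such listings exhibit), categorical
attributes (coat color, pattern, size, ear shape, distinctive mark) drawn
from fixed vocabularies, a deterministic templated description naming the
species and every attribute exactly once, a toy raster image whose colors
and shapes encode the attributes (with per-photo translation and brightness
jitter as nuisance variation), and per-photo embeddings per modality:

    e = ρ·prototype + (1−ρ)·fresh_direction + σ·jitter

where the prototype is a unit-norm identity latent built from fixed
per-attribute-value embeddings plus an identity-unique direction, the fresh
direction is a per-photo unit vector independent of identity, and jitter is
isotropic Gaussian. ρ = 0 makes a modality statistically independent of
identity; ρ = 1, σ = 0 reproduces the prototype exactly, which yields the
construction limits AUC = 1, EER = 0, Top-1 = 1 with no training.

*Complementarity.* The vision prototype sees {color, pattern, size, ear
shape}; the text prototype sees {color, pattern, mark}, with the distinctive
mark text-exclusive. The modalities therefore overlap but each carries
evidence the other lacks, so a well-functioning fusion can beat either
modality alone — the premise the fusion study tests.

*Defaults.* ρ_v = ρ_t = 0.6, σ = 0.1, vision dim 64, text dim 32: moderately
discriminative but imperfect modalities, the regime in which fusion is
interesting. One pseudo-random stream per purpose (profiles, photo counts,
noise), each derived from the master seed, so changing the photo-count
distribution does not reshuffle identity profiles.

*What the generator does not emulate:* photorealistic appearance, a real
captioner's linguistic variability, label noise, pose/viewpoint structure,
or species-dependent appearance statistics. Passing tests on this generator
demonstrate that the machinery is correct and that the fusion mechanisms
behave as designed under controlled informativeness — not that any
particular accuracy level transfers to real photographs.

## Desk-scale study sizes

The fusion study trains three configurations (vision-only, concat fusion,
gated fusion) on 50 identities with P = 8, K = 2 for 10 epochs, averaged
over 5 seeds, using the embedding adapters (width 64). These adapters are
trained from scratch, so the study uses learning rate 1e-3; the 1e-4
fine-tuning rate is calibrated for large pretrained backbones and underfits
a from-scratch trunk within the fixed 10-epoch budget. The gate-recovery
study repeats the gated run with ρ_t = 0 and reads the learned gate
weights; the image gate should dominate. All study sizes were chosen so the
full suite runs in minutes on one CPU.

## Known limitations

- The cross-attention trainer path over stored vector embeddings reduces to
  length-1 sequences; full sequence behaviour is exercised only at the unit
  level with patch/token sequences.
- The pair protocol's budget-reservation and greedy-negative conventions
  are this package's own; other implementations of the same caps may select
  different (equally valid) pair sets.
- The tiny reference encoders are deliberately small; they exercise the
  block semantics of the freeze policy, not the representational power of
  pretrained backbones.
- Per-identity standard deviation in manifest summaries uses the sample
  (n−1) convention, stated here because the reference statistics tables do
  not name theirs.
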