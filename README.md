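# petreid

Multimodal individual-animal identity verification: balanced-batch metric
learning, image–text fusion, and a constrained pair-based evaluation
protocol, with a synthetic multimodal pet-data generator for desk-scale,
CPU-only experiments.

## The problem

Reuniting lost pets with their owners requires *re-identification*: deciding
whether two photographs show the same individual animal (verification) and
retrieving the right individual from a gallery (identification). Photographs
of pets come with a second, naturally available modality — free-text
descriptions of coat color, pattern, size, ear shape and distinctive marks —
and a good system should exploit both. This package implements the full
training and evaluation machinery for that setting, aimed at researchers who
want to study encoder and fusion choices under a controlled, reproducible
protocol.

## The method

**Objective.** Embeddings f(·) are shaped by a combined loss
L = λ₁·L_triplet + λ₂·L_var (defaults λ₁ = 1.0, λ₂ = 0.5):

- *Triplet loss* with margin α = 0.45 on squared Euclidean distances:
  L_triplet = mean max(0, ‖f(x_a) − f(x_p)‖² − ‖f(x_a) − f(x_n)‖² + α),
  where anchor/positive share an identity and the negative does not.
- *Intra-pair variance regularization* on cosine similarity scores: with
  positive-pair scores {s_pi} (mean s̄_p) and negative-pair scores {s_nj}
  (mean s̄_n),
  L_var = meanᵢ max(0, (1−ε_pos)·s̄_p − s_pi)² + meanⱼ max(0, s_nj − (1+ε_neg)·s̄_n)²
  with ε_pos = ε_neg = 0.01 — only positives below, and negatives above, the
  tolerance-scaled group mean are penalized.

**Sampling.** Batches hold exactly P = 58 identities × K = 2 photos
(116 samples), so every identity exerts equal gradient pressure regardless
of how many photos it owns. Adam at a fixed 1 × 10⁻⁴ for 10 epochs; only the
final five encoder blocks are unfrozen (transfer policy).

**Fusion heads** (vision and text first projected into a shared space):
concatenation [v ; t]; weighted text [v ; w·t] with one trainable scalar;
cross-attention where text tokens query image patches and the attended
outputs are mean-pooled; and gated fusion, where a small MLP + softmax
yields weights (g_img, g_txt) and the fused vector is g_img·v + g_txt·t.

**Evaluation.** Verification pairs are generated under the controlled
protocol (≤ 15 positive pairs per identity, no image used more than 5 times
across all pairs, negatives matched in count and sharing the usage budget).
Reported: ROC AUC (rank formulation), EER (interpolated FPR = FNR crossing),
leave-one-out Top-1/5/10 retrieval, and McNemar's χ² = (b−c)²/(b+c) on
discordant per-query outcomes for paired model comparison.

Because the trainable components run on a small built-in reverse-mode
autodiff engine over numpy, everything works on one CPU with no deep-learning
framework installed.

## Worked example

```python
import petreid as pr

# 50 synthetic identities, 2-10 photos each; text carries one
# identity-discriminative attribute (distinctive mark) that vision lacks
cfg = pr.SynthConfig(n_identities=50, seed=3)
manifest, vision, text = pr.generate_dataset(cfg)

report = pr.evaluate(vision, manifest, seed=1)
print(report.auc, report.eer, report.topk)
```

prints (vision modality, untrained, at the generator's default
informativeness ρ_v = 0.6):

```
0.9619408284023668 0.11076923076923073 {1: 0.8093841642228738, 5: 0.9472140762463344, 10: 0.9736070381231672}
```

i.e. same-animal pairs outscore different-animal pairs with probability
≈ 0.96, the equal-error operating point is ≈ 11%, and the right identity is
the nearest neighbour for ≈ 81% of queries. Training the gated fusion of
both modalities lifts Top-1 to ≈ 0.77–0.80 from a vision-only trained
baseline of ≈ 0.42–0.46 (see the fusion study in `petreid.experiments`).

The same pipeline is scriptable from the shell:

```bash
petreid simulate --seed 4 --n-identities 60 --out sim/
petreid train --manifest sim/manifest.csv --vision-emb sim/vision \
              --text-emb sim/text --config run.yaml --out ckpt/
petreid evaluate --emb ckpt/embeddings --manifest sim/manifest.csv --out report.json
petreid compare --report-a a.json --report-b b.json
petreid visualize --emb sim/vision --manifest sim/manifest.csv --out fig.png
```

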