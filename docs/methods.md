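# Methods

## The model

The package segments an image without any task-specific training by reading
object structure out of the self-attention of a pretrained latent diffusion
U-Net. The working assumption is that unconditioned self-attention already
encodes grouping: the attention map cast from a spatial location
concentrates its probability mass on locations belonging to the same object
(intra-map similarity), and two locations inside one object cast nearly
identical maps (inter-map similarity). Segmentation then reduces to
clustering the maps — with the crucial property that the number of clusters
is *not* specified in advance, unlike k-means or spectral alternatives.

The pipeline has three stages.

**Attention aggregation.** The backbone emits 4-D self-attention tensors
`A_k ∈ R^{r×r×r×r}` at resolutions r ∈ {8, 16, 32, 64}; the slice
`A_k[I, J]` is a probability map over the r-grid. The map axes (the last
two) of every tensor are bilinearly upsampled to 64×64 and renormalized
(bilinear interpolation does not exactly preserve mass). The fused tensor is

    A_f[I, J] = normalize( Σ_k R_k · Ã_k[⌊I/δ_k⌋, ⌊J/δ_k⌋] ),   δ_k = 64 / r_k,

so one coarse map is replicated over the whole δ_k×δ_k block of fine
reference locations it covers. The weights `R_k` sum to one and default to
resolution-proportional (`R_k ∝ r_k`): finer maps carry more weight, while
coarse maps still contribute the large-object grouping they are best at.
The weights are the main aggregation hyper-parameter and can be set
explicitly in the config.

**Iterative attention merging.** An M×M grid of anchor maps is sampled from
`A_f` at cell-center coordinates `i_m = ⌊(m + 0.5)·64/M⌋` (plain "evenly
spaced" placement would bias anchors toward one border at small M).
Distances between maps use the halved symmetric KL divergence

    D(p, q) = ½ [ KL(p‖q) + KL(q‖p) ]   (natural log, nats),

with an additive floor ε = 1e-12 and renormalization before the logarithms
so maps with exact zeros compare finitely. In the first pass each anchor is
replaced by the average of *all* 4096 maps of `A_f` within distance τ of it
(neighbourhoods may overlap, so duplicates are expected). Each of the N−1
following passes scans the current proposal list in order: the head
proposal absorbs every remaining proposal within τ (maps averaged and
renormalized, provenance united) and absorbed proposals leave the list
immediately. The scan is greedy and order-dependent by design; that is the
price of a deterministic procedure that needs no cluster count.

**Non-maximum suppression.** The surviving proposals are bilinearly
upsampled to the output resolution (default 512×512) and every pixel takes
the index of the maximal proposal there, ties to the lowest index. The
result is always a total partition; no pixel is left unassigned. The output
deliberately carries no semantic labels — a user selects the region of
interest, and the evaluation module emulates exactly that selection.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| τ (`tau`) | 1.0 | nats | merge threshold on the halved symmetric KL |
| M (`anchors`) | 16 | – | anchor grid side (M² anchors) |
| N (`iterations`) | 3 | – | total merge passes (1 initial + N−1 reductions) |
| `out_size` | 512 | px | side of the output mask |
| `weights` | proportional | – | `R_k`, or an explicit list |
| ε | 1e-12 | – | additive floor before logarithms |
| sum tolerance | 1e-4 | – | probability-map validation; drifted slices are renormalized with a warning |

Because the distance is the *halved* symmetric divergence, users porting a
threshold calibrated on the unhalved form should double it. Larger τ merges
more aggressively and the final proposal count is (empirically) non-
increasing in τ; the `--sweep-tau` CLI mode reproduces that sensitivity
curve per image.

## The synthetic generator

Planted scenes make the pipeline testable without the multi-gigabyte
backbone. Ground truth is a seeded Voronoi partition of the 64-grid into K
connected regions — irregular boundaries, closer to lesion or wound shapes
than rectangles. For each resolution the label map is downsampled by
majority vote (so coarse tensors show coarse grouping, as real low-
resolution attention does) and the map referenced from a cell is the
normalized indicator of its region, mixed with a uniform map at weight
`noise_level` and perturbed by seeded multiplicative jitter
(`1 + noise_level·U(−0.5, 0.5)` per pixel), then renormalized.

This construction plants the two similarity structures exactly and offers a
provable separation margin: at noise ≤ 0.1 the minimum between-region
distance exceeds the maximum within-region distance, so a recoverable τ
band exists. What it does **not** emulate: heavy-tailed attention
statistics, attention-head structure, cross-object leakage, or textured
backgrounds. Passing the recovery battery therefore demonstrates the
correctness of the algorithm, not the segmentation quality achievable on
real medical images, which depends on the backbone's attention quality.

The study conditions used throughout (tests and `scripts/acceptance.py`)
are 20 scenes — K ∈ {2, 3, 4, 5}, five seeds each — at noise 0.05 with one
tensor per resolution (8, 16, 32, 64), scored at the default
configuration on 256×256 masks. Mask scale does not affect matching
because ground truth is resized nearest-neighbour to the prediction.

## Numerical and design choices

* **Index mapping** `⌊I/δ_k⌋` (floor division) is the only replication rule
  consistent with one coarse map covering a contiguous block of fine
  locations.
* **Renormalization points:** after upsampling, after aggregation, and
  after every averaging step — the KL distance is only defined between
  distributions, so the invariant is restored eagerly rather than once at
  the end.
* **Tensor inventory** is deliberately unconstrained per resolution: the
  algorithm is count-agnostic, and published backbone descriptions disagree
  on the exact per-resolution layout. The synthetic default is one tensor
  per resolution; the adapter records the actual layout in the container's
  `meta` group.
* **First-pass neighbourhoods are non-exclusive** (one map may be absorbed
  by several anchors); later passes are exclusive. Distances in later
  passes are taken against the current, progressively shrinking list.
* **Head reduction** in the adapter is mean over attention heads; token
  order is row-major; both are recorded in `meta` for auditability.
* **Degenerate metrics:** 0/0 ratios score 1 for identical empty masks and
  0 otherwise, applied uniformly to Dice, IoU, precision and recall.
* **Binary-truth matching** defaults to the best single predicted region;
  `union` mode greedily adds regions while Dice improves. The choice
  materially affects scores, so the mode is always recorded in reports.
* **Multi-class matching** is an optimal one-to-one assignment (Hungarian
  algorithm on the negated Dice table); unmatched truth classes score
  against an empty prediction.

## Known limitations

* The greedy scan makes the proposal count *approximately* monotone in τ:
  rare +1 steps occur when a larger τ reroutes a boundary proposal into a
  different cluster early in the scan (about one sweep step in 45 under the
  study conditions). Order-invariant merging would remove this at the cost
  of departing from the published procedure.
* Multi-resolution aggregation mixes regions at coarse-cell boundaries, so
  on *noiseless* scenes the within-cluster spread is dominated by boundary
  mixtures rather than noise; the recoverable τ band sits higher than the
  noise level alone would suggest.
* Bilinear upsampling follows the half-pixel-center convention of
  `skimage.transform.resize`; labels within one pixel of a proposal
  decision boundary can differ from other interpolation conventions.
* τ is calibrated in nats of the halved divergence on 64×64 maps; it is not
  scale-free, and a different grid size would need recalibration.
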