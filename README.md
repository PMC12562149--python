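# adzus

Zero-shot unsupervised segmentation from diffusion self-attention maps, for
biomedical images where annotated training data is scarce or absent —
skin-lesion photographs, wound images, chest radiographs, blood-cell
microscopy and similar settings.

A pretrained latent diffusion U-Net, run once on a clean image without any
text prompt, produces self-attention tensors `A_k ∈ R^{r×r×r×r}` at
resolutions r ∈ {8, 16, 32, 64}: the slice `A_k[I,J]` is a probability map
describing how strongly location (I, J) attends everywhere else. Locations
inside one object cast nearly identical maps, so segmentation becomes map
clustering without a preset cluster count:

1. **Aggregation** — map axes upsampled bilinearly to 64×64 and fused,
   `A_f[I,J] = normalize(Σ_k R_k · Ã_k[⌊I/δ_k⌋, ⌊J/δ_k⌋])` with
   `δ_k = 64/r_k` and resolution-proportional weights `R_k`.
2. **Iterative merging** — an M×M anchor grid is sampled from `A_f`; each
   anchor absorbs every map within symmetric-KL distance
   `D(p,q) = ½[KL(p‖q) + KL(q‖p)] < τ`, then N−1 greedy passes merge the
   proposals themselves until the list stabilizes.
3. **Non-maximum suppression** — proposals are upsampled to the output
   resolution (512×512 by default) and each pixel takes the argmax proposal
   index, yielding a total partition mask.

The output delineates *all* distinguishable structures without naming them;
a user (or the bundled matching rule) selects the region of interest. A
synthetic planted-scene generator reproduces the attention structure with
known ground truth, so the entire pipeline is testable without downloading
any model; the optional `backbone` extra (torch + diffusers) adds real
attention extraction from Stable Diffusion checkpoints.

## Worked example

Generate a planted 3-region scene, segment it, and score the result:

```sh
$ adzus synth --k 3 --noise 0.05 --seed 7 --out scene.h5 --truth truth.png
wrote 4 tensors to scene.h5
$ adzus segment --attn scene.h5 --out mask.png --report seg.json
wrote mask with 3 label(s) to mask.png
$ adzus eval --pred mask.png --truth truth.png --report eval.json
mean Dice 0.9867, mean IoU 0.9740
```

`scene.h5` holds four attention tensors (one per resolution) synthesized
from a seeded Voronoi partition with 5% uniform-mixture noise. The merge
stage reduced 256 anchors to 3 proposals — the planted region count,
recovered without being told K — and the per-pixel argmax mask overlaps the
planted regions at Dice 0.987 / IoU 0.974 after optimal label matching.
`eval.json` carries the per-class confusion counts and all four metrics
(Dice, IoU, precision, recall); `--match union` switches the binary-truth
reduction from best-single-region to a greedy union of regions.

The same from Python:

```python
import adzus

scene = adzus.generate_scene(3, seed=7, noise_level=0.05)
att = adzus.aggregate(adzus.synthesize_attention(scene))
mask = adzus.segment(att, adzus.MergeConfig(tau=1.0, n_iterations=3, grid_side=16))
match = adzus.match_regions_to_truth(mask, scene.label_map)
print(mask.n_labels, round(match.mean_dice, 3))   # 3 0.987
```

`adzus config show` prints every default; `adzus segment --sweep-tau
0.2:3.0:10 --truth truth.png --report sweep.json` reproduces a τ
sensitivity sweep (proposal count and Dice per threshold). For real images,
`adzus extract --image x.png --t 300 --out attn.h5` (backbone extra
required) writes the same HDF5 container the synthetic generator produces,
and `adzus run` chains extraction/loading, segmentation, evaluation and
overlay rendering.

See `docs/methods.md` for the model, parameter semantics, the synthetic
generator's scope, and known limitations.

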