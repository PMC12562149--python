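"""Planted-scene generator: attention tensors with known object grouping.

Real diffusion self-attention exhibits two structural regularities that the
segmentation pipeline exploits: locations respond strongly to other locations
of the same object (intra-map similarity), and maps referenced from locations
of one object share their activations (inter-map similarity).  This module
plants those regularities synthetically so the whole pipeline is testable
without any pretrained backbone:

* the ground truth is a seeded Voronoi partition of the 64-grid into K
  connected regions (irregular boundaries, closer to lesion or wound shapes
  than rectangles);
* for each requested resolution the label map is downsampled by majority
  vote, so coarse tensors exhibit coarse grouping, as low-resolution
  attention does;
* the map referenced from a cell is the normalized indicator of that cell's
  region, mixed with a uniform map at weight ``noise_level`` and perturbed by
  seeded multiplicative jitter, then renormalized.

With ``noise_level = 0`` all within-region maps of a tensor are identical and
between-region maps have disjoint support; at moderate noise the minimum
between-region KL distance still exceeds the maximum within-region distance,
which is what guarantees a non-empty recoverable tau band for the merging
threshold.  No attempt is made to mimic real attention statistics (heavy
tails, head structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .attention import GRID, AttentionTensorSet
from .errors import InvalidInputError

#: Default tensor inventory: one tensor per canonical resolution.
DEFAULT_RESOLUTIONS = (8, 16, 32, 64)

MAX_REGIONS = 16


@dataclass
class PlantedScene:
    """A known 64-grid partition plus the noise parameters used on it."""

    label_map: np.ndarray  # (64, 64) int, values 0..K-1
    n_regions: int
    noise_level: float = 0.05
    seed: int = 0
    resolutions: tuple[int, ...] = DEFAULT_RESOLUTIONS

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if lm.shape != (GRID, GRID) or not np.issubdtype(lm.dtype, np.integer):
            raise InvalidInputError("label_map must be a (64, 64) integer array")
        present = np.unique(lm)
        if present.min() < 0 or present.max() >= self.n_regions:
            raise InvalidInputError("labels must lie in [0, n_regions)")
        if len(present) != self.n_regions:
            raise InvalidInputError("every region must occupy at least one cell")
        if not (0.0 <= self.noise_level < 1.0):
            raise InvalidInputError("noise_level must be in [0, 1)")
        self.label_map = lm


def generate_label_map(n_regions: int, seed: int) -> np.ndarray:
    """Seeded Voronoi partition of the 64-grid into K connected regions.

    K distinct site cells are drawn uniformly; each grid cell takes the label
    of its nearest site (Euclidean, ties to the lowest site index).  Voronoi
    cells are convex, hence connected, and each site keeps its own cell, so
    all K labels are present.
    """
    if not (1 <= n_regions <= MAX_REGIONS):
        raise InvalidInputError(f"n_regions must be in [1, {MAX_REGIONS}]")
    rng = np.random.default_rng(seed)
    sites_flat = rng.choice(GRID * GRID, size=n_regions, replace=False)
    sites = np.stack(np.unravel_index(sites_flat, (GRID, GRID)), axis=1)
    ii, jj = np.meshgrid(np.arange(GRID), np.arange(GRID), indexing="ij")
    cells = np.stack([ii.ravel(), jj.ravel()], axis=1)
    d2 = ((cells[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1).astype(np.int64).reshape(GRID, GRID)


def generate_scene(
    n_regions: int,
    seed: int,
    noise_level: float = 0.05,
    resolutions: tuple[int, ...] = DEFAULT_RESOLUTIONS,
) -> PlantedScene:
    return PlantedScene(
        label_map=generate_label_map(n_regions, seed),
        n_regions=n_regions,
        noise_level=noise_level,
        seed=seed,
        resolutions=tuple(resolutions),
    )


def downsample_labels_majority(label_map: np.ndarray, resolution: int) -> np.ndarray:
    """Block-wise majority vote from the 64-grid to ``resolution`` (ties low)."""
    if GRID % resolution != 0:
        raise InvalidInputError(f"resolution {resolution} must divide {GRID}")
    b = GRID // resolution
    blocks = (
        np.asarray(label_map)
        .reshape(resolution, b, resolution, b)
        .transpose(0, 2, 1, 3)
        .reshape(resolution, resolution, b * b)
    )
    mode = stats.mode(blocks, axis=2, keepdims=False).mode
    return np.asarray(mode, dtype=np.int64)


def synthesize_attention(scene: PlantedScene) -> AttentionTensorSet:
    """Build one attention tensor per requested resolution from a scene.

    Deterministic for identical (label_map, noise_level, seed, resolutions):
    jitter streams are derived from the scene seed and each resolution.
    """
    tensors = []
    for r in scene.resolutions:
        down = downsample_labels_majority(scene.label_map, r)
        # Normalized indicator map per region present at this resolution.
        region_maps = np.zeros((scene.n_regions, r, r))
        for lab in np.unique(down):
            ind = (down == lab).astype(np.float64)
            region_maps[lab] = ind / ind.sum()
        uniform = np.full((r, r), 1.0 / (r * r))
        base = (1.0 - scene.noise_level) * region_maps[down] + (
            scene.noise_level * uniform
        )
        if scene.noise_level > 0:
            rng = np.random.default_rng([scene.seed, r])
            jitter = 1.0 + scene.noise_level * rng.uniform(-0.5, 0.5, size=base.shape)
            base = base * jitter
        base /= base.sum(axis=(-2, -1), keepdims=True)
        tensors.append(base)
    return AttentionTensorSet(tensors=tensors)


@dataclass
class SceneBattery:
    """The study conditions for recovery experiments: seeded scenes spanning
    K in [2, 5] at noise 0.05."""

    region_counts: tuple[int, ...] = (2, 3, 4, 5)
    seeds_per_count: int = 5
    noise_level: float = 0.05
    base_seed: int = 0
    resolutions: tuple[int, ...] = DEFAULT_RESOLUTIONS
    scenes: list[PlantedScene] = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.base_seed)
        self.scenes = [
            generate_scene(
                k,
                int(rng.integers(0, 2**31 - 1)),
                noise_level=self.noise_level,
                resolutions=self.resolutions,
            )
            for k in self.region_counts
            for _ in range(self.seeds_per_count)
        ]
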