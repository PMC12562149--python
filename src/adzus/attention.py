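"""Attention data model, bilinear upsampling and multi-resolution aggregation.

A self-attention tensor ``A_k`` of spatial resolution ``r`` is a 4-D array of
shape ``(r, r, r, r)``: the slice ``A_k[I, J]`` is the attention (probability)
map that reference location ``(I, J)`` casts over the whole grid.  Tensors are
extracted from a diffusion U-Net at the four resolutions 8, 16, 32 and 64.
Aggregation fuses them into a single ``(64, 64, 64, 64)`` tensor ``A_f`` by

1. bilinearly upsampling the *map* dimensions (the last two) of every tensor
   to 64 x 64, renormalizing each map so it remains a distribution;
2. for every target reference location ``(I, J)`` on the 64-grid, summing the
   upsampled maps referenced at ``(I // delta_k, J // delta_k)`` with
   ``delta_k = 64 / r_k``, weighted by resolution-proportional weights
   ``R_k`` (``sum_k R_k = 1``) — i.e. one low-resolution map is replicated to
   all ``delta_k x delta_k`` high-resolution locations it covers;
3. renormalizing each aggregated slice to a valid distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, InvalidInputError

logger = logging.getLogger(__name__)

#: Side of the aggregated reference grid (the highest attention resolution).
GRID = 64

#: Resolutions a diffusion U-Net emits and the container therefore accepts.
CANONICAL_RESOLUTIONS = (8, 16, 32, 64)

#: Resolutions the upsampler accepts: the replication pattern needs an
#: integer cell size, so the resolution must divide the 64-grid.
UPSAMPLE_RESOLUTIONS = (1, 2, 4, 8, 16, 32, 64)

#: Absolute tolerance on probability-map sums.
SUM_TOL = 1e-4


def _as_float_tensor(arr, name: str = "tensor") -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite entries")
    if np.any(arr < 0):
        raise InvalidInputError(f"{name} contains negative entries")
    return arr


def validate_probability_slices(
    arr: np.ndarray, tol: float = SUM_TOL, name: str = "tensor"
) -> np.ndarray:
    """Check that every slice over the last two axes sums to one.

    Slices whose sums drift beyond ``tol`` are renormalized with a logged
    warning rather than rejected — extracted tensors accumulate float error.
    Negative or non-finite entries are always rejected.
    """
    arr = _as_float_tensor(arr, name)
    sums = arr.sum(axis=(-2, -1))
    if np.any(sums <= 0):
        raise InvalidInputError(f"{name} has a slice with non-positive total mass")
    if np.any(np.abs(sums - 1.0) > tol):
        worst = float(np.abs(sums - 1.0).max())
        logger.warning(
            "%s: %d slice(s) deviate from unit sum (worst |sum-1| = %.3g); "
            "renormalizing",
            name,
            int(np.count_nonzero(np.abs(sums - 1.0) > tol)),
            worst,
        )
    return arr / sums[..., None, None]


@dataclass
class AttentionTensorSet:
    """An ordered collection of 4-D self-attention tensors.

    Each tensor has shape ``(r, r, r, r)`` with ``r`` one of the canonical
    resolutions; the slice at any reference location is a probability map.
    The per-resolution tensor count is unconstrained: the merging algorithm
    is count-agnostic, and different backbones expose different inventories.
    """

    tensors: list[np.ndarray] = field(default_factory=list)
    validation_tolerance: float = SUM_TOL

    def __post_init__(self) -> None:
        checked = []
        for k, t in enumerate(self.tensors):
            t = np.asarray(t)
            if t.ndim != 4 or len(set(t.shape)) != 1:
                raise InvalidInputError(
                    f"tensor {k}: expected shape (r, r, r, r), got {t.shape}"
                )
            r = t.shape[0]
            if r not in CANONICAL_RESOLUTIONS:
                raise InvalidInputError(
                    f"tensor {k}: resolution {r} not in {CANONICAL_RESOLUTIONS}"
                )
            checked.append(
                validate_probability_slices(
                    t, self.validation_tolerance, name=f"tensor {k} (r={r})"
                )
            )
        self.tensors = checked

    @property
    def resolutions(self) -> list[int]:
        return [t.shape[0] for t in self.tensors]

    @property
    def counts_per_resolution(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.resolutions:
            counts[r] = counts.get(r, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.tensors)


@dataclass
class ResolutionWeights:
    """Per-tensor aggregation weights ``R_k``, summing to one.

    The weights are the method's main aggregation hyper-parameter; the
    default assignment is proportional to each tensor's spatial resolution,
    so finer maps contribute more to the fused tensor.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or w.size == 0:
            raise ConfigurationError("weights must be a non-empty 1-D sequence")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ConfigurationError("weights must be finite and non-negative")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"weights must sum to 1 within 1e-9 (got {w.sum()!r})"
            )
        self.weights = w

    @classmethod
    def proportional(cls, attention_set: AttentionTensorSet) -> "ResolutionWeights":
        return default_resolution_weights(attention_set)

    @classmethod
    def explicit(cls, values) -> "ResolutionWeights":
        v = np.asarray(values, dtype=np.float64)
        total = v.sum()
        if total <= 0:
            raise ConfigurationError("explicit weights must have positive total")
        return cls(v / total)


@dataclass
class AggregatedAttention:
    """The fused ``(64, 64, 64, 64)`` attention tensor ``A_f``.

    Every slice ``tensor[I, J]`` is a probability map over the 64-grid.
    """

    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor)
        if t.shape != (GRID, GRID, GRID, GRID):
            raise InvalidInputError(
                f"aggregated tensor must have shape {(GRID,) * 4}, got {t.shape}"
            )
        self.tensor = validate_probability_slices(t, name="aggregated tensor")

    @property
    def slices_flat(self) -> np.ndarray:
        """All 4096 maps as a ``(4096, 4096)`` row-stochastic matrix."""
        return self.tensor.reshape(GRID * GRID, GRID * GRID)


def upsample_attention(tensor: np.ndarray) -> np.ndarray:
    """Bilinearly upsample the map dimensions of an attention tensor to 64.

    Only the last two axes change: ``(r, r, r, r) -> (r, r, 64, 64)``.  Each
    upsampled map is renormalized to sum to one, since bilinear interpolation
    does not exactly preserve mass.  A tensor already at resolution 64 is
    returned unchanged (as a validated copy).
    """
    tensor = _as_float_tensor(tensor)
    if tensor.ndim != 4 or len(set(tensor.shape)) != 1:
        raise InvalidInputError(f"expected shape (r, r, r, r), got {tensor.shape}")
    r = tensor.shape[0]
    if r not in UPSAMPLE_RESOLUTIONS:
        raise InvalidInputError(
            f"resolution {r} does not divide the {GRID}-grid; "
            f"accepted: {UPSAMPLE_RESOLUTIONS}"
        )
    if r == GRID:
        up = tensor.copy()
    else:
        # Move map axes first so one vectorized resize call interpolates the
        # map axes only (the trailing reference axis has zoom factor 1).
        maps_first = tensor.transpose(2, 3, 0, 1).reshape(r, r, r * r)
        up = resize(
            maps_first,
            (GRID, GRID, r * r),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        up = up.reshape(GRID, GRID, r, r).transpose(2, 3, 0, 1)
        up = np.clip(up, 0.0, None)
    sums = up.sum(axis=(-2, -1), keepdims=True)
    if np.any(sums <= 0):
        raise InvalidInputError("upsampled slice lost all mass")
    return up / sums


def default_resolution_weights(
    attention_set: AttentionTensorSet,
) -> ResolutionWeights:
    """Weights proportional to each tensor's spatial resolution ``w_k``."""
    if len(attention_set) == 0:
        raise ConfigurationError("cannot derive weights for an empty tensor set")
    res = np.asarray(attention_set.resolutions, dtype=np.float64)
    return ResolutionWeights(res / res.sum())


def aggregate(
    attention_set: AttentionTensorSet,
    weights: ResolutionWeights | None = None,
) -> AggregatedAttention:
    """Fuse a multi-resolution tensor set into the 64-grid tensor ``A_f``.

    For every target reference location ``(I, J)`` the output slice is the
    weighted sum of the upsampled maps referenced at
    ``(I // delta_k, J // delta_k)``, ``delta_k = 64 / r_k`` — one coarse map
    feeds the whole ``delta_k x delta_k`` block of target locations it covers
    — followed by renormalization to a probability map.
    """
    if len(attention_set) == 0:
        raise ConfigurationError("cannot aggregate an empty tensor set")
    if weights is None:
        weights = default_resolution_weights(attention_set)
    if weights.weights.size != len(attention_set):
        raise ConfigurationError(
            f"{weights.weights.size} weights for {len(attention_set)} tensors"
        )

    out = np.zeros((GRID, GRID, GRID, GRID), dtype=np.float64)
    for t, w in zip(attention_set.tensors, weights.weights):
        if w == 0.0:
            continue
        r = t.shape[0]
        delta = GRID // r
        up = upsample_attention(t)  # (r, r, 64, 64)
        # Replicate each reference cell over its delta x delta block.
        view = out.reshape(r, delta, r, delta, GRID, GRID)
        view += w * up[:, None, :, None, :, :]

    # The constructor validates and renormalizes every slice; the weighted
    # sum of distributions already sums to ~1, so no extra pass is needed.
    return AggregatedAttention(out)
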