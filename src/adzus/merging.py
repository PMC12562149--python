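"""Anchor sampling, symmetric KL distance, iterative merging and NMS.

The fused tensor ``A_f`` holds 4096 attention maps, one per reference
location.  Maps referenced from the same object tend to be nearly identical,
so segmentation reduces to clustering maps without fixing a cluster count:

1. sample an ``M x M`` grid of evenly spaced *anchor* maps from ``A_f``;
2. replace each anchor by the average of all maps of ``A_f`` within symmetric
   KL distance ``tau`` of it (the initial merge);
3. for ``N - 1`` passes, greedily scan the proposal list in order, averaging
   each proposal with every remaining proposal within ``tau`` and removing
   the absorbed ones — proposal count is non-increasing;
4. bilinearly upsample the surviving proposals to the output resolution and
   label each pixel by the index of the maximal proposal there (per-pixel
   non-maximum suppression), yielding a total partition mask.

The distance is the halved symmetric KL divergence
``D(p, q) = (KL(p||q) + KL(q||p)) / 2`` in nats, with an additive floor
``eps = 1e-12`` applied before logarithms so maps with exact zeros compare
finitely.  The scan is greedy and order-dependent by design (row-major
anchors, proposals absorbed immediately); this keeps the procedure
deterministic and faithful to its published pseudocode form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr
from skimage.transform import resize

from .attention import GRID, SUM_TOL, AggregatedAttention, validate_probability_slices
from .errors import InvalidInputError

#: Additive floor applied to both distributions before logarithms.
KL_EPS = 1e-12

#: Default output resolution of the segmentation mask.
DEFAULT_OUT_SIZE = 512


@dataclass
class MergeConfig:
    """Parameters of the merging stage.

    tau : KL threshold in nats below which two maps are considered the same
        object group. Larger tau merges more aggressively (fewer proposals).
    n_iterations : total iteration count N; the initial anchor merge is
        iteration 1, followed by N - 1 greedy reduction passes.
    grid_side : M, the side of the M x M anchor grid.
    """

    tau: float = 1.0
    n_iterations: int = 3
    grid_side: int = 16

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise InvalidInputError(f"tau must be positive, got {self.tau}")
        if self.n_iterations < 1:
            raise InvalidInputError("n_iterations must be >= 1")
        if not (1 <= self.grid_side <= GRID):
            raise InvalidInputError(f"grid_side must be in [1, {GRID}]")


@dataclass
class AnchorGrid:
    """M x M evenly spaced reference locations and their attention maps."""

    grid_side: int
    anchor_points: list[tuple[int, int]]
    anchor_maps: np.ndarray  # (M*M, 64, 64)

    def __post_init__(self) -> None:
        if len(self.anchor_points) != self.grid_side**2:
            raise InvalidInputError("anchor grid must hold M^2 points")
        self.anchor_maps = validate_probability_slices(
            self.anchor_maps, name="anchor maps"
        )


@dataclass
class ProposalStack:
    """Ordered object proposals (probability maps) with their provenance.

    ``provenance[i]`` records the flat 64-grid indices of the source maps
    merged into proposal ``i``.  After the initial merge one source map may
    feed several proposals (anchor neighbourhoods overlap); every later pass
    keeps provenance sets disjoint.
    """

    proposals: np.ndarray  # (N_p, 64, 64)
    provenance: list[frozenset[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = np.asarray(self.proposals, dtype=np.float64)
        if p.ndim != 3 or p.shape[0] < 1:
            raise InvalidInputError("proposal stack must hold at least one map")
        self.proposals = validate_probability_slices(p, name="proposals")
        if not self.provenance:
            self.provenance = [frozenset() for _ in range(p.shape[0])]
        if len(self.provenance) != p.shape[0]:
            raise InvalidInputError("one provenance set per proposal required")

    def __len__(self) -> int:
        return int(self.proposals.shape[0])


@dataclass
class SegmentationMask:
    """Integer label image forming a total partition of the pixels."""

    labels: np.ndarray
    n_labels: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise InvalidInputError("labels must be a 2-D integer array")
        if self.n_labels < 1 or lab.min() < 0 or lab.max() >= self.n_labels:
            raise InvalidInputError("labels must lie in [0, n_labels)")
        self.labels = lab


# ---------------------------------------------------------------------------
# Anchor sampling
# ---------------------------------------------------------------------------

def anchor_coordinates(grid_side: int, grid: int = GRID) -> list[tuple[int, int]]:
    """Cell-center coordinates ``floor((m + 0.5) * grid / M)`` in row-major order."""
    centers = [int((m + 0.5) * grid // grid_side) for m in range(grid_side)]
    return [(i, j) for i in centers for j in centers]


def sample_anchors(att: AggregatedAttention, grid_side: int) -> AnchorGrid:
    """Extract the M^2 anchor maps from ``A_f`` at cell-center spacing."""
    if not (1 <= grid_side <= GRID):
        raise InvalidInputError(f"grid_side must be in [1, {GRID}], got {grid_side}")
    points = anchor_coordinates(grid_side)
    maps = np.stack([att.tensor[i, j] for i, j in points])
    return AnchorGrid(grid_side=grid_side, anchor_points=points, anchor_maps=maps)


# ---------------------------------------------------------------------------
# Symmetric KL distance
# ---------------------------------------------------------------------------

def _floor_and_normalize(flat: np.ndarray) -> np.ndarray:
    flat = flat + KL_EPS
    return flat / flat.sum(axis=-1, keepdims=True)


def symmetric_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Halved symmetric KL divergence ``(KL(p||q) + KL(q||p)) / 2`` in nats.

    Both maps are floored by ``KL_EPS`` and renormalized before the
    logarithms, so distributions with disjoint support get a large finite
    distance instead of infinity.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise InvalidInputError(f"shape mismatch: {p.shape} vs {q.shape}")
    for name, m in (("p", p), ("q", q)):
        s = float(m.sum())
        if not np.isfinite(s) or abs(s - 1.0) > SUM_TOL or np.any(m < 0):
            raise InvalidInputError(f"{name} is not a probability map (sum={s!r})")
    pf = _floor_and_normalize(p.reshape(-1))
    qf = _floor_and_normalize(q.reshape(-1))
    return float(0.5 * (rel_entr(pf, qf).sum() + rel_entr(qf, pf).sum()))


def pairwise_symmetric_kl(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Distance matrix ``D[i, j] = symmetric_kl(rows[i], cols[j])``.

    Inputs are stacks of maps, flattened internally; computed via the
    ``sum p log p - p . log q`` decomposition so the cross terms are two
    matrix products.
    """
    P = _floor_and_normalize(np.asarray(rows, dtype=np.float64).reshape(len(rows), -1))
    Q = _floor_and_normalize(np.asarray(cols, dtype=np.float64).reshape(len(cols), -1))
    if P.shape[1] != Q.shape[1]:
        raise InvalidInputError("maps must have equal size")
    logP = np.log(P)
    logQ = np.log(Q)
    neg_ent_p = np.einsum("ij,ij->i", P, logP)  # sum p log p
    neg_ent_q = np.einsum("ij,ij->i", Q, logQ)
    kl_pq = neg_ent_p[:, None] - P @ logQ.T
    kl_qp = neg_ent_q[None, :] - (Q @ logP.T).T
    d = 0.5 * (kl_pq + kl_qp)
    return np.maximum(d, 0.0)  # clip float negatives near zero


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def anchor_distance_matrix(
    anchors: AnchorGrid, att: AggregatedAttention
) -> np.ndarray:
    """``(M^2, 4096)`` distances from each anchor to every map of ``A_f``.

    Computing this once lets a tau sweep re-threshold cheaply.
    """
    return pairwise_symmetric_kl(anchors.anchor_maps, att.slices_flat)


def initial_merge(
    anchors: AnchorGrid,
    att: AggregatedAttention,
    tau: float,
    distances: np.ndarray | None = None,
) -> ProposalStack:
    """Average, for each anchor, all maps of ``A_f`` within distance tau.

    Yields M^2 proposals; neighbourhoods may overlap, so duplicates are
    expected at this stage.  Each anchor is itself a map of ``A_f`` (distance
    zero), so no neighbourhood is empty.
    """
    if not (tau > 0):
        raise InvalidInputError("tau must be positive")
    flat = att.slices_flat
    if distances is None:
        distances = anchor_distance_matrix(anchors, att)
    members = distances < tau  # (M^2, 4096) neighbourhood indicators
    for v, (i, j) in enumerate(anchors.anchor_points):
        members[v, i * GRID + j] = True  # the anchor's own map, robust to float
    counts = members.sum(axis=1, keepdims=True)
    merged = (members.astype(np.float64) @ flat) / counts
    merged /= merged.sum(axis=1, keepdims=True)
    provenance = [frozenset(np.flatnonzero(row).tolist()) for row in members]
    return ProposalStack(
        proposals=merged.reshape(-1, GRID, GRID), provenance=provenance
    )


def iterative_merge(stack: ProposalStack, cfg: MergeConfig) -> ProposalStack:
    """Greedy reduction: N - 1 passes of scan-average-absorb at threshold tau.

    Each pass walks the current list in order; the head proposal absorbs
    every remaining proposal within tau (averaging maps, uniting provenance)
    and absorbed proposals leave the list immediately.  The proposal count
    never increases, and a list whose pairwise distances all exceed tau is a
    fixed point.
    """
    maps = stack.proposals
    prov = list(stack.provenance)
    for _ in range(cfg.n_iterations - 1):
        new_maps: list[np.ndarray] = []
        new_prov: list[frozenset[int]] = []
        remaining = list(range(len(maps)))
        while remaining:
            head = remaining[0]
            cand = maps[remaining]
            dists = pairwise_symmetric_kl(maps[head][None], cand)[0]
            absorbed = [r for r, d in zip(remaining, dists) if d < cfg.tau]
            if head not in absorbed:  # guard against float drift at zero
                absorbed.insert(0, head)
            merged = maps[absorbed].mean(axis=0)
            new_maps.append(merged / merged.sum())
            new_prov.append(frozenset().union(*(prov[a] for a in absorbed)))
            remaining = [r for r in remaining if r not in set(absorbed)]
        maps = np.stack(new_maps)
        prov = new_prov
    return ProposalStack(proposals=maps, provenance=prov)


def nms_assign(stack: ProposalStack, out_size: int = DEFAULT_OUT_SIZE) -> SegmentationMask:
    """Per-pixel argmax over bilinearly upsampled proposals.

    Ties break toward the lowest proposal index, so the output is a
    deterministic total partition.
    """
    if out_size < GRID:
        raise InvalidInputError(f"out_size must be >= {GRID}")
    n_p = len(stack)
    if out_size == GRID:
        up = stack.proposals
    else:
        maps_last = stack.proposals.transpose(1, 2, 0)  # (64, 64, N_p)
        up = resize(
            maps_last,
            (out_size, out_size, n_p),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        ).transpose(2, 0, 1)
    labels = np.argmax(up, axis=0).astype(np.int32)
    return SegmentationMask(labels=labels, n_labels=n_p)


def segment(
    att: AggregatedAttention,
    cfg: MergeConfig | None = None,
    out_size: int = DEFAULT_OUT_SIZE,
) -> SegmentationMask:
    """Full merging pipeline: anchors -> initial merge -> reduction -> NMS."""
    cfg = cfg or MergeConfig()
    anchors = sample_anchors(att, cfg.grid_side)
    stack = initial_merge(anchors, att, cfg.tau)
    stack = iterative_merge(stack, cfg)
    return nms_assign(stack, out_size)


def propose(att: AggregatedAttention, cfg: MergeConfig | None = None) -> ProposalStack:
    """Run merging up to (and excluding) NMS, returning the proposal stack."""
    cfg = cfg or MergeConfig()
    anchors = sample_anchors(att, cfg.grid_side)
    return iterative_merge(initial_merge(anchors, att, cfg.tau), cfg)


def sweep_tau(
    att: AggregatedAttention,
    taus,
    cfg: MergeConfig | None = None,
) -> list[tuple[float, ProposalStack]]:
    """Rerun the merge at each tau, reusing the anchor distance matrix."""
    cfg = cfg or MergeConfig()
    anchors = sample_anchors(att, cfg.grid_side)
    distances = anchor_distance_matrix(anchors, att)
    out = []
    for tau in taus:
        tau_cfg = MergeConfig(
            tau=float(tau), n_iterations=cfg.n_iterations, grid_side=cfg.grid_side
        )
        stack = initial_merge(anchors, att, tau_cfg.tau, distances=distances)
        out.append((float(tau), iterative_merge(stack, tau_cfg)))
    return out
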