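"""Independent brute-force reference implementations used as test oracles.

Everything here is written as literal, loop-based transcriptions of the
operations under test, deliberately avoiding the vectorized code paths in
the package.
"""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-12
GRID = 64


def naive_symmetric_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Halved symmetric KL by direct python-loop summation (natural log)."""
    pf = (np.asarray(p, dtype=np.float64) + EPS).ravel()
    qf = (np.asarray(q, dtype=np.float64) + EPS).ravel()
    pf = pf / pf.sum()
    qf = qf / qf.sum()
    kl_pq = 0.0
    kl_qp = 0.0
    for a, b in zip(pf.tolist(), qf.tolist()):
        kl_pq += a * math.log(a / b)
        kl_qp += b * math.log(b / a)
    return 0.5 * (kl_pq + kl_qp)


def _pair_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Vectorized but formula-direct symmetric KL for larger oracle runs."""
    pf = (np.asarray(p, dtype=np.float64) + EPS).ravel()
    qf = (np.asarray(q, dtype=np.float64) + EPS).ravel()
    pf = pf / pf.sum()
    qf = qf / qf.sum()
    return float(0.5 * (np.sum(pf * np.log(pf / qf)) + np.sum(qf * np.log(qf / pf))))


def naive_bilinear_upsample(img: np.ndarray, out: int) -> np.ndarray:
    """Dense per-pixel bilinear interpolation, half-pixel centers, edge clamp."""
    img = np.asarray(img, dtype=np.float64)
    r = img.shape[0]
    res = np.zeros((out, out))
    scale = r / out
    for oy in range(out):
        for ox in range(out):
            sy = (oy + 0.5) * scale - 0.5
            sx = (ox + 0.5) * scale - 0.5
            y0 = math.floor(sy)
            x0 = math.floor(sx)
            wy = sy - y0
            wx = sx - x0
            acc = 0.0
            for dy, fy in ((y0, 1 - wy), (y0 + 1, wy)):
                for dx, fx in ((x0, 1 - wx), (x0 + 1, wx)):
                    cy = min(max(dy, 0), r - 1)
                    cx = min(max(dx, 0), r - 1)
                    acc += fy * fx * img[cy, cx]
            res[oy, ox] = acc
    return res


def naive_aggregate(tensors, weights, upsample) -> np.ndarray:
    """Quadruple-loop weighted aggregation with floor-division replication.

    ``upsample`` maps one (r, r, r, r) tensor to (r, r, 64, 64); the loop
    structure (replication, weighting, renormalization) is what this oracle
    pins down.
    """
    ups = [upsample(t) for t in tensors]
    out = np.zeros((GRID, GRID, GRID, GRID))
    for I in range(GRID):
        for J in range(GRID):
            acc = np.zeros((GRID, GRID))
            for up, w in zip(ups, weights):
                r = up.shape[0]
                delta = GRID // r
                acc = acc + w * up[I // delta, J // delta]
            out[I, J] = acc / acc.sum()
    return out


def naive_initial_merge(anchor_points, att_tensor, tau) -> np.ndarray:
    """First merging stage transcribed literally: one averaged map per anchor."""
    proposals = []
    for (i, j) in anchor_points:
        anchor = att_tensor[i, j]
        members = []
        for y in range(GRID):
            for z in range(GRID):
                if _pair_kl(anchor, att_tensor[y, z]) < tau:
                    members.append(att_tensor[y, z])
        merged = np.mean(members, axis=0)
        proposals.append(merged / merged.sum())
    return np.stack(proposals)


def naive_iterative_merge(proposals: np.ndarray, tau: float, n_iterations: int):
    """Greedy reduction passes transcribed literally with python lists."""
    maps = [p.copy() for p in proposals]
    for _ in range(n_iterations - 1):
        new_maps = []
        while maps:
            head = maps[0]
            absorbed = [m for m in maps if _pair_kl(head, m) < tau]
            if not any(m is head for m in absorbed):
                absorbed.insert(0, head)
            merged = np.mean(absorbed, axis=0)
            new_maps.append(merged / merged.sum())
            keep = []
            for m in maps:
                if not any(m is a for a in absorbed):
                    keep.append(m)
            maps = keep
        maps = new_maps
    return np.stack(maps)


def naive_nms(proposals: np.ndarray, out_size: int) -> np.ndarray:
    """Upsample each proposal independently, then per-pixel argmax."""
    ups = np.stack([naive_bilinear_upsample(p, out_size) for p in proposals])
    labels = np.zeros((out_size, out_size), dtype=np.int64)
    for y in range(out_size):
        for x in range(out_size):
            best = 0
            for idx in range(ups.shape[0]):
                if ups[idx, y, x] > ups[best, y, x]:
                    best = idx
            labels[y, x] = best
    return labels
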