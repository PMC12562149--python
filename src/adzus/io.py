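"""File formats: the HDF5 attention container, indexed-PNG masks, images.

The HDF5 layout is shared by the synthetic generator and the backbone
adapter, so downstream stages cannot tell where a tensor set came from:

    attn/<k>/<resolution>   float32 dataset, shape (r, r, r, r)
                            attrs: resolution, block_index
    meta                    group; attrs record at least timestep and
                            backbone identifier

Masks are written as single-channel indexed PNG with a fixed palette, so a
given label image always serializes to the same bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from PIL import Image

from .attention import AttentionTensorSet
from .errors import InvalidInputError
from .merging import SegmentationMask

#: Fixed palette: 16 well-separated colors, then a grayscale ramp.
_BASE_COLORS = [
    (0, 0, 0), (230, 25, 75), (60, 180, 75), (255, 225, 25),
    (0, 130, 200), (245, 130, 48), (145, 30, 180), (70, 240, 240),
    (240, 50, 230), (210, 245, 60), (250, 190, 212), (0, 128, 128),
    (220, 190, 255), (170, 110, 40), (255, 250, 200), (128, 0, 0),
]


def _palette() -> list[int]:
    colors = list(_BASE_COLORS) + [
        (g, g, g) for g in np.linspace(16, 255, 256 - len(_BASE_COLORS)).astype(int)
    ]
    return [c for rgb in colors for c in rgb]


def save_attention_h5(
    path, attention_set: AttentionTensorSet, meta: dict | None = None
) -> None:
    """Write a tensor set to the shared HDF5 container layout."""
    with h5py.File(path, "w") as f:
        for k, t in enumerate(attention_set.tensors):
            r = t.shape[0]
            ds = f.create_dataset(f"attn/{k}/{r}", data=t.astype(np.float32))
            ds.attrs["resolution"] = r
            ds.attrs["block_index"] = k
        grp = f.create_group("meta")
        meta = {"timestep": 0, "backbone": "synthetic", **(meta or {})}
        for key, value in meta.items():
            grp.attrs[key] = value


def load_attention_h5(path) -> tuple[AttentionTensorSet, dict]:
    """Read a tensor set and its metadata back from the container."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"attention container not found: {path}")
    tensors = []
    with h5py.File(path, "r") as f:
        if "attn" not in f:
            raise InvalidInputError(f"{path} has no 'attn' group")
        for k in sorted(f["attn"], key=int):
            grp = f[f"attn/{k}"]
            for name in grp:
                tensors.append(np.asarray(grp[name], dtype=np.float64))
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return AttentionTensorSet(tensors=tensors), meta


def save_mask_png(path, mask: SegmentationMask | np.ndarray) -> None:
    """Write a label image as indexed PNG with the fixed palette."""
    labels = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    if labels.min() < 0 or labels.max() > 255:
        raise InvalidInputError("indexed PNG supports labels in [0, 255]")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    img.putpalette(_palette())
    img.save(path, format="PNG", optimize=False, compress_level=6)


def load_mask_png(path) -> np.ndarray:
    """Read an indexed or grayscale PNG mask back as an integer label array."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"mask not found: {path}")
    img = Image.open(path)
    if img.mode not in ("P", "L", "I", "1"):
        img = img.convert("L")
    arr = np.asarray(img).astype(np.int64)
    if img.mode == "1":
        arr = (arr > 0).astype(np.int64)
    return arr


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an array (RGB kept, palettes expanded)."""
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"image not found: {path}")
    img = Image.open(path)
    if img.mode == "P":
        img = img.convert("RGB")
    return np.asarray(img)


def save_report_json(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
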