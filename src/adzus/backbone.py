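"""Optional extraction of real self-attention tensors from a latent
diffusion U-Net.

The convention is a single unconditioned pass: the image is encoded to the
latent space, noised to a large timestep (default t = 300, so a clean image
looks like a mostly denoised sample to the model), and pushed once through
the U-Net with the empty-prompt text embedding.  Every self-attention layer's
attention probabilities are captured, averaged over heads, and reshaped from
(tokens x tokens) to (h, w, h, w) in row-major token order, then grouped into
an :class:`~adzus.attention.AttentionTensorSet`.

This module needs the ``backbone`` extra (``pip install adzus[backbone]``,
i.e. torch + diffusers).  Everything downstream consumes the same HDF5
container the synthetic module writes, so the rest of the package works
without these dependencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionTensorSet
from .errors import InvalidInputError

_INSTALL_HINT = (
    "the pretrained-backbone adapter requires the optional 'backbone' extra; "
    "install it with: pip install adzus[backbone]  (torch and diffusers)"
)


@dataclass
class ExtractionConfig:
    """Settings for a single-pass unconditioned attention extraction."""

    backbone_id: str = "CompVis/stable-diffusion-v1-4"
    timestep: int = 300
    image_size: int = 512
    seed: int = 0
    unconditional: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.timestep < 1:
            raise InvalidInputError("timestep must be >= 1")
        if self.image_size < 64:
            raise InvalidInputError("image_size must be >= 64")
        if not self.unconditional:
            raise InvalidInputError(
                "only unconditioned extraction is supported (no text prompts)"
            )

    def meta(self) -> dict:
        return {
            "backbone": self.backbone_id,
            "timestep": self.timestep,
            "image_size": self.image_size,
            "seed": self.seed,
            "token_order": "row-major",
            "head_reduction": "mean",
        }


def _import_backbone_deps():
    try:
        import torch
        from diffusers import StableDiffusionPipeline
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(_INSTALL_HINT) from exc
    return torch, StableDiffusionPipeline


def _prepare_image(image: np.ndarray, size: int) -> np.ndarray:
    """Coerce to a square float RGB array in [-1, 1]."""
    from skimage.transform import resize

    arr = np.asarray(image)
    if arr.ndim == 2:  # grayscale replicated to 3 channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise InvalidInputError(f"expected an RGB or grayscale image, got {arr.shape}")
    arr = arr[..., :3].astype(np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    if arr.shape[:2] != (size, size):
        arr = resize(arr, (size, size), order=1, anti_aliasing=True, preserve_range=True)
    return arr * 2.0 - 1.0


class _AttentionRecorder:
    """diffusers attention processor that stores head-averaged probabilities."""

    def __init__(self, store: list):
        self.store = store

    def __call__(self, attn, hidden_states, encoder_hidden_states=None,
                 attention_mask=None, **kwargs):  # pragma: no cover - needs torch
        import torch

        residual = hidden_states
        query = attn.to_q(hidden_states)
        context = hidden_states if encoder_hidden_states is None else encoder_hidden_states
        key = attn.to_k(context)
        value = attn.to_v(context)
        query = attn.head_to_batch_dim(query)
        key = attn.head_to_batch_dim(key)
        value = attn.head_to_batch_dim(value)
        probs = attn.get_attention_scores(query, key, attention_mask)
        if encoder_hidden_states is None:  # record self-attention only
            heads = attn.heads
            p = probs.reshape(-1, heads, *probs.shape[1:]).mean(dim=1)
            self.store.append(p[0].detach().cpu().numpy())
        hidden_states = torch.bmm(probs, value)
        hidden_states = attn.batch_to_head_dim(hidden_states)
        hidden_states = attn.to_out[0](hidden_states)
        hidden_states = attn.to_out[1](hidden_states)
        if attn.residual_connection:
            hidden_states = hidden_states + residual
        return hidden_states / attn.rescale_output_factor


def _tokens_to_grid(mat: np.ndarray) -> np.ndarray:
    """Reshape a (tokens, tokens) attention matrix to (h, w, h, w)."""
    n = mat.shape[0]
    side = int(math.isqrt(n))
    if side * side != n:
        raise InvalidInputError(f"token count {n} is not a square grid")
    return mat.reshape(side, side, side, side)


def extract_attention(
    image: np.ndarray, cfg: ExtractionConfig | None = None
) -> AttentionTensorSet:
    """Single unconditioned denoising pass, capturing all self-attention maps.

    Raises an actionable :class:`ImportError` when torch/diffusers are not
    installed.
    """
    torch, StableDiffusionPipeline = _import_backbone_deps()
    cfg = cfg or ExtractionConfig()

    pipe = StableDiffusionPipeline.from_pretrained(cfg.backbone_id)
    pipe.unet.eval()
    device = "cuda" if torch.cuda.is_available() else "cpu"
    pipe = pipe.to(device)

    captured: list[np.ndarray] = []
    processors = {
        name: _AttentionRecorder(captured) if name.endswith("attn1.processor")
        else pipe.unet.attn_processors[name]
        for name in pipe.unet.attn_processors
    }
    pipe.unet.set_attn_processor(processors)

    arr = _prepare_image(image, cfg.image_size)
    with torch.no_grad():
        pixel = torch.from_numpy(arr.transpose(2, 0, 1)[None]).float().to(device)
        latent = pipe.vae.encode(pixel).latent_dist.mode()
        latent = latent * pipe.vae.config.scaling_factor

        generator = torch.Generator(device=device).manual_seed(cfg.seed)
        noise = torch.randn(latent.shape, generator=generator, device=device)
        t = torch.tensor([cfg.timestep], device=device)
        noisy = pipe.scheduler.add_noise(latent, noise, t)

        tokens = pipe.tokenizer(
            "", padding="max_length",
            max_length=pipe.tokenizer.model_max_length, return_tensors="pt",
        )
        uncond = pipe.text_encoder(tokens.input_ids.to(device))[0]
        pipe.unet(noisy, t, encoder_hidden_states=uncond)

    tensors = sorted((_tokens_to_grid(m) for m in captured), key=lambda a: a.shape[0])
    return AttentionTensorSet(tensors=[t.astype(np.float64) for t in tensors])
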