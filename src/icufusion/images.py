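"""Radiograph preprocessing and the patch-based vision encoder.

Grayscale chest-radiograph-like images are resized, replicated to three
channels and normalised with ImageNet channel statistics (the convention
inherited from ImageNet-pretrained vision transformers), then split into
P x P patches and encoded by a small transformer into N = (H/P)(W/P)
image tokens.

"Image absent" is represented by the all-zero tensor *in normalised
space* (:func:`zero_image`), so the clinical-only regime, vision dropout
and missing-image inference all feed the model one canonical input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .nn import Linear, Module, Tensor, TransformerEncoder
from .types import TokenBlock

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "ImageSpec",
    "BackboneConfig",
    "VisionBackbone",
    "preprocess_image",
    "zero_image",
    "patchify",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass(frozen=True)
class ImageSpec:
    """Target geometry and normalisation for preprocessed radiographs."""

    height: int = 384
    width: int = 384
    patch_size: int = 16
    channels: int = 3
    norm_mean: tuple = tuple(IMAGENET_MEAN)
    norm_std: tuple = tuple(IMAGENET_STD)

    def __post_init__(self):
        if self.height % self.patch_size or self.width % self.patch_size:
            raise ValueError(
                f"image {self.height}x{self.width} not divisible by patch {self.patch_size}"
            )
        if len(self.norm_mean) != self.channels or len(self.norm_std) != self.channels:
            raise ValueError("normalisation statistics must be per-channel")

    @property
    def n_tokens(self) -> int:
        return (self.height // self.patch_size) * (self.width // self.patch_size)

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.channels


@dataclass(frozen=True)
class BackboneConfig:
    """Vision transformer geometry.  The tiny default (depth 2, D=64) runs a
    CPU forward pass in well under a second and needs no downloaded weights;
    a pretrained backbone can be injected by loading its state dict as long
    as the geometry matches."""

    depth: int = 2
    dim: int = 64
    heads: int = 4
    mlp_ratio: int = 4
    pretrained: bool = False

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError("dim must be divisible by heads")


def _to_gray_float(raw) -> np.ndarray:
    """Accept a path, PIL image or 2-d array; return float grayscale in [0, 1]."""
    if isinstance(raw, (str, Path)):
        path = Path(raw)
        try:
            img = Image.open(path)
        except Exception as exc:
            raise IOError(f"cannot read image {path}: {exc}") from exc
        raw = img
    if isinstance(raw, Image.Image):
        mode = raw.mode
        if mode == "I;16":
            arr = np.asarray(raw, dtype=np.float64) / 65535.0
        else:
            arr = np.asarray(raw.convert("L"), dtype=np.float64) / 255.0
        return arr
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-d grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.max() > 1.0:  # 8- or 16-bit integer range
        arr = arr / (65535.0 if arr.max() > 255 else 255.0)
    return arr


def preprocess_image(raw, spec: ImageSpec = ImageSpec()) -> np.ndarray:
    """Resize to spec, replicate grayscale to 3 channels, normalise.

    Returns a (channels, H, W) float array; deterministic for fixed input.
    """
    gray = _to_gray_float(raw)
    if gray.shape != (spec.height, spec.width):
        pil = Image.fromarray(np.clip(gray * 255.0, 0, 255).astype(np.uint8))
        pil = pil.resize((spec.width, spec.height), Image.BILINEAR)
        gray = np.asarray(pil, dtype=np.float64) / 255.0
    stacked = np.repeat(gray[None, :, :], spec.channels, axis=0)
    mean = np.asarray(spec.norm_mean)[:, None, None]
    std = np.asarray(spec.norm_std)[:, None, None]
    return (stacked - mean) / std


def zero_image(img: np.ndarray) -> np.ndarray:
    """The canonical 'image absent' input: zeros in normalised space."""
    return np.zeros_like(img)


def patchify(img: np.ndarray, patch_size: int) -> np.ndarray:
    """(C, H, W) -> (N, P*P*C) row-major patch flattening."""
    c, h, w = img.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image {h}x{w} not divisible by patch {p}")
    gh, gw = h // p, w // p
    x = img.reshape(c, gh, p, gw, p)
    x = x.transpose(1, 3, 0, 2, 4)  # (gh, gw, c, p, p)
    return x.reshape(gh * gw, c * p * p)


class VisionBackbone(Module):
    """Patch-embedding transformer encoder producing N image tokens.

    Learned positional embeddings are added to the patch embeddings so the
    token block is sensitive to patch arrangement.  No internal class token
    is used: the fusion encoder owns the classification token, and the
    backbone's output block contains image tokens only.
    """

    def __init__(self, spec: ImageSpec, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.cfg = cfg
        self.patch_embed = Linear(spec.patch_dim, cfg.dim, rng)
        self.pos_embed = Tensor(
            rng.normal(0.0, 0.02, size=(spec.n_tokens, cfg.dim)), requires_grad=True
        )
        self.encoder = TransformerEncoder(
            cfg.dim, cfg.depth, cfg.heads, cfg.mlp_ratio * cfg.dim, rng
        )

    def encode_patches(self, patches: Tensor) -> Tensor:
        """(B, N, patch_dim) -> (B, N, D); also accepts a single (N, patch_dim)."""
        x = self.patch_embed(patches) + self.pos_embed
        return self.encoder(x)

    def encode_image(self, img: np.ndarray) -> TokenBlock:
        if img.shape != (self.spec.channels, self.spec.height, self.spec.width):
            raise ValueError(
                f"image shape {img.shape} does not match backbone spec "
                f"({self.spec.channels}, {self.spec.height}, {self.spec.width})"
            )
        patches = Tensor(patchify(img, self.spec.patch_size)[None, :, :])
        tokens = self.encode_patches(patches)
        return TokenBlock(tokens=tokens[0], modality="image")
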